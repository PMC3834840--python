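"""Score one gene with every statistic in the benchmark.

Builds a single gene with a classic imbalanced-signal pattern — 4 of 30 cases
shifted far above all 25 controls — and prints the DIDS variants, the four
outlier comparators, and the classical two-sample tests side by side.
"""

import numpy as np

from dids import analyze_gene, classical_stats, copa_stat, most_stat, ort_stat, os_stat
from dids.core import GeneVector

rng = np.random.default_rng(3)
controls = rng.normal(size=25)
cases = rng.normal(size=30)
cases[:4] += 4.0  # the aberrant subgroup

g = GeneVector("example_gene", controls, cases)

print("DIDS (up direction):")
for scoring in ("tanh", "quad", "sqrt"):
    r = analyze_gene(g, scoring, alpha=0.05, direction="up")
    print(f"  {scoring:>4}: k={r.k}  score={r.score:.3f}  exact p={r.p_value:.2e}")

print("\nOutlier comparators (score only — no p-value):")
print(f"  COPA(90): {copa_stat(g):.3f}")
print(f"  OS      : {os_stat(g):.3f}")
print(f"  ORT     : {ort_stat(g):.3f}")
stat, k = most_stat(g, return_k=True)
print(f"  MOST    : {stat:.3f}  (maximising subgroup size k = {k})")

print("\nClassical two-sample tests (two-sided):")
for which, label in [("t_ev", "t (pooled)"), ("t_uv", "t (Welch)"),
                     ("mw", "Mann-Whitney U"), ("ks", "KS D")]:
    stat, p = classical_stats(g, which)
    print(f"  {label:>14}: stat={stat:.3f}  p={p:.3g}")

print("\nThe outlier statistics respond strongly to the 4-sample subgroup while")
print("the group-mean tests see only a diluted shift of ~0.5 SD.")
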