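"""Screen a small synthetic cohort for subgroup markers with DIDS.

Simulates a 20-control / 20-case expression matrix of 2 000 genes in which
100 reporter genes carry a shift of delta = 3 in 25% of the cases (5 of 20),
runs the DIDS screen in the up direction, and prints the top candidates.
"""

from dids import run_dids
from dids.simulation import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n1=20, n2=20, n_genes=2000, reporter_fraction=0.05,
                       p_a=0.25, delta=3.0, seed=7)
ds = simulate_dataset(cfg)

tables = run_dids(ds.matrix, ds.labels, f="tanh", alpha=0.05, directions=["up"])
up = tables["up"]

top = up.head(10)[["gene_id", "k", "threshold", "score", "p_value", "rank"]]
print(top.to_string(index=False))

called = up[up["passed_filter"]]
hits = called["gene_id"].str.startswith("reporter_")
print(f"\n{len(called)} genes pass the alpha = 0.05 filter; "
      f"{hits.sum()} of them are true reporters "
      f"(PPV = {hits.mean():.2f}).")
print("k is the number of case samples strictly above the control maximum;")
print("the score sums tanh(excess) over those samples, and the p-value is the")
print("exact probability of >= k case outliers under random relabelling.")
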