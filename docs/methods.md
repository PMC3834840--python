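# Methods

## The model of imbalanced differential signal

The screen targets genes whose expression separates a *subgroup* of the case
samples from everything else: all n1 controls and the remaining cases sit in
a common baseline distribution, while an aberrant case subgroup sits above
(or below) **every** control value. The defining design choice is the
threshold: the control-group extremum (maximum for up-regulation, minimum for
down-regulation). Requiring outliers to clear every control buys clean
case/control separation — if a control sample also reached the aberrant
level, the gene could not cleanly mark the case-specific mechanism — at the
price of sensitivity to a single extreme control. The comparators relax this
in different ways (ORT/MOST fence outliers at the control quartiles; COPA/OS
ignore the grouping when setting the cutoff), which is precisely the contrast
the benchmark explores.

For one gene with control values a_1..a_n1 and case values b_1..b_n2,
threshold M = max_i a_i, the score is S = Σ_j f(b_j − M) over cases strictly
above M, with f strictly increasing and f(0) = 0.

### Scoring functions

* `quad` f(e) = e²: amplifies large excess; best when a very small subgroup
  carries a strong shift.
* `tanh` f(e) = tanh(e): bounded per-sample contribution; rewards recurrent
  modest excess and caps the influence of a single extreme value of possible
  technical origin. Default.
* `sqrt` f(e) = √e: intermediate, concave but unbounded.

These algebraic forms are this package's own choice of representatives for
the three named shapes; only the strictly-increasing contract and the
qualitative behaviour (amplifying vs. attenuating large excess) are
essential, and the benchmark (below) quantifies the consequences of the
choice. Any strictly increasing f with f(0)=0 can be passed as a custom
`ScoringFunction`.

### Exact permutation p-value

Under uniformly random reassignment of the n1 control and n2 case labels to
the n1+n2 observed values (held fixed, assumed distinct), the event
"at least k case-labelled samples exceed the control maximum" is exactly the
event "the k most extreme values are all case-labelled", whence

P(K ≥ k) = Π_{i=0}^{k−1} (n2 − i)/(n1 + n2 − i),  P(K ≥ 0) = 1.

The test suite verifies this closed form against exhaustive enumeration of
all C(n1+n2, n2) label assignments for every design with n1 + n2 ≤ 12. The
p-value depends only on (k, n1, n2), not on excess magnitudes, and is
therefore conservative: it measures only how improbable the *count* of
outliers is. Two properties worth noting for interpretation: P(K ≥ 1) =
n2/(n1+n2), so with few controls even one outlier is unremarkable; and p is
strictly decreasing in k and strictly decreasing in n1 (more controls raise
the bar).

### Ties and degenerate input

A case value exactly equal to the threshold is **not** an outlier: the
strict inequality matches the distinct-values permutation model and errs
conservative with tied (e.g. quantised) data. Genes containing non-finite
values are rejected by default; with `drop_na` they are dropped gene-wise,
so n1/n2 vary per gene, which the p-value accommodates naturally. Ranking of
filter survivors is by score descending with deterministic tie-breaks
(smaller p first, then gene id), so output files are byte-stable. The
Bonferroni-adjusted p column in output tables is informational only — the
published procedure filters on the nominal p, and ranking never uses the
adjusted value.

## Comparator statistics

Formulas follow the original publications of each method, with two
harmonising conventions: every median absolute deviation that stands in for
a standard deviation is scaled by 1.4826 (normal-consistency constant), and
genes whose robust scale is exactly zero get a not-available sentinel
(ranked last, printed as NA) rather than an infinity. COPA's percentile is a
parameter (default 90). MOST's null normalisation constants μ_k, σ_k — mean
and SD of the top-k partial sums of standard-normal order statistics — are
estimated once per n2 by Monte-Carlo with 10⁵ replicates under a fixed
internal seed and cached; ranking accuracy is insensitive to this estimate.
The classical tests are implemented from the textbook formulas (scipy
supplies tail areas only) and are cross-checked against scipy's independent
high-level implementations to 1e−8; the KS p-value uses the classic
Kolmogorov limiting distribution (the convention of R's `ks.test` with
`exact = FALSE`).

## The synthetic benchmark

### Generator

Non-reporter genes draw all n1+n2 samples i.i.d. N(0,1). Reporter genes draw
controls and a (1 − p_a) fraction of cases from N(0,1) and the
round-half-up(p_a·n2) aberrant cases from N(Δ, 1). Since all variances are 1,
Δ is the signal-to-noise ratio. Defaults mirror the study conditions: 25 000
genes, 1% reporters, p_a on a 1–39% grid (step 2%), Δ ∈ {1, 2, 3, 4},
scenarios (n1, n2) ∈ {(50,50), (25,95), (95,25), (10,10)} — the balanced and
small-cohort sizes are stated study conditions, the unbalanced pair are this
package's declared defaults, all overridable. The generator warns when
round(p_a·n2) ≤ 1, where reporters carry one or no aberrant case and power
is structurally low.

Randomness is counter-style: gene values are derived from the master seed in
fixed blocks of 4 096 gene streams, so gene *i*'s values depend only on
(seed, stream, i) and never on how many genes a run requests. Two runs with
the same seed are byte-identical.

What the generator does *not* emulate: correlated genes, heavy-tailed or
platform-specific noise, sample-level batch effects, or aberrant subgroups
that differ per gene (the same columns are aberrant in every reporter,
which is immaterial for per-gene statistics but means cross-gene structure
is absent). Passing benchmarks therefore demonstrate the statistics'
operating characteristics under idealised Gaussian conditions, not
performance on any particular platform.

### Power protocol

Following the empirical-null design, only reporter genes are simulated for
the power measurement; thresholds come from a separate run of null genes
(default 10⁵, resolving α ≥ 10⁻⁴). For each method the detection threshold at
false-positive rate α is the empirical (1−α) quantile of its null scores, so
methods are compared at the same realised α regardless of their own p-value
machinery. One-sided outlier statistics are thresholded on their upper tail;
the two-sided classical tests contribute the magnitude of their centred
statistic (|t|, |z|, D), matching their two-sided usage. Detection is
score ≥ threshold (so α = 1 calls everything, score atoms at zero included).
Power = fraction of reporters detected; pairwise power-difference tables are
emitted for every method pair.

### PPV protocol

PPV runs use full datasets: all genes are ranked by the method's score (for
DIDS: α-filter survivors by score first, then the remainder — the same
candidate-list order the screen produces) and PPV(N) is the fraction of
reporters in the top N, averaged over replicate datasets; FDR = 1 − PPV by
definition. Gene order is randomly permuted per replicate before ranking so
stable-sort tie-breaking cannot favour the reporters, which the generator
places first.

### Measured behaviour and a known limitation

The two regimes the benchmark is designed to exhibit both reproduce: with a
small, strongly shifted subgroup (Δ = 4, p_a = 5% on (50,50)) the outlier
statistics dominate the group-mean tests by a wide margin, and with a large,
weakly shifted subgroup (Δ = 1, p_a = 35%) the Welch t-test overtakes DIDS
at permissive α. Within DIDS, the quadratic scoring function is by far the
strongest in the first regime (power ≈ 0.77 vs ≈ 0.08 for tanh at α = 10⁻³,
500 reporters), because bounded tanh contributions cap a reporter's score
near its outlier count k, while at stringent α the null threshold is set by
null genes with k ≈ 8–10 modest outliers (P(K ≥ 9) ≈ 1.3·10⁻³ at n1 = n2 =
50). For the same reason MOST outperforms DIDS-tanh (though not DIDS-quad)
in that corner. The practical guidance follows directly: keep tanh as the
robust general-purpose default, but switch to quad when hunting very small
subgroups with large expected shifts at stringent significance levels.

## Problem sizes

Default test-suite and reproduction-script scales — 500 reporter genes and
10⁵ null genes per power cell, 6 replicate datasets for PPV baselines, exact
enumeration up to n1 + n2 = 12 — were chosen so every Monte-Carlo band in
the checks is at least three standard errors wide while a full run completes
in well under a minute on one CPU.
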