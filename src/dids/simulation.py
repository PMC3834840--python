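"""Synthetic benchmark: artificial datasets and power / PPV evaluation surfaces.

The artificial dataset emulates a two-group expression study in which only a
subgroup of the cases carries signal. Non-reporter genes draw every sample
from N(0,1). Reporter genes draw the controls and a (1 - p_a) fraction of the
cases from N(0,1) and shift the remaining round(p_a * n2) "aberrant" case
samples to N(delta, 1); since the variance is one everywhere, delta is the
signal-to-noise ratio of the aberrant subgroup. Defaults: 25 000 genes of
which 250 (1%) are reporters; p_a on a 1-39% grid; delta in {1, 2, 3, 4}.

Method comparison follows the empirical-null protocol: a large block of null
(non-reporter) genes is scored with each method and the (1 - alpha) quantile
of those scores becomes the detection threshold, so every method is compared
at the same realised false-positive rate regardless of whether it has a
p-value of its own. Power is then the fraction of simulated reporter genes
scoring above the threshold (reporter genes only are simulated for power, the
null block being a separate run). PPV is measured on full datasets: rank all
genes by the method's score and take the fraction of reporters in the top N;
FDR = 1 - PPV.

Randomness is counter-style: gene streams are derived from the master seed in
fixed-size blocks, so the values of gene *i* depend only on the seed and on
*i*, never on how many genes a run asks for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import comparators
from .core import dids_bulk_scores
from .io import ExpressionMatrix, GroupLabels

__all__ = [
    "SimulationConfig",
    "EvaluationSurface",
    "METHODS",
    "simulate_dataset",
    "simulate_null_genes",
    "simulate_reporter_genes",
    "empirical_null_threshold",
    "power_surface",
    "ppv_surface",
    "surface_difference",
    "run_benchmark",
    "DEFAULT_PA_GRID",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_TOPN_GRID",
    "DEFAULT_DELTAS",
    "DEFAULT_SCENARIOS",
]

DEFAULT_DELTAS: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
DEFAULT_PA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.40, 0.02), 2))
DEFAULT_ALPHA_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_TOPN_GRID: tuple[int, ...] = (10, 20, 50, 100, 250)
#: (n1, n2) group-size scenarios: balanced, the two unbalanced designs, and a
#: small-cohort setting.
DEFAULT_SCENARIOS: tuple[tuple[int, int], ...] = ((50, 50), (25, 95), (95, 25), (10, 10))


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs for one artificial-dataset condition."""

    n1: int
    n2: int
    n_genes: int = 25_000
    reporter_fraction: float = 0.01
    p_a: float = 0.05
    delta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both group sizes must be at least 1")
        if not 0.0 < self.p_a < 1.0:
            raise ValueError(f"p_a must lie in (0, 1), got {self.p_a}")
        if self.delta < 0.0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if not 0.0 <= self.reporter_fraction <= 1.0:
            raise ValueError("reporter_fraction must lie in [0, 1]")

    @property
    def n_reporters(self) -> int:
        return int(round(self.n_genes * self.reporter_fraction))

    @property
    def n_aberrant(self) -> int:
        """Aberrant case samples per reporter gene: round-half-up of p_a * n2."""
        return int(np.floor(self.p_a * self.n2 + 0.5))


@dataclass
class Dataset:
    """A simulated dataset with its ground truth."""

    matrix: ExpressionMatrix
    reporter_ids: set[str]
    labels: GroupLabels
    config: SimulationConfig


@dataclass
class EvaluationSurface:
    """Power or PPV values over a parameter grid, in long format.

    ``table`` columns: method, delta, p_a, the grid column (``alpha`` for
    power, ``top_n`` for PPV), ``value`` in [0, 1], and the per-cell sample
    size (``n_reporters`` or ``replicates``). PPV tables carry an ``fdr``
    column equal to 1 - value.
    """

    method: str
    kind: str  # "power" | "ppv"
    table: pd.DataFrame

    def pivot(self, delta: float) -> pd.DataFrame:
        axis = "alpha" if self.kind == "power" else "top_n"
        sub = self.table[self.table["delta"] == delta]
        return sub.pivot(index=axis, columns="p_a", values="value")


# ---------------------------------------------------------------------------
# random-number discipline

_BLOCK = 4096  # genes per derived stream; fixed so per-gene values are stable


def _blocked_normals(seed: int, stream: tuple[int, ...], n_genes: int, n_cols: int) -> np.ndarray:
    """N(0,1) block whose row i depends only on (seed, stream, i, n_cols)."""
    out = np.empty((n_genes, n_cols))
    for start in range(0, n_genes, _BLOCK):
        block_index = start // _BLOCK
        ss = np.random.SeedSequence(entropy=seed, spawn_key=stream + (block_index,))
        block = np.random.default_rng(ss).standard_normal((_BLOCK, n_cols))
        stop = min(start + _BLOCK, n_genes)
        out[start:stop] = block[: stop - start]
    return out


def _warn_low_aberrant(cfg: SimulationConfig) -> None:
    m = cfg.n_aberrant
    if m == 0:
        warnings.warn(
            f"round(p_a * n2) = 0 aberrant cases for p_a={cfg.p_a}, n2={cfg.n2}: "
            "reporter genes carry no signal and power will be nil",
            stacklevel=3,
        )
    elif m == 1:
        warnings.warn(
            f"p_a={cfg.p_a} with n2={cfg.n2} yields a single aberrant case per "
            "reporter gene; expect low power",
            stacklevel=3,
        )


def simulate_reporter_genes(cfg: SimulationConfig, n_reporters: int, stream: tuple[int, ...] = (1,)) -> tuple[np.ndarray, np.ndarray]:
    """Simulate reporter genes only; returns (controls, cases) blocks.

    The first ``round(p_a * n2)`` case columns are the aberrant samples
    (samples are exchangeable, so which columns carry the shift is
    immaterial to every statistic in the benchmark).
    """
    _warn_low_aberrant(cfg)
    values = _blocked_normals(cfg.seed, stream, n_reporters, cfg.n1 + cfg.n2)
    values[:, cfg.n1 : cfg.n1 + cfg.n_aberrant] += cfg.delta
    return values[:, : cfg.n1], values[:, cfg.n1 :]


def simulate_null_genes(cfg: SimulationConfig, n_null: int, stream: tuple[int, ...] = (0,)) -> tuple[np.ndarray, np.ndarray]:
    """Simulate non-reporter genes; returns (controls, cases) blocks."""
    values = _blocked_normals(cfg.seed, stream, n_null, cfg.n1 + cfg.n2)
    return values[:, : cfg.n1], values[:, cfg.n1 :]


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Full artificial dataset: reporters first, then non-reporters.

    Returns the matrix, the reporter gene IDs (ground truth) and the sample
    labels; fully reproducible from ``cfg.seed``.
    """
    n_rep = cfg.n_reporters
    n_null = cfg.n_genes - n_rep
    rep_c, rep_b = simulate_reporter_genes(cfg, n_rep, stream=(1,))
    null_c, null_b = simulate_null_genes(cfg, n_null, stream=(0,))
    values = np.vstack(
        [np.hstack([rep_c, rep_b]), np.hstack([null_c, null_b])]
    )
    width = len(str(cfg.n_genes))
    gene_ids = [f"reporter_{i + 1:0{width}d}" for i in range(n_rep)] + [
        f"null_{i + 1:0{width}d}" for i in range(n_null)
    ]
    sample_ids = [f"ctrl_{j + 1:03d}" for j in range(cfg.n1)] + [
        f"case_{j + 1:03d}" for j in range(cfg.n2)
    ]
    labels = GroupLabels(
        {**{s: "control" for s in sample_ids[: cfg.n1]}, **{s: "case" for s in sample_ids[cfg.n1 :]}}
    )
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    return Dataset(matrix, set(gene_ids[:n_rep]), labels, cfg)


# ---------------------------------------------------------------------------
# method registry

def _dids_scorer(scoring: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    def score(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
        return dids_bulk_scores(controls, cases, scoring)[0]

    return score


#: Bulk gene scorers by benchmark method name.
METHODS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "dids-tanh": _dids_scorer("tanh"),
    "dids-quad": _dids_scorer("quad"),
    "dids-sqrt": _dids_scorer("sqrt"),
    **comparators.BULK_SCORERS,
}


def _get_method(name: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    try:
        return METHODS[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}") from None


# ---------------------------------------------------------------------------
# empirical null and power

def _null_scores(method: str, cfg: SimulationConfig, n_null: int) -> np.ndarray:
    controls, cases = simulate_null_genes(cfg, n_null)
    return _get_method(method)(controls, cases)


def empirical_null_threshold(
    method: str,
    cfg: SimulationConfig,
    alpha: float,
    n_null: int = 100_000,
    null_scores: np.ndarray | None = None,
) -> float:
    """Detection threshold: the empirical (1 - alpha) quantile of null scores.

    ``null_scores`` may be passed to reuse one null run across alphas and
    methods. A gene is called detected when its score is at or above the
    threshold (so alpha = 1 calls everything, score atoms included); a fresh
    null sample reaches it at rate ~alpha.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if null_scores is None:
        null_scores = _null_scores(method, cfg, n_null)
    n = len(null_scores)
    if alpha < 1.0 / n:
        raise ValueError(
            f"alpha={alpha} is below the resolution of {n} null genes; "
            f"use at least {int(np.ceil(1.0 / alpha))} (100x more for stable tails)"
        )
    if alpha == 1.0:
        return float(np.nanmin(null_scores))
    return float(np.nanquantile(null_scores, 1.0 - alpha))


def power_surface(
    method: str,
    cfg: SimulationConfig,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    pa_grid: Sequence[float] = DEFAULT_PA_GRID,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_reporters: int = 500,
    n_null: int = 100_000,
    null_scores: np.ndarray | None = None,
) -> EvaluationSurface:
    """Power (fraction of reporters detected) over a (delta, p_a, alpha) grid.

    Reporter genes only are simulated for the power measurement; the null
    block is a separate run used solely to calibrate thresholds.
    """
    if null_scores is None:
        null_scores = _null_scores(method, cfg, n_null)
    thresholds = {
        a: empirical_null_threshold(method, cfg, a, null_scores=null_scores) for a in alpha_grid
    }
    scorer = _get_method(method)
    rows = []
    for di, delta in enumerate(deltas):
        for pi, p_a in enumerate(pa_grid):
            cell = replace(cfg, delta=float(delta), p_a=float(p_a))
            controls, cases = simulate_reporter_genes(
                cell, n_reporters, stream=(1, di, pi)
            )
            scores = scorer(controls, cases)
            for a in alpha_grid:
                detected = np.sum(scores >= thresholds[a])
                rows.append(
                    {
                        "method": method,
                        "delta": float(delta),
                        "p_a": float(p_a),
                        "alpha": float(a),
                        "value": detected / n_reporters,
                        "n_reporters": n_reporters,
                    }
                )
    return EvaluationSurface(method, "power", pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# PPV

def _ranking_order(method: str, controls: np.ndarray, cases: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Gene indices from best to worst candidate under a method's ranking.

    DIDS ranks p-value-filter survivors by score, then the remainder by
    score, mirroring the candidate-list construction; score-only methods rank
    by score with undefined (NaN) statistics last.
    """
    scores = _get_method(method)(controls, cases)
    if method.startswith("dids-"):
        n1, n2 = controls.shape[1], cases.shape[1]
        _, k = dids_bulk_scores(controls, cases, method.split("-", 1)[1])
        p_by_k = np.concatenate(
            [[1.0], np.cumprod((n2 - np.arange(n2)) / (n1 + n2 - np.arange(n2)))]
        )
        passed = p_by_k[k] <= alpha
        # survivors (key >= 1) always precede non-survivors (key in [0, 1)),
        # and each block is ordered by score descending
        key = np.where(passed, 1.0 + scores, 1.0 - 1.0 / (1.0 + np.maximum(scores, 0.0)))
        return np.argsort(-key, kind="stable")
    order_scores = np.where(np.isnan(scores), -np.inf, scores)
    return np.argsort(-order_scores, kind="stable")


def ppv_surface(
    method: str,
    cfg: SimulationConfig,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    pa_grid: Sequence[float] = DEFAULT_PA_GRID,
    topn_grid: Sequence[int] = DEFAULT_TOPN_GRID,
    replicates: int = 3,
    alpha: float = 0.05,
) -> EvaluationSurface:
    """PPV (fraction of reporters in the top N candidates) over the grid.

    Each cell simulates ``replicates`` full datasets, ranks all genes by the
    method's score and averages the top-N reporter fraction. The ``fdr``
    column is exactly 1 - value.
    """
    if max(topn_grid) > cfg.n_genes:
        raise ValueError("top-N exceeds the number of genes")
    rows = []
    for di, delta in enumerate(deltas):
        for pi, p_a in enumerate(pa_grid):
            ppv_sum = {n: 0.0 for n in topn_grid}
            for rep in range(replicates):
                cell = replace(
                    cfg,
                    delta=float(delta),
                    p_a=float(p_a),
                    seed=int(np.random.SeedSequence(
                        entropy=cfg.seed, spawn_key=(2, di, pi, rep)
                    ).generate_state(1)[0] % (2**31)),
                )
                ds = simulate_dataset(cell)
                # permute genes so positional tie-breaks cannot favour the
                # reporters (which the generator places first)
                perm = np.random.default_rng(cell.seed).permutation(cell.n_genes)
                controls = ds.matrix.values[perm, : cell.n1]
                cases = ds.matrix.values[perm, cell.n1 :]
                order = _ranking_order(method, controls, cases, alpha=alpha)
                is_reporter = np.zeros(cell.n_genes, dtype=bool)
                is_reporter[: cell.n_reporters] = True
                hits = np.cumsum(is_reporter[perm][order])
                for n in topn_grid:
                    ppv_sum[n] += hits[n - 1] / n
            for n in topn_grid:
                value = ppv_sum[n] / replicates
                rows.append(
                    {
                        "method": method,
                        "delta": float(delta),
                        "p_a": float(p_a),
                        "top_n": int(n),
                        "value": value,
                        "fdr": 1.0 - value,
                        "replicates": replicates,
                    }
                )
    return EvaluationSurface(method, "ppv", pd.DataFrame(rows))


def surface_difference(a: EvaluationSurface, b: EvaluationSurface) -> pd.DataFrame:
    """Cell-wise value difference (a minus b) of two surfaces on one grid."""
    if a.kind != b.kind:
        raise ValueError("cannot difference a power surface against a PPV surface")
    axis = "alpha" if a.kind == "power" else "top_n"
    keys = ["delta", "p_a", axis]
    merged = a.table.merge(b.table, on=keys, suffixes=("_a", "_b"))
    out = merged[keys].copy()
    out.insert(0, "method_b", b.method)
    out.insert(0, "method_a", a.method)
    out["difference"] = merged["value_a"] - merged["value_b"]
    return out


# ---------------------------------------------------------------------------
# benchmark driver

def run_benchmark(
    scenarios: Sequence[tuple[int, int]] = ((50, 50),),
    methods: Sequence[str] = ("dids-tanh", "copa", "os", "ort", "most", "ttest-uv"),
    deltas: Sequence[float] = DEFAULT_DELTAS,
    pa_grid: Sequence[float] = DEFAULT_PA_GRID,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    topn_grid: Sequence[int] = DEFAULT_TOPN_GRID,
    n_reporters: int = 500,
    n_null: int = 100_000,
    ppv_replicates: int = 0,
    n_genes: int = 25_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Power (and optionally PPV) surfaces for every scenario x method, plus
    pairwise difference tables; optionally written as long-format TSVs.

    Set ``ppv_replicates`` > 0 to include the (much more expensive) PPV
    surfaces on full ``n_genes``-gene datasets. Two runs with the same seed
    produce byte-identical outputs.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {sorted(METHODS)}")
    tables: dict[str, pd.DataFrame] = {}
    for n1, n2 in scenarios:
        tag = f"{n1}v{n2}"
        cfg = SimulationConfig(n1=n1, n2=n2, n_genes=n_genes, seed=seed)
        null_controls, null_cases = simulate_null_genes(cfg, n_null)
        surfaces: dict[str, EvaluationSurface] = {}
        for method in methods:
            null_scores = _get_method(method)(null_controls, null_cases)
            surfaces[method] = power_surface(
                method, cfg, deltas, pa_grid, alpha_grid,
                n_reporters=n_reporters, null_scores=null_scores,
            )
            tables[f"power_{tag}_{method}"] = surfaces[method].table
        for i, ma in enumerate(methods):
            for mb in methods[i + 1 :]:
                tables[f"power_diff_{tag}_{ma}_vs_{mb}"] = surface_difference(
                    surfaces[ma], surfaces[mb]
                )
        if ppv_replicates > 0:
            ppvs = {
                m: ppv_surface(m, cfg, deltas, pa_grid, topn_grid, ppv_replicates)
                for m in methods
            }
            for m, s in ppvs.items():
                tables[f"ppv_{tag}_{m}"] = s.table
            for i, ma in enumerate(methods):
                for mb in methods[i + 1 :]:
                    tables[f"ppv_diff_{tag}_{ma}_vs_{mb}"] = surface_difference(
                        ppvs[ma], ppvs[mb]
                    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.17g")
    return tables
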