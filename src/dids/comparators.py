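"""Baseline outlier and group-difference statistics used as benchmark comparators.

Four outlier-aware statistics from the cancer-outlier literature — COPA,
Outlier Sums (OS), the Outlier Robust T-statistic (ORT) and Maximum Ordered
Subset T-statistics (MOST) — plus the classical two-sample tests (pooled and
Welch t, Mann-Whitney, Kolmogorov-Smirnov). Each is exposed both as a
per-gene function on a :class:`~dids.core.GeneVector` and as a vectorised
bulk scorer over a genes-by-samples block, which is what the simulation
harness uses.

The outlier statistics differ in where the outlier cutoff comes from and how
contributions are standardised:

* COPA: r-th percentile of the cases, centred by the overall median and
  scaled by the overall MAD — no control-specific cutoff at all.
* OS: standardise everything by overall median/MAD, then sum the case values
  above the q75 + IQR fence of the standardised pooled values.
* ORT: fence from the *controls* (q75 + IQR of controls); sum control-median-
  centred case values beyond it, scaled by the pooled within-group median
  absolute deviation.
* MOST: for every candidate subgroup size k, the standardised sum of the top
  k case values, normalised by the null mean/sd of the top-k sum of normal
  order statistics; the statistic is the max over k.

Wherever a MAD plays the role of a standard deviation it is scaled by 1.4826
(the consistency constant for the normal distribution) so scales are
comparable across methods. A gene whose robust scale estimate is exactly zero
has no defined statistic; it is flagged as NaN internally and callers rank it
last / print it as NA — the sentinel never silently propagates as infinity.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats

from .core import GeneVector

__all__ = [
    "copa_stat",
    "os_stat",
    "ort_stat",
    "most_stat",
    "classical_stats",
    "copa_bulk",
    "os_bulk",
    "ort_bulk",
    "most_bulk",
    "t_ev_bulk",
    "t_uv_bulk",
    "mw_bulk",
    "ks_bulk",
    "most_null_constants",
]

#: MAD -> SD consistency constant for the normal distribution.
MAD_SCALE = 1.4826


def _mad(x: np.ndarray, axis: int = -1) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def _as_rows(g: GeneVector) -> tuple[np.ndarray, np.ndarray]:
    return g.controls[None, :], g.cases[None, :]


# ---------------------------------------------------------------------------
# COPA

def copa_bulk(controls: np.ndarray, cases: np.ndarray, r: float = 90.0) -> np.ndarray:
    """COPA over gene rows: (q_r(cases) - median(all)) / (1.4826 * MAD(all))."""
    if not 50.0 < r < 100.0:
        raise ValueError(f"COPA percentile must lie in (50, 100), got {r}")
    pooled = np.concatenate([controls, cases], axis=1)
    med = np.median(pooled, axis=1)
    scale = MAD_SCALE * _mad(pooled, axis=1)
    qr = np.percentile(cases, r, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (qr - med) / scale
    out[scale == 0.0] = np.nan
    return out


def copa_stat(g: GeneVector, r: float = 90.0) -> float:
    """Cancer Outlier Profile Analysis statistic (percentile default 90)."""
    return float(copa_bulk(*_as_rows(g), r=r)[0])


# ---------------------------------------------------------------------------
# Outlier Sums

def os_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Outlier Sums over gene rows.

    All values are standardised by the overall median and scaled MAD; the
    statistic is the sum of standardised case values above q75 + IQR of the
    standardised pooled values (zero when no case clears the fence).
    """
    pooled = np.concatenate([controls, cases], axis=1)
    med = np.median(pooled, axis=1, keepdims=True)
    scale = MAD_SCALE * _mad(pooled, axis=1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pooled = (pooled - med) / scale
        z_cases = (cases - med) / scale
    q75 = np.percentile(z_pooled, 75, axis=1)
    q25 = np.percentile(z_pooled, 25, axis=1)
    fence = (q75 + (q75 - q25))[:, None]
    out = np.where(z_cases > fence, z_cases, 0.0).sum(axis=1)
    out[scale[:, 0] == 0.0] = np.nan
    return out


def os_stat(g: GeneVector) -> float:
    if g.n1 + g.n2 < 4:
        raise ValueError("Outlier Sums needs at least 4 samples for stable quartiles")
    return float(os_bulk(*_as_rows(g))[0])


# ---------------------------------------------------------------------------
# ORT

def _pooled_group_mad(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Median absolute deviation from the own-group median, pooled, x1.4826."""
    dev_c = np.abs(controls - np.median(controls, axis=1, keepdims=True))
    dev_b = np.abs(cases - np.median(cases, axis=1, keepdims=True))
    return MAD_SCALE * np.median(np.concatenate([dev_c, dev_b], axis=1), axis=1)


def ort_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Outlier Robust T-statistic over gene rows.

    Outliers are case values above q75(controls) + IQR(controls); the
    statistic sums their control-median-centred values, divided by the pooled
    within-group median absolute deviation.
    """
    q75 = np.percentile(controls, 75, axis=1)
    q25 = np.percentile(controls, 25, axis=1)
    fence = (q75 + (q75 - q25))[:, None]
    med_c = np.median(controls, axis=1)[:, None]
    num = np.where(cases > fence, cases - med_c, 0.0).sum(axis=1)
    scale = _pooled_group_mad(controls, cases)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / scale
    out[scale == 0.0] = np.nan
    return out


def ort_stat(g: GeneVector) -> float:
    if g.n1 < 4:
        raise ValueError("ORT needs at least 4 control samples for control quartiles")
    return float(ort_bulk(*_as_rows(g))[0])


# ---------------------------------------------------------------------------
# MOST

_MOST_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_MOST_REPLICATES = 100_000
_MOST_SEED = 731      # internal; fixed so constants never depend on analysis seeds


def most_null_constants(n2: int, n_replicates: int = _MOST_REPLICATES) -> tuple[np.ndarray, np.ndarray]:
    """Null mean and sd of the top-k partial sums of N(0,1) order statistics.

    For samples of size ``n2``, returns arrays ``mu[k-1]``, ``sigma[k-1]`` for
    k = 1..n2, estimated by Monte-Carlo (fixed internal seed, cached per n2).
    """
    if n2 < 1:
        raise ValueError("n2 must be positive")
    if n2 not in _MOST_CACHE:
        rng = np.random.default_rng(_MOST_SEED + n2)
        draws = rng.standard_normal((n_replicates, n2))
        draws.sort(axis=1)
        partial = np.cumsum(draws[:, ::-1], axis=1)  # top-k sums, k = 1..n2
        _MOST_CACHE[n2] = (partial.mean(axis=0), partial.std(axis=0, ddof=1))
    return _MOST_CACHE[n2]


def most_bulk(
    controls: np.ndarray, cases: np.ndarray, return_k: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Maximum Ordered Subset T-statistics over gene rows.

    ``M_k`` is the sum over the top k case values of the control-median-
    centred value divided by the pooled within-group median absolute
    deviation; each ``M_k`` is standardised by the null moments of the top-k
    normal order-statistic sum and the statistic is the maximum over k. With
    ``return_k`` the maximising subgroup size is returned as well.
    """
    n2 = cases.shape[1]
    mu, sigma = most_null_constants(n2)
    med_c = np.median(controls, axis=1)[:, None]
    scale = _pooled_group_mad(controls, cases)[:, None]
    top = np.sort(cases, axis=1)[:, ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.cumsum((top - med_c) / scale, axis=1)
        t = (m - mu[None, :]) / sigma[None, :]
    stat = t.max(axis=1)
    stat[scale[:, 0] == 0.0] = np.nan
    if return_k:
        best_k = t.argmax(axis=1) + 1
        return stat, best_k
    return stat


def most_stat(g: GeneVector, return_k: bool = False) -> float | tuple[float, int]:
    if g.n2 < 2:
        raise ValueError("MOST needs at least 2 case samples")
    if return_k:
        stat, k = most_bulk(*_as_rows(g), return_k=True)
        return float(stat[0]), int(k[0])
    return float(most_bulk(*_as_rows(g))[0])


# ---------------------------------------------------------------------------
# Classical two-sample tests
#
# Implemented from the textbook formulas (scipy supplies tail areas only);
# scipy's high-level tests serve as the independent cross-check in the suite.

def t_ev_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic (cases minus controls)."""
    n1, n2 = controls.shape[1], cases.shape[1]
    v1 = controls.var(axis=1, ddof=1)
    v2 = cases.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (cases.mean(axis=1) - controls.mean(axis=1)) / denom
    t[denom == 0.0] = np.nan
    return t


def t_uv_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Welch (unequal variance) two-sample t statistic (cases minus controls)."""
    n1, n2 = controls.shape[1], cases.shape[1]
    se2 = controls.var(axis=1, ddof=1) / n1 + cases.var(axis=1, ddof=1) / n2
    denom = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (cases.mean(axis=1) - controls.mean(axis=1)) / denom
    t[denom == 0.0] = np.nan
    return t


def _welch_df(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    n1, n2 = controls.shape[1], cases.shape[1]
    a = controls.var(axis=1, ddof=1) / n1
    b = cases.var(axis=1, ddof=1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def mw_u(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Mann-Whitney U counting case-over-control wins (ties count half)."""
    pooled = np.concatenate([controls, cases], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    n2 = cases.shape[1]
    return ranks[:, controls.shape[1]:].sum(axis=1) - n2 * (n2 + 1) / 2.0


def mw_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Normal-approximation z for the Mann-Whitney U, continuity-corrected.

    Tie correction is applied to the variance; with continuous expression
    values ties have probability zero but integer-valued inputs are handled.
    """
    n1, n2 = controls.shape[1], cases.shape[1]
    u = mw_u(controls, cases)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([controls, cases], axis=1)
    n = n1 + n2
    tie_term = np.zeros(pooled.shape[0])
    srt = np.sort(pooled, axis=1)
    has_ties = np.where((np.diff(srt, axis=1) == 0.0).any(axis=1))[0]
    for i in has_ties:  # ties have probability zero for continuous data
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    z[var == 0.0] = np.nan
    return z


def ks_bulk(controls: np.ndarray, cases: np.ndarray) -> np.ndarray:
    """Two-sample Kolmogorov-Smirnov D over gene rows."""
    n1, n2 = controls.shape[1], cases.shape[1]
    pooled = np.concatenate([controls, cases], axis=1)
    order = np.argsort(pooled, axis=1, kind="stable")
    srt = np.take_along_axis(pooled, order, axis=1)
    is_case = order >= n1
    cum_case = np.cumsum(is_case, axis=1) / n2
    cum_ctrl = np.cumsum(~is_case, axis=1) / n1
    gap = np.abs(cum_case - cum_ctrl)
    # the ECDF difference is only evaluable after a full tie group; interior
    # positions of a tie are not valid evaluation points
    valid = np.ones_like(gap, dtype=bool)
    valid[:, :-1] = np.diff(srt, axis=1) != 0.0
    return np.where(valid, gap, 0.0).max(axis=1)


def classical_stats(g: GeneVector, which: str) -> tuple[float, float]:
    """Classical two-sample statistic and two-sided p-value.

    ``which`` is one of ``t_ev`` (pooled t), ``t_uv`` (Welch t), ``mw``
    (Mann-Whitney U; p from the continuity-corrected normal approximation) or
    ``ks`` (two-sample D; asymptotic Kolmogorov p).
    """
    C, B = _as_rows(g)
    if which in ("t_ev", "t_uv"):
        if g.n1 < 2 or g.n2 < 2:
            raise ValueError("t-tests need at least 2 samples per group")
        if which == "t_ev":
            t = float(t_ev_bulk(C, B)[0])
            df = g.n1 + g.n2 - 2
        else:
            t = float(t_uv_bulk(C, B)[0])
            df = float(_welch_df(C, B)[0])
        if np.isnan(t):
            return np.nan, np.nan
        return t, float(2.0 * stats.t.sf(abs(t), df))
    if which == "mw":
        u = float(mw_u(C, B)[0])
        z = float(mw_bulk(C, B)[0])
        if np.isnan(z):
            return u, np.nan
        return u, float(2.0 * stats.norm.sf(abs(z)))
    if which == "ks":
        d = float(ks_bulk(C, B)[0])
        en = np.sqrt(g.n1 * g.n2 / (g.n1 + g.n2))
        return d, float(np.clip(stats.kstwobign.sf(en * d), 0.0, 1.0))
    raise ValueError(f"unknown classical statistic {which!r}")


#: Bulk scorers by method name as used in the simulation harness. Two-sided
#: tests contribute their *magnitude* to the empirical-null thresholding,
#: matching their two-sided usage; one-sided outlier statistics use the upper
#: tail directly.
BULK_SCORERS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "copa": copa_bulk,
    "os": os_bulk,
    "ort": ort_bulk,
    "most": most_bulk,
    "ttest-ev": lambda C, B: np.abs(t_ev_bulk(C, B)),
    "ttest-uv": lambda C, B: np.abs(t_uv_bulk(C, B)),
    "mw": lambda C, B: np.abs(mw_bulk(C, B)),
    "ks": ks_bulk,
}
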