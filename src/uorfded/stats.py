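"""Shared nonparametric statistics and binning helpers.

Thin, contract-stable wrappers around scipy/statsmodels routines used by the
Ribo-Seq and MPRA analyses: Mann-Whitney U comparisons with the figure-legend
star convention, Spearman correlation, one-sided hypergeometric overlap
tests, notched-boxplot summaries (type-7 quartiles, 1.58·IQR/√n notch) and
the quantile / fixed-size binning used throughout the cohort analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "NotchedSummary",
    "mann_whitney_u",
    "spearman_rho",
    "hypergeometric_overlap",
    "notched_summary",
    "make_bins",
    "bh_adjust",
    "significance_stars",
]

#: Largest combined sample size at which the exact MWU null distribution is
#: enumerated (ties force the tie-corrected normal approximation).
_EXACT_MWU_N = 12


def significance_stars(p: float) -> str:
    """Map a p-value to the star convention used in the figures."""
    if np.isnan(p):
        return "n.s."
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    label_x: str
    label_y: str
    median_x: float
    median_y: float
    u_statistic: float
    pvalue: float
    stars: str


@dataclass(frozen=True)
class NotchedSummary:
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float
    n: int


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is <= 12 and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two nonempty samples")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= _EXACT_MWU_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return GroupComparison(
        label_x,
        label_y,
        float(np.median(x)),
        float(np.median(y)),
        float(res.statistic),
        p,
        significance_stars(p),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_rho requires equal-length samples of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return (float("nan"), float("nan"))
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def hypergeometric_overlap(k: int, n_a: int, n_b: int, universe: int) -> float:
    """P(overlap >= k) for two gene sets of sizes n_a, n_b drawn from a
    universe of ``universe`` genes, computed in log space via the survival
    function of the hypergeometric distribution."""
    if not (0 <= k <= min(n_a, n_b) and max(n_a, n_b) <= universe):
        raise ValueError(f"inconsistent overlap sizes k={k}, nA={n_a}, nB={n_b}, N={universe}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, universe, n_a, n_b))


def notched_summary(values: Sequence[float]) -> NotchedSummary:
    """Median, type-7 quartiles and the 95% median notch (1.58·IQR/√n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("notched_summary requires n >= 2")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # numpy default is type-7
    half = 1.58 * (q3 - q1) / np.sqrt(v.size)
    return NotchedSummary(float(med), float(q1), float(q3), float(med - half), float(med + half), int(v.size))


def make_bins(
    values: Sequence[float],
    mode: str,
    k: int,
    order_key: Sequence[float] | None = None,
) -> np.ndarray:
    """Assign items to ordered bins.

    mode="quantile": k near-equal bins by rank of ``values`` (stable ties).
    mode="fixed_size": ceil(n/k) bins of size k, remainder in the last bin,
    items ordered by ``order_key`` (default: ``values``), again stable.
    Returns an integer bin id per input item, bin 0 first in the ordering.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("make_bins requires nonempty values")
    if k < 1:
        raise ValueError("bin parameter must be >= 1")
    key = v if order_key is None else np.asarray(order_key, dtype=float)
    if key.size != v.size:
        raise ValueError("order_key length mismatch")
    order = np.argsort(key, kind="stable")
    bins = np.empty(v.size, dtype=int)
    if mode == "quantile":
        # split ranks into k contiguous chunks whose sizes differ by <= 1
        for b, chunk in enumerate(np.array_split(order, k)):
            bins[chunk] = b
    elif mode == "fixed_size":
        bins[order] = np.arange(v.size) // k
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return bins


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, NaN-tolerant."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
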