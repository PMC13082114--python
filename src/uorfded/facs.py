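"""FACS-uORF MPRA quantification.

In a FACS-uORF experiment, yeast carrying a pooled library of YFP reporters —
each 5'UTR present once with its native uORF (variant WT) and once with the
uORF start codon mutated to a dead AAG (variant MUT) — are flow-sorted into
eight bins of increasing YFP/mCherry fluorescence and each bin is sequenced.
A reporter's expression is summarised as the read-weighted mean of the bin
values; by default bin values are the indices 1..8 (monotone in fluorescence,
which is all the rank statistics need), optionally replaced by
fluorescence-valued bin means for quantitative work.

Per uORF and replicate, the WT and MUT bin-count vectors are compared with a
Wilcoxon rank-sum test computed directly on the binned reads; per-replicate
p-values are BH-adjusted across the library and a uORF is called
"consistently significantly repressive" (CSR) when every replicate is
significant at FDR < 0.05 with the same direction.  The uORF effect is the
+uORF/−uORF expression ratio (< 1 = repression), and the ded1/DED1 ratio of
uORF effects classifies each uORF as Ded1-suppressed (ratio < 1/1.33),
Ded1-enhanced (> 1.33) or neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import bh_adjust, mann_whitney_u  # bh_adjust re-exported here

__all__ = [
    "FacsBinMatrix",
    "estimate_reporter_expression",
    "wrt_compare",
    "bh_adjust",
    "call_csr",
    "uorf_effect",
    "effect_ratio",
    "summarize_library",
    "read_bin_tsv",
    "N_BINS",
]

N_BINS = 8
DEFAULT_BIN_VALUES = np.arange(1, N_BINS + 1, dtype=float)

#: Per-reporter, per-replicate read cap; larger vectors are proportionally
#: downsampled before rank testing so the z-statistic is not driven by
#: sequencing depth alone.  Expression estimates are scale-invariant so the
#: cap never changes point estimates.
DEFAULT_READ_CAP = 10_000


@dataclass
class FacsBinMatrix:
    """Reporter x 8-bin read counts for one (strain, replicate) sort.

    ``counts`` is indexed by (gene, uorf_id, variant) with variant "WT"
    (uORF present) or "MUT" (start codon killed); columns bin1..bin8.
    ``bin_values`` are strictly increasing scores assigned to the bins.
    """

    strain: str
    replicate: int
    counts: pd.DataFrame
    bin_values: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_VALUES.copy())

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.counts.shape[1] != N_BINS or self.bin_values.size != N_BINS:
            raise ValueError("FACS matrices must have exactly 8 bins")
        if not np.all(np.diff(self.bin_values) > 0):
            raise ValueError("bin_values must be strictly increasing")


def estimate_reporter_expression(
    counts: Sequence[float],
    bin_values: Sequence[float] = DEFAULT_BIN_VALUES,
    min_reads: int = 20,
) -> float:
    """Expression of one reporter: count-weighted mean of the bin values.

    Returns NaN when total reads fall below ``min_reads``.  Invariant to
    rescaling all counts by a common factor.
    """
    c = np.asarray(counts, dtype=float)
    v = np.asarray(bin_values, dtype=float)
    total = c.sum()
    if total < min_reads:
        return float("nan")
    return float(np.dot(c, v) / total)


def _downsample(counts: np.ndarray, cap: int) -> np.ndarray:
    total = counts.sum()
    if total <= cap:
        return counts
    scaled = counts * (cap / total)
    floored = np.floor(scaled)
    # distribute the remainder to the largest fractional parts (deterministic)
    remainder = int(round(cap - floored.sum()))
    if remainder > 0:
        order = np.argsort(-(scaled - floored), kind="stable")
        floored[order[:remainder]] += 1
    return floored


def wrt_compare(
    wt_counts: Sequence[float],
    mut_counts: Sequence[float],
    bin_values: Sequence[float] = DEFAULT_BIN_VALUES,
    min_reads: int = 20,
    read_cap: int = DEFAULT_READ_CAP,
) -> tuple[float, int]:
    """Wilcoxon rank-sum test between the WT and MUT binned read populations.

    Each read is an observation at its bin value; with only 8 distinct
    values the test reduces to closed-form midrank arithmetic on the two
    count vectors (tie-corrected normal approximation, continuity
    correction), so no expansion is ever materialised.

    Returns (two-sided p, direction) with direction = sign(mean MUT - mean
    WT): +1 means the start-codon mutant is expressed higher, i.e. the uORF
    is repressive.  Degenerate comparisons (all mass in one shared bin, or
    either total below ``min_reads``) give (NaN-or-1, 0): under-read inputs
    return (nan, 0); a shared point mass returns (1.0, 0).
    """
    w = np.asarray(wt_counts, dtype=float)
    m = np.asarray(mut_counts, dtype=float)
    if w.sum() < min_reads or m.sum() < min_reads:
        return (float("nan"), 0)
    w = _downsample(w, read_cap)
    m = _downsample(m, read_cap)
    v = np.asarray(bin_values, dtype=float)
    n_w, n_m = w.sum(), m.sum()
    pooled = w + m
    n = n_w + n_m
    mean_w = float(np.dot(w, v) / n_w)
    mean_m = float(np.dot(m, v) / n_m)
    direction = int(np.sign(mean_m - mean_w))
    # midranks per bin from pooled counts
    cum = np.concatenate([[0.0], np.cumsum(pooled)])[:-1]
    midranks = cum + (pooled + 1) / 2.0
    rank_sum_w = float(np.dot(w, midranks))
    u_w = rank_sum_w - n_w * (n_w + 1) / 2.0
    mu = n_w * n_m / 2.0
    tie_term = float(np.sum(pooled**3 - pooled))
    var = n_w * n_m / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return (1.0, 0)
    z = (abs(u_w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(math.erfc(z / math.sqrt(2.0)))  # two-sided
    return (min(p, 1.0), direction)


def call_csr(
    qvalues: Sequence[float],
    directions: Sequence[int],
    alpha: float = 0.05,
    min_replicates: int = 2,
) -> tuple[bool, str]:
    """CSR call from per-replicate (q-value, direction) pairs.

    CSR requires every replicate with data to be significant at FDR<alpha
    with an identical non-zero direction, and at least ``min_replicates``
    replicates with data.  Returns (csr, direction) with direction
    "repressive" (MUT expressed higher), "enhancing" or "none".
    """
    q = np.asarray(qvalues, dtype=float)
    d = np.asarray(directions, dtype=int)
    present = ~np.isnan(q)
    if present.sum() < min_replicates:
        return (False, "none")
    q, d = q[present], d[present]
    if np.all(q < alpha) and np.all(d == d[0]) and d[0] != 0:
        return (True, "repressive" if d[0] > 0 else "enhancing")
    return (False, "none")


def uorf_effect(expr_with_uorf: float, expr_without_uorf: float) -> float:
    """uORF effect: expression with the uORF over expression without it.

    Values < 1 indicate repression by the uORF.  NaN for nonpositive or
    missing inputs.
    """
    if not (expr_with_uorf > 0 and expr_without_uorf > 0):
        return float("nan")
    return expr_with_uorf / expr_without_uorf


def effect_ratio(
    effect_mut_strain: float,
    effect_wt_strain: float,
    fold_threshold: float = 1.33,
) -> tuple[float, str]:
    """ded1/DED1 ratio of uORF effects and the Ded1-modulation class.

    ratio < 1/fold_threshold: the uORF is more inhibitory when Ded1 is
    impaired ("ded1_suppressed" — Ded1 normally suppresses the uORF, the
    START-model prediction); ratio > fold_threshold: "ded1_enhanced";
    otherwise "neutral".
    """
    if not (effect_mut_strain > 0 and effect_wt_strain > 0):
        return (float("nan"), "none")
    ratio = effect_mut_strain / effect_wt_strain
    if ratio < 1.0 / fold_threshold:
        return (ratio, "ded1_suppressed")
    if ratio > fold_threshold:
        return (ratio, "ded1_enhanced")
    return (ratio, "neutral")


def _replicate_calls(
    matrices: Sequence[FacsBinMatrix],
    uorf_index: pd.MultiIndex,
    alpha: float,
    min_reads: int,
    read_cap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate q-values and directions for one strain.

    Returns arrays shaped (n_uorfs, n_replicates); BH adjustment is applied
    within each replicate across the whole library.
    """
    n_u = len(uorf_index)
    qv = np.full((n_u, len(matrices)), np.nan)
    dv = np.zeros((n_u, len(matrices)), dtype=int)
    for j, mat in enumerate(matrices):
        pvals = np.full(n_u, np.nan)
        for i, (gene, uorf_id) in enumerate(uorf_index):
            try:
                wt = mat.counts.loc[(gene, uorf_id, "WT")].to_numpy(dtype=float)
                mut = mat.counts.loc[(gene, uorf_id, "MUT")].to_numpy(dtype=float)
            except KeyError:
                continue
            p, d = wrt_compare(wt, mut, mat.bin_values, min_reads, read_cap)
            pvals[i] = p
            dv[i, j] = d
        qv[:, j] = bh_adjust(pvals)
    return qv, dv


def summarize_library(
    matrices: Iterable[FacsBinMatrix],
    wt_strain: str = "DED1",
    mut_strain: str = "ded1-cs",
    alpha: float = 0.05,
    fold_threshold: float = 1.33,
    min_reads: int = 20,
    read_cap: int = DEFAULT_READ_CAP,
) -> tuple[pd.DataFrame, dict]:
    """Full per-uORF analysis of a two-strain FACS-uORF library.

    For every paired (WT, MUT) reporter: replicate-level rank-sum tests and
    CSR calls per strain; replicate-pooled expression estimates per variant
    and strain; strain-specific uORF effects; the ded1/DED1 effect ratio and
    its modulation class.  Unpaired reporters are excluded and tallied.

    Returns (per-uORF table, cohort summary dict).  The cohort summary
    reports median effects and ratios for the subsets mirrored from the
    study design: uORFs CSR in either strain with full data in both, and
    uORFs CSR in the mutant strain with data in both.
    """
    by_strain: dict[str, list[FacsBinMatrix]] = {}
    for mat in matrices:
        by_strain.setdefault(mat.strain, []).append(mat)
    for strain, mats in by_strain.items():
        mats.sort(key=lambda m: m.replicate)
    if wt_strain not in by_strain or mut_strain not in by_strain:
        raise ValueError(f"need matrices for both strains {wt_strain!r} and {mut_strain!r}")

    # pairing: uORFs with both variants present in at least one matrix
    keys: set[tuple[str, str]] = set()
    unpaired = 0
    all_rows: set[tuple[str, str, str]] = set()
    for mats in by_strain.values():
        for mat in mats:
            all_rows.update(mat.counts.index)
    seen_pairs = {(g, u) for g, u, v in all_rows}
    for gene, uorf_id in seen_pairs:
        if (gene, uorf_id, "WT") in all_rows and (gene, uorf_id, "MUT") in all_rows:
            keys.add((gene, uorf_id))
        else:
            unpaired += 1
    uorf_index = pd.MultiIndex.from_tuples(sorted(keys), names=["gene", "uorf_id"])

    records = []
    calls = {}
    for strain in (wt_strain, mut_strain):
        calls[strain] = _replicate_calls(by_strain[strain], uorf_index, alpha, min_reads, read_cap)

    # replicate-pooled expression estimates (counts summed across replicates)
    pooled: dict[tuple[str, str], pd.DataFrame] = {}
    for strain in (wt_strain, mut_strain):
        summed = None
        for mat in by_strain[strain]:
            summed = mat.counts if summed is None else summed.add(mat.counts, fill_value=0)
        pooled[strain] = summed
    bin_values = {s: by_strain[s][0].bin_values for s in (wt_strain, mut_strain)}

    for i, (gene, uorf_id) in enumerate(uorf_index):
        row: dict = {"gene": gene, "uorf_id": uorf_id}
        effects = {}
        for strain in (wt_strain, mut_strain):
            qv, dv = calls[strain]
            csr, direction = call_csr(qv[i], dv[i], alpha=alpha)
            tag = "wt" if strain == wt_strain else "mut"
            row[f"csr_{tag}_strain"] = csr
            row[f"direction_{tag}_strain"] = direction
            row[f"n_sig_reps_{tag}_strain"] = int(np.nansum(qv[i] < alpha))
            expr = {}
            for variant in ("WT", "MUT"):
                try:
                    c = pooled[strain].loc[(gene, uorf_id, variant)].to_numpy(dtype=float)
                    expr[variant] = estimate_reporter_expression(c, bin_values[strain], min_reads)
                except KeyError:
                    expr[variant] = float("nan")
            row[f"expr_with_uorf_{tag}_strain"] = expr["WT"]
            row[f"expr_without_uorf_{tag}_strain"] = expr["MUT"]
            effects[strain] = uorf_effect(expr["WT"], expr["MUT"])
            row[f"effect_{tag}_strain"] = effects[strain]
        ratio, modulation = effect_ratio(effects[mut_strain], effects[wt_strain], fold_threshold)
        row["effect_ratio"] = ratio
        row["modulation"] = modulation
        records.append(row)

    table = pd.DataFrame.from_records(records)
    if len(table):
        table = table.set_index(["gene", "uorf_id"])

    summary: dict = {"n_uorfs": len(table), "n_unpaired_excluded": unpaired}
    if len(table):
        full = table[np.isfinite(table["effect_ratio"])]
        csr_either = full[(full["csr_wt_strain"]) | (full["csr_mut_strain"])]
        csr_mut = full[full["csr_mut_strain"]]
        summary["n_csr_wt_strain"] = int(table["csr_wt_strain"].sum())
        summary["n_csr_mut_strain"] = int(table["csr_mut_strain"].sum())
        summary["median_effect_wt_strain"] = float(np.nanmedian(table["effect_wt_strain"]))
        summary["median_effect_mut_strain"] = float(np.nanmedian(table["effect_mut_strain"]))
        summary["median_effect_ratio"] = float(np.nanmedian(table["effect_ratio"]))
        for name, sub in (("csr_either", csr_either), ("csr_mut_strain", csr_mut)):
            summary[f"n_{name}"] = len(sub)
            if len(sub):
                summary[f"median_effect_ratio_{name}"] = float(np.nanmedian(sub["effect_ratio"]))
        ok = np.isfinite(table["effect_wt_strain"]) & np.isfinite(table["effect_mut_strain"])
        if ok.sum() >= 2:
            cmp = mann_whitney_u(
                np.log2(table.loc[ok, "effect_wt_strain"]),
                np.log2(table.loc[ok, "effect_mut_strain"]),
                wt_strain,
                mut_strain,
            )
            summary["effect_mwu_p"] = cmp.pvalue
            summary["effect_mwu_stars"] = cmp.stars
    return table, summary


def read_bin_tsv(path) -> list[FacsBinMatrix]:
    """Read FACS bin matrices from TSV with columns strain, replicate, gene,
    uorf_id, variant, bin1..bin8."""
    df = pd.read_csv(path, sep="\t")
    bin_cols = [f"bin{i}" for i in range(1, N_BINS + 1)]
    required = ["strain", "replicate", "gene", "uorf_id", "variant"] + bin_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"bin table missing columns {missing}")
    out = []
    for (strain, rep), sub in df.groupby(["strain", "replicate"]):
        counts = sub.set_index(["gene", "uorf_id", "variant"])[bin_cols]
        out.append(FacsBinMatrix(str(strain), int(rep), counts))
    return out
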