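"""PARS-based secondary-structure scores over 5'UTRs and uORF-proximal windows.

PARS assigns one score per transcript nucleotide, higher meaning more
double-stranded.  Three summaries are computed here: cumulative scores over
fixed windows downstream of a uORF start codon (offsets 16-30, 16-45 or
16-60 from the +1 nucleotide, the A of the start codon, both ends
inclusive); the total score over a 5'UTR; and Max30, the maximum 30-nt
sliding-window sum within a 5'UTR, a length-independent proxy for local
structure.

Profiles may have missing positions (NaN).  Missing values are imputed as 0
for sums and the covered fraction is reported alongside every score; window
scores with coverage below a threshold come back as NaN.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .annotation import Span

__all__ = ["WindowScore", "window_score", "max30", "total_utr_score", "read_pars_tsv"]


class WindowScore(NamedTuple):
    score: float
    coverage: float


def window_score(
    profile: np.ndarray,
    anchor: int,
    window: tuple[int, int] = (16, 45),
    min_coverage: float = 0.8,
) -> WindowScore:
    """Cumulative PARS score in a fixed window downstream of a uORF start.

    ``anchor`` is the 0-based position of the first nucleotide of the start
    codon (the +1 nucleotide); ``window=(a, b)`` covers 1-based offsets
    a..b inclusive, i.e. 0-based positions anchor+a-1 .. anchor+b-1.  NaNs
    are imputed as 0; if the covered fraction falls below ``min_coverage``
    or the window extends past either transcript end the score is NaN.
    """
    a, b = window
    if b < a:
        raise ValueError(f"invalid window {window}")
    profile = np.asarray(profile, dtype=float)
    lo = anchor + a - 1
    hi = anchor + b  # half-open
    if lo < 0 or hi > profile.size:
        return WindowScore(float("nan"), 0.0)
    sl = profile[lo:hi]
    coverage = float(np.mean(~np.isnan(sl)))
    if coverage < min_coverage:
        return WindowScore(float("nan"), coverage)
    return WindowScore(float(np.nansum(sl)), coverage)


def max30(profile: np.ndarray, utr5: Span, width: int = 30) -> float:
    """Maximum ``width``-nt sliding-window sum of PARS scores inside a 5'UTR.

    If the UTR is shorter than ``width`` the sum over the whole UTR is
    returned.  NaNs count as 0; an entirely missing UTR profile gives NaN.
    """
    profile = np.asarray(profile, dtype=float)
    sl = profile[utr5.start : utr5.end]
    if sl.size == 0:
        raise ValueError("max30 requires a nonempty 5'UTR")
    if np.all(np.isnan(sl)):
        return float("nan")
    filled = np.nan_to_num(sl, nan=0.0)
    if sl.size <= width:
        return float(filled.sum())
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    window_sums = csum[width:] - csum[:-width]
    return float(window_sums.max())


def total_utr_score(profile: np.ndarray, utr5: Span) -> WindowScore:
    """Total PARS score summed across all 5'UTR nucleotides (missing as 0)."""
    profile = np.asarray(profile, dtype=float)
    sl = profile[utr5.start : utr5.end]
    if sl.size == 0:
        raise ValueError("total_utr_score requires a nonempty 5'UTR")
    coverage = float(np.mean(~np.isnan(sl)))
    return WindowScore(float(np.nansum(sl)), coverage)


def read_pars_tsv(path, transcript_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read per-nucleotide PARS scores from TSV (transcript_id, position,
    score; 0-based positions).  Unlisted positions are NaN (missing)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["transcript_id", "position", "score"], header=0)
    profiles = {
        tid: np.full(length, np.nan) for tid, length in transcript_lengths.items()
    }
    for tid, sub in df.groupby("transcript_id"):
        if tid not in profiles:
            raise KeyError(f"PARS table references unknown transcript {tid!r}")
        pos = sub["position"].to_numpy(dtype=int)
        if (pos < 0).any() or (pos >= profiles[tid].size).any():
            raise ValueError(f"PARS positions out of range for {tid}")
        profiles[tid][pos] = sub["score"].to_numpy(dtype=float)
    return profiles
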