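"""Feature-level Ribo-Seq quantification and differential translational efficiency.

The experiment compared here is two genotypes (WT *DED1* vs. a *ded1*
mutant) x two assays (ribosome-protected fragments, RPF, and mRNA-Seq) x two
biological replicates.  Footprints arrive as per-nucleotide P-site tracks;
counting into transcript features applies the exclusion rules of the source
protocol — the first and last nucleotide triplets of 5'UTRs and the first 20
codons of mORFs are skipped for RPF counting, while mRNA counting uses full
spans.  Translational efficiency (TE) of a 5'UTR or uORF is its RPF count
normalized to the mRNA count of the host transcript's mORF; mORF TE is mORF
RPF over mORF mRNA.

Differential TE between genotypes is tested per feature with a
negative-binomial GLM on raw counts, design ``assay + genotype +
assay:genotype`` with log size-factor offsets: the interaction coefficient
is the log2 TE change in the mutant (log2ΔTE).  Dispersions are
method-of-moments estimates shrunk halfway toward a 1/mean trend fitted
across features, and Wald statistics are referred to a t distribution with
the residual degrees of freedom.  BH adjustment runs separately within the
mORF family and the uORF/5'UTR family, matching the distinct FDR thresholds
applied to each.

The center of ribosome density (CRD) is the first transcript position at
which half the footprint reads have been passed; its between-genotype shift
ΔCRD (mutant minus WT, averaged over replicates, normalized to transcript
length) is negative when footprints move 5'-ward in the mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .annotation import Span, TranscriptModel, UORFCompilation, UORFRecord
from .stats import bh_adjust

__all__ = [
    "SampleMeta",
    "FeatureCountTable",
    "assign_psites",
    "count_features",
    "size_factors",
    "compute_te",
    "filter_features",
    "differential_te",
    "classify_dependence",
    "compute_crd",
    "delta_crd",
    "metagene_profile",
    "feature_id",
    "host_transcript",
]

UTR5_EDGE_EXCLUSION = 3  # nt trimmed from each end of the 5'UTR (RPF only)
MORF_START_EXCLUSION_CODONS = 20  # leading mORF codons excluded (RPF only)


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: genotype WT/MUT, assay RPF/MRNA, replicate."""

    sample_id: str
    genotype: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "MUT"):
            raise ValueError(f"genotype must be WT or MUT, got {self.genotype!r}")
        if self.assay not in ("RPF", "MRNA"):
            raise ValueError(f"assay must be RPF or MRNA, got {self.assay!r}")


class FeatureCountTable:
    """Integer counts per feature per sample with sample metadata.

    ``counts`` is a DataFrame indexed by feature_id with one column per
    sample; ``meta`` maps sample_id to :class:`SampleMeta`.  Feature ids are
    ``<transcript>:utr5|morf|utr3`` for transcript features and the uORF id
    for uORFs.
    """

    def __init__(self, counts: pd.DataFrame, meta: Mapping[str, SampleMeta]):
        missing = [c for c in counts.columns if c not in meta]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        seen = set()
        for m in meta.values():
            key = (m.genotype, m.assay, m.replicate)
            if key in seen:
                raise ValueError(f"duplicate sample design cell {key}")
            seen.add(key)
        self.counts = counts
        self.meta = dict(meta)

    def samples(self, assay: str | None = None, genotype: str | None = None) -> list[str]:
        out = []
        for sid in self.counts.columns:
            m = self.meta[sid]
            if assay is not None and m.assay != assay:
                continue
            if genotype is not None and m.genotype != genotype:
                continue
            out.append(sid)
        return out

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        pd.DataFrame(
            [
                {"sample_id": m.sample_id, "genotype": m.genotype, "assay": m.assay, "replicate": m.replicate}
                for m in self.meta.values()
            ]
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "FeatureCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        meta = {
            r.sample_id: SampleMeta(r.sample_id, r.genotype, r.assay, int(r.replicate))
            for r in sheet.itertuples()
        }
        return cls(counts, meta)


def feature_id(transcript_id: str, kind: str) -> str:
    return f"{transcript_id}:{kind}"


def host_transcript(fid: str, uorf_hosts: Mapping[str, str]) -> str:
    """Transcript owning a feature id (transcript features or uORF ids)."""
    if fid in uorf_hosts:
        return uorf_hosts[fid]
    tid, sep, kind = fid.rpartition(":")
    if sep and kind in ("utr5", "morf", "utr3"):
        return tid
    raise KeyError(f"cannot resolve host transcript of feature {fid!r}")


def assign_psites(
    reads: Iterable[tuple[int, int]],
    transcript_length: int,
    offsets: Mapping[int, int],
    default_offset: int | None = None,
) -> tuple[np.ndarray, int]:
    """Convert (5'-end position, read length) pairs into a P-site track.

    The P-site of a read is its 5' position plus a length-specific offset.
    Reads whose P-site falls outside the transcript are dropped and tallied.
    A read length with no configured offset raises unless ``default_offset``
    is given.
    """
    track = np.zeros(transcript_length, dtype=np.int64)
    dropped = 0
    for pos, length in reads:
        if length in offsets:
            off = offsets[length]
        elif default_offset is not None:
            off = default_offset
        else:
            raise KeyError(f"no P-site offset configured for read length {length}")
        p = pos + off
        if 0 <= p < transcript_length:
            track[p] += 1
        else:
            dropped += 1
    return track, dropped


def _rpf_spans(tm: TranscriptModel) -> dict[str, Span]:
    """Feature spans with the RPF-counting exclusion zones applied."""
    u5 = tm.utr5
    if len(u5) < 2 * UTR5_EDGE_EXCLUSION:
        u5_counted = Span(u5.start, u5.start)  # degenerate: counts as 0
    else:
        u5_counted = Span(u5.start + UTR5_EDGE_EXCLUSION, u5.end - UTR5_EDGE_EXCLUSION)
    skip = 3 * MORF_START_EXCLUSION_CODONS
    morf_counted = Span(min(tm.morf.start + skip, tm.morf.end), tm.morf.end)
    return {"utr5": u5_counted, "morf": morf_counted, "utr3": tm.utr3}


def count_features(
    track: np.ndarray,
    tm: TranscriptModel,
    uorfs: Sequence[UORFRecord] = (),
    assay: str = "RPF",
) -> dict[str, int]:
    """Sum a per-nucleotide track into feature counts.

    RPF counting excludes the first/last 5'UTR triplets and the first 20
    mORF codons; uORF and 3'UTR spans are summed in full.  mRNA counting
    uses full spans for every feature.  A 5'UTR too short to survive its
    exclusions is counted as 0 with a warning.
    """
    track = np.asarray(track)
    if track.size != tm.length:
        raise ValueError(f"track length {track.size} != transcript length {tm.length} ({tm.transcript_id})")
    if assay == "RPF":
        spans = _rpf_spans(tm)
        if len(tm.utr5) < 2 * UTR5_EDGE_EXCLUSION and len(tm.utr5) > 0:
            warnings.warn(
                f"{tm.transcript_id}: 5'UTR shorter than {2 * UTR5_EDGE_EXCLUSION} nt; RPF count set to 0",
                stacklevel=2,
            )
    elif assay == "MRNA":
        spans = {"utr5": tm.utr5, "morf": tm.morf, "utr3": tm.utr3}
    else:
        raise ValueError(f"unknown assay {assay!r}")
    out = {
        feature_id(tm.transcript_id, kind): int(track[s.start : s.end].sum())
        for kind, s in spans.items()
    }
    for rec in uorfs:
        out[rec.uorf_id] = int(track[rec.span.start : rec.span.end].sum())
    return out


def size_factors(table: FeatureCountTable, assay: str) -> pd.Series:
    """Median-of-ratios size factors within one assay, over mORF rows.

    Rows with any zero count are dropped (as in the standard estimator);
    factors are rescaled to geometric mean 1 within the assay.  If no
    all-positive mORF row exists, total-count scaling is used with a
    warning.
    """
    samples = table.samples(assay=assay)
    if not samples:
        raise ValueError(f"no samples with assay {assay!r}")
    morf_rows = [f for f in table.counts.index if f.endswith(":morf")]
    sub = table.counts.loc[morf_rows, samples].to_numpy(dtype=float)
    positive = (sub > 0).all(axis=1)
    if positive.any():
        logs = np.log(sub[positive])
        log_geo = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geo, axis=0))
    else:
        warnings.warn(f"no all-positive mORF row for assay {assay}; using total-count scaling", stacklevel=2)
        totals = table.counts[samples].to_numpy(dtype=float).sum(axis=0)
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples)


def _all_size_factors(table: FeatureCountTable) -> pd.Series:
    parts = [size_factors(table, assay) for assay in ("RPF", "MRNA") if table.samples(assay=assay)]
    return pd.concat(parts).reindex(table.counts.columns)


def compute_te(
    table: FeatureCountTable,
    uorf_hosts: Mapping[str, str],
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature relative TE point estimates per genotype.

    TE(feature, genotype) is the geometric mean over replicates of
    (normalized feature RPF + pc) / (normalized host-mORF mRNA + pc); for
    mORF features numerator and denominator both refer to the mORF.
    Replicates are paired by replicate number across assays.  Returns
    columns te_wt, te_mut and log2_te_ratio (mut/wt).
    """
    if factors is None:
        factors = _all_size_factors(table)
    norm = table.counts.div(factors, axis=1)
    result = {}
    for genotype, col in (("WT", "te_wt"), ("MUT", "te_mut")):
        rpf_by_rep = {table.meta[s].replicate: s for s in table.samples("RPF", genotype)}
        mrna_by_rep = {table.meta[s].replicate: s for s in table.samples("MRNA", genotype)}
        reps = sorted(set(rpf_by_rep) & set(mrna_by_rep))
        if not reps:
            raise ValueError(f"no paired RPF/mRNA replicates for genotype {genotype}")
        log_ratios = np.zeros(len(table.counts.index))
        for rep in reps:
            num = norm[rpf_by_rep[rep]].to_numpy(dtype=float) + pseudocount
            hosts = [host_transcript(f, uorf_hosts) for f in table.counts.index]
            denom_rows = [feature_id(t, "morf") for t in hosts]
            den = norm.loc[denom_rows, mrna_by_rep[rep]].to_numpy(dtype=float) + pseudocount
            log_ratios = log_ratios + np.log(num / den)
        result[col] = np.exp(log_ratios / len(reps))
    df = pd.DataFrame(result, index=table.counts.index)
    df["log2_te_ratio"] = np.log2(df["te_mut"] / df["te_wt"])
    return df


def filter_features(
    table: FeatureCountTable,
    uorf_hosts: Mapping[str, str],
    min_morf_mrna: int = 128,
    min_uorf_rpf: int = 8,
) -> set[str]:
    """Features retained for TE analysis.

    A feature survives iff its host transcript's mORF has >= ``min_morf_mrna``
    total mRNA reads summed over all samples; uORF and 5'UTR features must
    additionally carry >= ``min_uorf_rpf`` total RPF reads themselves.
    """
    mrna_samples = table.samples(assay="MRNA")
    rpf_samples = table.samples(assay="RPF")
    mrna_totals = table.counts[mrna_samples].sum(axis=1)
    rpf_totals = table.counts[rpf_samples].sum(axis=1)
    retained = set()
    for fid in table.counts.index:
        host = host_transcript(fid, uorf_hosts)
        morf_fid = feature_id(host, "morf")
        if morf_fid not in mrna_totals.index or mrna_totals[morf_fid] < min_morf_mrna:
            continue
        is_uorf_like = fid in uorf_hosts or fid.endswith(":utr5")
        if is_uorf_like and rpf_totals.get(fid, 0) < min_uorf_rpf:
            continue
        retained.add(fid)
    return retained


def _design_matrix(metas: Sequence[SampleMeta]) -> np.ndarray:
    X = np.ones((len(metas), 4))
    for i, m in enumerate(metas):
        X[i, 1] = 1.0 if m.assay == "RPF" else 0.0
        X[i, 2] = 1.0 if m.genotype == "MUT" else 0.0
        X[i, 3] = X[i, 1] * X[i, 2]
    return X


def _moderated_dispersions(y: np.ndarray, sf: np.ndarray, cells: np.ndarray, weight: float = 0.5) -> np.ndarray:
    """Per-feature NB dispersions: method-of-moments shrunk toward a
    a0 + a1/mean trend fitted across features.

    ``cells`` assigns each sample to its design cell; the MoM estimate
    averages (s² − μ)/μ² over cells with positive means.
    """
    q = y / sf  # normalized counts, features x samples
    n_feat = y.shape[0]
    alpha_mom = np.full(n_feat, np.nan)
    means = np.zeros(n_feat)
    for i in range(n_feat):
        alphas = []
        mus = []
        for c in np.unique(cells):
            qc = q[i, cells == c]
            mu = qc.mean()
            if mu <= 0 or qc.size < 2:
                continue
            s2 = qc.var(ddof=1)
            alphas.append((s2 - mu) / mu**2)
            mus.append(mu)
        if alphas:
            alpha_mom[i] = max(np.mean(alphas), 0.0)
            means[i] = np.mean(mus)
    ok = np.isfinite(alpha_mom) & (means > 0)
    if ok.sum() >= 3:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
        coef, *_ = np.linalg.lstsq(A, alpha_mom[ok], rcond=None)
        coef = np.clip(coef, 0.0, None)
        trend = coef[0] + coef[1] / np.maximum(means, 1e-8)
    else:
        trend = np.full(n_feat, np.nanmean(alpha_mom) if ok.any() else 0.1)
    alpha = weight * np.nan_to_num(alpha_mom, nan=0.0) + (1 - weight) * trend
    return np.clip(alpha, 1e-8, 10.0)


def differential_te(
    table: FeatureCountTable,
    features: Iterable[str] | None = None,
    uorf_hosts: Mapping[str, str] | None = None,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Differential TE per feature via an NB GLM with interaction design.

    Counts of one feature across all RPF and mRNA samples are modelled as
    NB with log link, design ``1 + assay + genotype + assay:genotype`` and
    log size-factor offsets; the interaction coefficient (converted to
    log2) is the TE change in the mutant.  Wald p-values use a t reference
    with moderated degrees of freedom: the residual df (n_samples − 4) plus
    the prior df contributed by the dispersion trend, df_resid·(1−w)/w for
    shrink weight w — a plain normal reference is anti-conservative and the
    bare residual df over-conservative at the 2-replicate scale of the
    design.  BH FDR is computed within two families: mORF/3'UTR features
    and uORF/5'UTR features.
    """
    uorf_hosts = uorf_hosts or {}
    if factors is None:
        factors = _all_size_factors(table)
    feats = list(features) if features is not None else list(table.counts.index)
    samples = list(table.counts.columns)
    metas = [table.meta[s] for s in samples]
    X = _design_matrix(metas)
    sf = factors.reindex(samples).to_numpy(dtype=float)
    offset = np.log(sf)
    y = table.counts.loc[feats, samples].to_numpy(dtype=float)
    cells = np.array([f"{m.assay}/{m.genotype}" for m in metas])
    cell_codes = pd.factorize(cells)[0]
    for cell in np.unique(cell_codes):
        if (cell_codes == cell).sum() < 2:
            raise ValueError("differential_te requires >=2 replicates per assay x genotype cell")
    alphas = _moderated_dispersions(y, sf, cell_codes, weight=shrink_weight)
    df_resid = len(samples) - X.shape[1]
    # dispersion moderation adds information: prior df from the trend
    df_test = df_resid + df_resid * (1.0 - shrink_weight) / max(shrink_weight, 1e-6)

    rows = []
    ln2 = np.log(2.0)
    for i, fid in enumerate(feats):
        yi = y[i]
        out = {
            "feature_id": fid,
            "base_mean": float((yi / sf).mean()),
            "log2_dte": np.nan,
            "se_log2": np.nan,
            "pvalue": np.nan,
            "converged": False,
        }
        if yi.sum() > 0:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.GLM(
                        yi, X, family=sm.families.NegativeBinomial(alpha=float(alphas[i])), offset=offset
                    )
                    fit = model.fit(maxiter=100, tol=1e-8)
                beta = fit.params[3]
                se = fit.bse[3]
                if np.isfinite(beta) and np.isfinite(se) and se > 0:
                    tstat = beta / se
                    out.update(
                        log2_dte=float(beta / ln2),
                        se_log2=float(se / ln2),
                        pvalue=float(2.0 * sps.t.sf(abs(tstat), df_test)),
                        converged=bool(fit.converged),
                    )
            except Exception:
                pass  # reported as non-converged with NA p-value
        rows.append(out)
    res = pd.DataFrame(rows).set_index("feature_id")

    family = pd.Series(
        ["uorf_utr5" if (f in uorf_hosts or f.endswith(":utr5")) else "morf" for f in res.index],
        index=res.index,
    )
    res["family"] = family
    res["fdr"] = np.nan
    for fam in family.unique():
        mask = family == fam
        res.loc[mask, "fdr"] = bh_adjust(res.loc[mask, "pvalue"].to_numpy())
    return res


def classify_dependence(
    results: pd.DataFrame,
    fold_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """Classify features as HYPER (TE down in the mutant at the fold/FDR
    cut), HYPO (TE up) or UNCHANGED.  Defaults follow the mORF criteria
    (1.5-fold, FDR<0.05); uORF analyses use (2.0, 0.01)."""
    cut = np.log2(fold_threshold)
    lfc = results["log2_dte"]
    fdr = results["fdr"]
    cls = pd.Series("UNCHANGED", index=results.index)
    cls[(lfc <= -cut) & (fdr < fdr_threshold)] = "HYPER"
    cls[(lfc >= cut) & (fdr < fdr_threshold)] = "HYPO"
    cls[lfc.isna() | fdr.isna()] = "FILTERED"
    return cls


def compute_crd(track: np.ndarray) -> float:
    """Center of ribosome density: the smallest 0-based position whose
    cumulative footprint count reaches half the track total.  NaN for an
    empty track."""
    track = np.asarray(track, dtype=float)
    total = track.sum()
    if total <= 0:
        return float("nan")
    csum = np.cumsum(track)
    return float(np.searchsorted(csum, total / 2.0, side="left"))


def delta_crd(
    crd_mut_reps: Sequence[float],
    crd_wt_reps: Sequence[float],
    length: int,
    normalize: bool = True,
) -> float:
    """ΔCRD: mean mutant CRD minus mean WT CRD, normalized to transcript
    length.  Negative values indicate a 5'-ward footprint shift in the
    mutant.  NaN if any replicate CRD is undefined."""
    mut = np.asarray(crd_mut_reps, dtype=float)
    wt = np.asarray(crd_wt_reps, dtype=float)
    if mut.size == 0 or wt.size == 0 or np.isnan(mut).any() or np.isnan(wt).any():
        return float("nan")
    delta = mut.mean() - wt.mean()
    return float(delta / length) if normalize else float(delta)


def metagene_profile(
    tracks: Mapping[str, np.ndarray],
    transcripts: Mapping[str, TranscriptModel],
    window: tuple[int, int] = (-48, 99),
    min_reads: int = 32,
    anchor: str = "morf_start",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized footprint density around the mORF start codon.

    Each qualifying transcript (>= ``min_reads`` in the window and fully
    spanning it) contributes its windowed density divided by its own mean
    density in the window; the profile is the position-wise mean across
    transcripts.  Returns (positions relative to the anchor, profile).
    """
    if anchor != "morf_start":
        raise ValueError(f"unsupported anchor {anchor!r}")
    lo, hi = window
    if hi < lo:
        raise ValueError(f"invalid window {window}")
    positions = np.arange(lo, hi + 1)
    acc = []
    for tid, track in tracks.items():
        tm = transcripts[tid]
        a = tm.morf.start
        if a + lo < 0 or a + hi >= tm.length:
            continue
        seg = np.asarray(track[a + lo : a + hi + 1], dtype=float)
        if seg.sum() < min_reads:
            continue
        acc.append(seg / seg.mean())
    if not acc:
        raise ValueError("no transcripts qualify for the metagene window")
    return positions, np.mean(acc, axis=0)


def read_track_tsv(path, transcript_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read P-site/mRNA tracks from TSV (transcript_id, position, count)."""
    df = pd.read_csv(path, sep="\t")
    tracks = {tid: np.zeros(L, dtype=np.int64) for tid, L in transcript_lengths.items()}
    for tid, sub in df.groupby("transcript_id"):
        if tid not in tracks:
            raise KeyError(f"track references unknown transcript {tid!r}")
        pos = sub["position"].to_numpy(dtype=int)
        tracks[tid][pos] = sub["count"].to_numpy(dtype=np.int64)
    return tracks
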