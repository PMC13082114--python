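"""Synthetic data generators for every pipeline input.

Two experiment emulators live here, matching the study designs the analyses
assume:

* A Ribo-Seq simulator: two genotypes (WT vs. a *ded1*-like mutant) x two
  assays (RPF, mRNA) x two biological replicates over a synthetic yeast-like
  transcriptome with embedded uORFs.  Feature counts are negative-binomial
  around abundance x TE means; genotype effects multiply TEs by planted
  log2 fold changes; P-site positions are placed uniformly within features.
  An optional cycloheximide-style artifact adds a start-codon footprint
  pileup over the first five mORF codons whose magnitude follows transcript
  abundance but not the genotype TE effect — an initiation-site pileup, which
  is what makes it distort the center-of-ribosome-density statistic.

* A FACS-uORF sort-seq simulator: paired WT/dead-start reporters per uORF,
  two strains x three replicates, log-normal single-cell fluorescence, eight
  sort gates at pooled quantiles and multinomial sequencing reads per bin.
  A configurable strain x uORF interaction plants Ded1-suppressed or
  Ded1-enhanced uORF subsets.

Every generator takes a mandatory seed and returns a truth table recording
the planted per-feature parameters, sufficient to score recovery without
re-reading any configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Span, TranscriptModel, UORFCompilation, UORFRecord
from .facs import N_BINS, FacsBinMatrix
from .riboseq import FeatureCountTable, SampleMeta, count_features, feature_id

__all__ = [
    "RiboSimConfig",
    "FacsSimConfig",
    "RiboSimResult",
    "generate_annotation",
    "simulate_riboseq",
    "simulate_pars",
    "simulate_facs",
    "figure4a_scenario",
]


@dataclass
class RiboSimConfig:
    """Parameters of the synthetic Ribo-Seq experiment.

    Lengths are log-normal around yeast-like medians; ``mean_rpf`` /
    ``mean_mrna`` set the expected mORF read count of an average-abundance
    transcript per sample (sequencing depth at desk scale).  Effects:
    ``effect_mode="gaussian"`` draws per-transcript (mORF, uORF) log2 TE
    changes from a correlated bivariate normal; ``"discrete"`` plants fixed
    log2 fold changes on marked fractions; ``"none"`` is a global null.
    """

    seed: int
    n_transcripts: int = 500
    replicates: int = 2
    # transcript architecture (log-normal medians / log-sigmas, nt)
    utr5_median: float = 60.0
    utr5_sigma: float = 0.6
    morf_median_codons: float = 330.0
    morf_sigma: float = 0.45
    utr3_median: float = 120.0
    utr3_sigma: float = 0.5
    # uORF content
    uorf_fraction: float = 0.4
    uorf_mean_extra: float = 0.4  # Poisson mean of uORFs beyond the first
    ncc_fraction: float = 0.5
    # expression model
    abundance_sigma: float = 1.0
    morf_te_sigma: float = 0.25
    uorf_share_median: float = 0.05  # uORF RPF count relative to mORF RPF
    uorf_share_sigma: float = 0.5
    utr5_bg_share: float = 0.01
    utr3_share: float = 0.005
    dispersion: float = 0.1
    mean_rpf: float = 200.0
    mean_mrna: float = 200.0
    libsize_sigma: float = 0.1
    # planted genotype effects
    effect_mode: str = "none"  # none | gaussian | discrete
    sd_morf: float = 1.0
    sd_uorf: float = 1.0
    rho: float = 0.5
    frac_morf_down: float = 0.0
    frac_morf_up: float = 0.0
    morf_log2fc: float = 1.0
    frac_uorf_up: float = 0.0
    frac_uorf_down: float = 0.0
    uorf_log2fc: float = 1.0
    # cycloheximide-style start-codon pileup
    chx_artifact: bool = False
    chx_intensity: float = 10.0  # peak density relative to baseline mORF body
    make_tracks: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for frac in (
            self.uorf_fraction,
            self.frac_morf_down,
            self.frac_morf_up,
            self.frac_uorf_up,
            self.frac_uorf_down,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_morf_down + self.frac_morf_up > 1 or self.frac_uorf_up + self.frac_uorf_down > 1:
            raise ValueError("effect fractions must sum to <= 1 per family")


def _lognormal_int(rng, median: float, sigma: float, lo: int, hi: int, size: int) -> np.ndarray:
    vals = rng.lognormal(math.log(median), sigma, size)
    return np.clip(np.round(vals), lo, hi).astype(int)


def generate_annotation(
    cfg: RiboSimConfig,
) -> tuple[dict[str, TranscriptModel], UORFCompilation, pd.DataFrame]:
    """Generate a synthetic annotated transcriptome with planted parameters.

    Deterministic for a fixed seed.  The truth table has one row per
    transcript (abundance, baseline TE, planted log2 TE changes) plus the
    per-uORF spans and shares encoded in the uORF compilation / truth
    columns.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_transcripts
    utr5_len = _lognormal_int(rng, cfg.utr5_median, cfg.utr5_sigma, 12, 400, n)
    morf_len = 3 * _lognormal_int(rng, cfg.morf_median_codons, cfg.morf_sigma, 100, 2000, n)
    utr3_len = _lognormal_int(rng, cfg.utr3_median, cfg.utr3_sigma, 30, 600, n)

    transcripts: dict[str, TranscriptModel] = {}
    for i in range(n):
        tid = f"T{i:05d}"
        u5, mo, u3 = int(utr5_len[i]), int(morf_len[i]), int(utr3_len[i])
        transcripts[tid] = TranscriptModel(
            tid, u5 + mo + u3, Span(0, u5), Span(u5, u5 + mo), Span(u5 + mo, u5 + mo + u3)
        )

    abundance = rng.lognormal(0.0, cfg.abundance_sigma, n)
    abundance /= abundance.mean()
    morf_te = rng.lognormal(0.0, cfg.morf_te_sigma, n)

    # planted genotype effects (log2 TE change in the mutant)
    morf_fc = np.zeros(n)
    uorf_fc = np.zeros(n)
    if cfg.effect_mode == "gaussian":
        cov = [[1.0, cfg.rho], [cfg.rho, 1.0]]
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        morf_fc = cfg.sd_morf * z[:, 0]
        uorf_fc = cfg.sd_uorf * z[:, 1]
    elif cfg.effect_mode == "discrete":
        order = rng.permutation(n)
        n_dn = int(round(cfg.frac_morf_down * n))
        n_up = int(round(cfg.frac_morf_up * n))
        morf_fc[order[:n_dn]] = -cfg.morf_log2fc
        morf_fc[order[n_dn : n_dn + n_up]] = cfg.morf_log2fc
        order_u = rng.permutation(n)
        n_uu = int(round(cfg.frac_uorf_up * n))
        n_ud = int(round(cfg.frac_uorf_down * n))
        uorf_fc[order_u[:n_uu]] = cfg.uorf_log2fc
        uorf_fc[order_u[n_uu : n_uu + n_ud]] = -cfg.uorf_log2fc
    elif cfg.effect_mode != "none":
        raise ValueError(f"unknown effect_mode {cfg.effect_mode!r}")

    records: list[UORFRecord] = []
    uorf_share: dict[str, float] = {}
    has_uorf = rng.random(n) < cfg.uorf_fraction
    counter = 0
    for i, tid in enumerate(transcripts):
        if not has_uorf[i]:
            continue
        n_uorfs = 1 + rng.poisson(cfg.uorf_mean_extra)
        tm = transcripts[tid]
        u5 = len(tm.utr5)
        taken: set[tuple[int, int]] = set()
        for _ in range(n_uorfs):
            placed = False
            for _attempt in range(100):
                max_codons = (u5 - 3) // 3 - 1  # span + stop codon must fit the UTR
                if max_codons < 2:
                    break
                ncod = int(rng.integers(2, min(max_codons, 10) + 1))
                span_len = 3 * ncod
                start = int(rng.integers(0, u5 - span_len - 3 + 1))
                key = (start, start + span_len)
                if key in taken:
                    continue
                taken.add(key)
                counter += 1
                uid = f"u{counter:05d}"
                start_class = "NCC" if rng.random() < cfg.ncc_fraction else "AUG"
                records.append(
                    UORFRecord(uid, tid, Span(*key), start_class, frozenset({"synthetic"}))
                )
                uorf_share[uid] = float(
                    rng.lognormal(math.log(cfg.uorf_share_median), cfg.uorf_share_sigma)
                )
                placed = True
                break
            if not placed and (u5 - 3) // 3 - 1 >= 2:
                raise ValueError(f"could not place a uORF on {tid} after 100 attempts")

    comp = UORFCompilation(
        tuple(sorted(records, key=UORFRecord.key)), ("synthetic",)
    )
    truth = pd.DataFrame(
        {
            "transcript_id": list(transcripts),
            "abundance": abundance,
            "morf_te": morf_te,
            "morf_log2fc": morf_fc,
            "uorf_log2fc": uorf_fc,
        }
    ).set_index("transcript_id")
    truth.attrs["uorf_share"] = uorf_share
    return transcripts, comp, truth


@dataclass
class RiboSimResult:
    table: FeatureCountTable
    samples: list[SampleMeta]
    rpf_tracks: dict[str, dict[str, np.ndarray]] | None
    mrna_tracks: dict[str, dict[str, np.ndarray]] | None
    truth: pd.DataFrame


def _nb(rng, mean: np.ndarray | float, alpha: float):
    """Negative binomial via gamma-Poisson mixing (dispersion alpha)."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(1.0 / alpha, alpha * np.maximum(mean, 1e-12))
    return rng.poisson(lam)


def _scatter_uniform(rng, track: np.ndarray, span: Span, count: int) -> None:
    if count > 0 and len(span) > 0:
        track[span.start : span.end] += rng.multinomial(count, np.full(len(span), 1.0 / len(span)))


def simulate_riboseq(
    transcripts: Mapping[str, TranscriptModel],
    uorfs: UORFCompilation,
    truth: pd.DataFrame,
    cfg: RiboSimConfig,
) -> RiboSimResult:
    """Draw counts (and optionally position tracks) for the 2x2x2 design.

    With ``make_tracks`` the returned count table is produced by running
    :func:`uorfded.riboseq.count_features` on the generated tracks, so RPF
    exclusion zones apply exactly as in a real analysis; without tracks,
    counts are drawn directly at feature level with full-span semantics.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    samples: list[SampleMeta] = []
    for assay in ("RPF", "MRNA"):
        for genotype in ("WT", "MUT"):
            for rep in range(1, cfg.replicates + 1):
                sid = f"{assay.lower()}_{'wt' if genotype == 'WT' else 'mut'}_{rep}"
                samples.append(SampleMeta(sid, genotype, assay, rep))
    libsize = {s.sample_id: float(rng.lognormal(0.0, cfg.libsize_sigma)) for s in samples}

    uorf_by_tid = uorfs.by_transcript()
    uorf_share: dict[str, float] = truth.attrs.get("uorf_share", {})
    tids = list(transcripts)

    rpf_tracks: dict[str, dict[str, np.ndarray]] | None = {} if cfg.make_tracks else None
    mrna_tracks: dict[str, dict[str, np.ndarray]] | None = {} if cfg.make_tracks else None
    col_counts: dict[str, dict[str, int]] = {}

    for s in samples:
        f = libsize[s.sample_id]
        is_mut = s.genotype == "MUT"
        col: dict[str, int] = {}
        tracks: dict[str, np.ndarray] = {}
        for tid in tids:
            tm = transcripts[tid]
            row = truth.loc[tid]
            ab = row["abundance"]
            recs = uorf_by_tid.get(tid, [])
            if s.assay == "MRNA":
                density = ab * cfg.mean_mrna / len(tm.morf)
                feat_counts = {
                    kind: int(_nb(rng, density * len(getattr(tm, kind)) * f, cfg.dispersion))
                    for kind in ("utr5", "morf", "utr3")
                }
                if cfg.make_tracks:
                    track = np.zeros(tm.length, dtype=np.int64)
                    for kind in ("utr5", "morf", "utr3"):
                        _scatter_uniform(rng, track, getattr(tm, kind), feat_counts[kind])
                    tracks[tid] = track
                for kind in ("utr5", "morf", "utr3"):
                    col[feature_id(tid, kind)] = feat_counts[kind]
                for rec in recs:
                    # mRNA reads over a uORF span, proportional to its length
                    col[rec.uorf_id] = int(_nb(rng, density * len(rec.span) * f, cfg.dispersion))
            else:
                g_morf = 2.0 ** row["morf_log2fc"] if is_mut else 1.0
                g_uorf = 2.0 ** row["uorf_log2fc"] if is_mut else 1.0
                mu_morf = ab * row["morf_te"] * g_morf * cfg.mean_rpf * f
                mu_bg = ab * cfg.utr5_bg_share * g_uorf * cfg.mean_rpf * f
                mu_u3 = ab * cfg.utr3_share * cfg.mean_rpf * f
                c_morf = int(_nb(rng, mu_morf, cfg.dispersion))
                c_bg = int(_nb(rng, mu_bg, cfg.dispersion))
                c_u3 = int(_nb(rng, mu_u3, cfg.dispersion))
                c_uorf = {
                    rec.uorf_id: int(
                        _nb(rng, ab * uorf_share.get(rec.uorf_id, 0.05) * g_uorf * cfg.mean_rpf * f, cfg.dispersion)
                    )
                    for rec in recs
                }
                if cfg.make_tracks:
                    track = np.zeros(tm.length, dtype=np.int64)
                    _scatter_uniform(rng, track, tm.morf, c_morf)
                    _scatter_uniform(rng, track, tm.utr5, c_bg)
                    _scatter_uniform(rng, track, tm.utr3, c_u3)
                    for rec in recs:
                        _scatter_uniform(rng, track, rec.span, c_uorf[rec.uorf_id])
                    if cfg.chx_artifact:
                        # initiation-site pileup: follows abundance and the
                        # genotype-independent baseline TE, not the TE change
                        peak_span = Span(tm.morf.start, min(tm.morf.start + 15, tm.morf.end))
                        mu_peak = (
                            cfg.chx_intensity
                            * ab
                            * row["morf_te"]
                            * cfg.mean_rpf
                            * f
                            * len(peak_span)
                            / len(tm.morf)
                        )
                        _scatter_uniform(rng, track, peak_span, int(_nb(rng, mu_peak, cfg.dispersion)))
                    tracks[tid] = track
                else:
                    col[feature_id(tid, "morf")] = c_morf
                    # full-span 5'UTR counting includes reads on embedded uORFs
                    col[feature_id(tid, "utr5")] = c_bg + sum(c_uorf.values())
                    col[feature_id(tid, "utr3")] = c_u3
                    col.update(c_uorf)
        if cfg.make_tracks:
            for tid in tids:
                col.update(
                    count_features(tracks[tid], transcripts[tid], uorf_by_tid.get(tid, []), assay=s.assay)
                )
            if s.assay == "RPF":
                rpf_tracks[s.sample_id] = tracks
            else:
                mrna_tracks[s.sample_id] = tracks
        col_counts[s.sample_id] = col

    counts = pd.DataFrame(col_counts).fillna(0).astype(np.int64)
    counts = counts[[s.sample_id for s in samples]]
    table = FeatureCountTable(counts, {s.sample_id: s for s in samples})
    return RiboSimResult(table, samples, rpf_tracks, mrna_tracks, truth)


def simulate_pars(
    transcripts: Mapping[str, TranscriptModel],
    uorfs: UORFCompilation,
    planted_uorf_ids: Sequence[str],
    seed: int,
    window: tuple[int, int] = (16, 45),
    block_height: float = 3.0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-nucleotide PARS profiles: N(0,1) background plus planted stems.

    A planted stem adds ``block_height`` per nucleotide over the 1-based
    offsets ``window`` downstream of the +1 nucleotide of each listed uORF.
    The truth table records which uORFs actually received a block (blocks
    that would overrun the transcript are skipped and flagged).
    """
    rng = np.random.default_rng(seed)
    profiles = {tid: rng.normal(0.0, 1.0, tm.length) for tid, tm in transcripts.items()}
    planted = set(planted_uorf_ids)
    rows = []
    for rec in uorfs:
        ok = False
        if rec.uorf_id in planted:
            a, b = window
            lo = rec.span.start + a - 1
            hi = rec.span.start + b
            if 0 <= lo and hi <= transcripts[rec.transcript_id].length:
                profiles[rec.transcript_id][lo:hi] += block_height
                ok = True
        rows.append({"uorf_id": rec.uorf_id, "planted": rec.uorf_id in planted, "applied": ok})
    return profiles, pd.DataFrame(rows).set_index("uorf_id")


@dataclass
class FacsSimConfig:
    """Parameters of the synthetic FACS-uORF sort-seq experiment.

    Cell fluorescence is log10-normal: mean = base x gene offset x strain
    ratio x (uORF effect and strain-interaction terms, WT variant only),
    sd ``sigma_cell``.  Gates are the 8 pooled quantiles of each (strain,
    replicate) sort, so marginal bin occupancy is near-uniform by
    construction.  ``bin_value_mode`` "index" scores bins 1..8;
    "fluorescence" uses the pooled per-bin mean linear fluorescence.
    """

    seed: int
    n_uorfs: int = 1000
    replicates: int = 3
    wt_strain: str = "DED1"
    mut_strain: str = "ded1-cs"
    cells_per_reporter: int = 2000
    reads_per_reporter: int = 2000
    sigma_cell: float = 0.15  # sd of log10 fluorescence across cells
    gene_sigma: float = 0.30  # sd of per-gene log10 baseline expression
    rep_sigma: float = 0.0  # optional replicate-level log10 jitter per reporter
    base_expression: float = 1.0  # -uORF expression in the WT strain
    strain_expression_ratio: float = 0.7  # global mutant/WT expression ratio
    fraction_repressive: float = 0.3
    repressive_effect: float = 0.6  # true +uORF/-uORF ratio of repressive uORFs
    effect_sigma: float = 0.0  # log10 jitter on per-uORF effects
    fraction_suppressed: float = 0.0
    fraction_enhanced: float = 0.0
    suppressed_ratio: float = 0.5  # true ded1/DED1 effect ratio of that class
    enhanced_ratio: float = 1.5
    bin_value_mode: str = "index"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.fraction_suppressed + self.fraction_enhanced > 1:
            raise ValueError("interaction fractions must sum to <= 1")
        if self.bin_value_mode not in ("index", "fluorescence"):
            raise ValueError(f"unknown bin_value_mode {self.bin_value_mode!r}")


def simulate_facs(cfg: FacsSimConfig) -> tuple[list[FacsBinMatrix], pd.DataFrame]:
    """Simulate sort-seq bin counts for both strains and all replicates.

    Returns the per-(strain, replicate) bin matrices plus a truth table with
    every uORF's true effect per strain and its modulation class.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_uorfs
    uorf_ids = [f"u{i:05d}" for i in range(n)]
    genes = [f"G{i:05d}" for i in range(n)]
    gene_offset = rng.normal(0.0, cfg.gene_sigma, n)

    repressive = rng.random(n) < cfg.fraction_repressive
    effects = np.where(repressive, cfg.repressive_effect, 1.0)
    if cfg.effect_sigma > 0:
        effects = effects * 10 ** rng.normal(0.0, cfg.effect_sigma, n)

    interaction = np.ones(n)
    order = rng.permutation(n)
    n_sup = int(round(cfg.fraction_suppressed * n))
    n_enh = int(round(cfg.fraction_enhanced * n))
    interaction[order[:n_sup]] = cfg.suppressed_ratio
    interaction[order[n_sup : n_sup + n_enh]] = cfg.enhanced_ratio
    modulation = np.full(n, "neutral", dtype=object)
    modulation[order[:n_sup]] = "ded1_suppressed"
    modulation[order[n_sup : n_sup + n_enh]] = "ded1_enhanced"

    truth = pd.DataFrame(
        {
            "uorf_id": uorf_ids,
            "gene": genes,
            "repressive": repressive,
            "true_effect_wt_strain": effects,
            "true_effect_mut_strain": effects * interaction,
            "true_effect_ratio": interaction,
            "modulation": modulation,
        }
    ).set_index("uorf_id")

    index = pd.MultiIndex.from_tuples(
        [(g, u, v) for g, u in zip(genes, uorf_ids) for v in ("WT", "MUT")],
        names=["gene", "uorf_id", "variant"],
    )
    n_reporters = len(index)
    is_wt_variant = np.tile([1.0, 0.0], n)
    base = math.log10(cfg.base_expression) + np.repeat(gene_offset, 2)
    log_effect = np.repeat(np.log10(effects), 2) * is_wt_variant
    log_interaction = np.repeat(np.log10(interaction), 2) * is_wt_variant

    bin_cols = [f"bin{i}" for i in range(1, N_BINS + 1)]
    matrices: list[FacsBinMatrix] = []
    for strain in (cfg.wt_strain, cfg.mut_strain):
        is_mut = strain == cfg.mut_strain
        mu = base + log_effect
        if is_mut:
            mu = mu + math.log10(cfg.strain_expression_ratio) + log_interaction
        for rep in range(1, cfg.replicates + 1):
            mu_rep = mu + rng.normal(0.0, cfg.rep_sigma, n_reporters)
            cells = rng.normal(
                mu_rep[:, None], cfg.sigma_cell, (n_reporters, cfg.cells_per_reporter)
            )
            gates = np.quantile(cells, np.arange(1, N_BINS) / N_BINS)
            idx = np.searchsorted(gates, cells)  # 0..7 per cell
            flat = idx + N_BINS * np.arange(n_reporters)[:, None]
            occupancy = np.bincount(flat.ravel(), minlength=N_BINS * n_reporters).reshape(
                n_reporters, N_BINS
            )
            reads = np.vstack(
                [
                    rng.multinomial(cfg.reads_per_reporter, row / row.sum())
                    for row in occupancy
                ]
            )
            if cfg.bin_value_mode == "fluorescence":
                pooled = np.bincount(idx.ravel(), minlength=N_BINS).astype(float)
                sums = np.bincount(idx.ravel(), weights=10.0 ** cells.ravel(), minlength=N_BINS)
                bin_values = sums / np.maximum(pooled, 1.0)
            else:
                bin_values = np.arange(1, N_BINS + 1, dtype=float)
            counts = pd.DataFrame(reads, index=index, columns=bin_cols)
            matrices.append(FacsBinMatrix(strain, rep, counts, bin_values))
    return matrices, truth


def figure4a_scenario(
    seed: int,
    cells_per_reporter: int = 50_000,
    reads_per_reporter: int = 20_000,
) -> FacsSimConfig:
    """The single-uORF worked-example scenario.

    True mean expressions — WT strain: 1.0 with the uORF, 2.0 without;
    mutant strain: 0.5 with, 1.8 without — i.e. a true uORF effect of 0.5 in
    the WT strain, 0.5/1.8 ≈ 0.28 in the mutant, and an effect ratio of
    (0.5/1.8)/0.5 = 5/9 ≈ 0.56.  Cell noise is kept small and bins carry
    fluorescence values so the estimates converge on the true ratios.
    """
    return FacsSimConfig(
        seed=seed,
        n_uorfs=1,
        replicates=3,
        cells_per_reporter=cells_per_reporter,
        reads_per_reporter=reads_per_reporter,
        sigma_cell=0.05,
        gene_sigma=0.0,
        rep_sigma=0.0,
        base_expression=2.0,
        strain_expression_ratio=0.9,
        fraction_repressive=1.0,
        repressive_effect=0.5,
        effect_sigma=0.0,
        fraction_suppressed=1.0,
        suppressed_ratio=(0.5 / 1.8) / 0.5,
        bin_value_mode="fluorescence",
    )


def write_facs_tsv(matrices: Sequence[FacsBinMatrix], path) -> None:
    """Serialise bin matrices to the TSV format read_bin_tsv understands."""
    rows = []
    for mat in matrices:
        for (gene, uorf_id, variant), counts in mat.counts.iterrows():
            row = {"strain": mat.strain, "replicate": mat.replicate, "gene": gene, "uorf_id": uorf_id, "variant": variant}
            row.update(counts.to_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
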