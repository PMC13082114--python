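# Methods

`uorfded` quantifies how a general translational activator — modelled on the
yeast DEAD-box helicase Ded1 — interacts with upstream open reading frames
(uORFs), using two orthogonal designs: feature-resolved ribosome profiling
(Ribo-Seq) and a FACS-sorted massively parallel reporter assay (MPRA).  This
note records the models, the parameters that matter, the design choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Coordinate and data model

All coordinates are transcript-space, 0-based, half-open (BED convention).
A transcript is tiled by a 5'UTR, a main ORF (mORF, length a positive
multiple of 3) and a 3'UTR; uORFs are spans inside the 5'UTR that exclude
their stop codon.  Genome-to-transcript projection is out of scope, which
removes strand handling from the core.  uORF compilations from different
sources are merged by **exact span identity**: records sharing
(transcript, span) collapse to one record carrying the union of source
tags, while partially overlapping records are kept as distinct biology.
"Overlap" between compilations could also be read as any-overlap; exact
identity is the conservative choice and is configurable only by
pre-processing the inputs.

Start codons classify as AUG, near-cognate (NCC, default set
{CUG, GUG, UUG, ACG, AUA, AUU, AUC}) or non-functional.  AAG and AGG are
deliberately outside the NCC set because AUG→AAG is the canonical dead-start
substitution used to build the uORF-less mutant reporters; a classifier that
called AAG near-cognate would contradict the mutagenesis design.  The
minimum uORF length defaults to 2 codons excluding the stop (the most
permissive criterion among published compilations; very short uORFs are
rare, so the choice barely moves cohort sizes).

## Ribo-Seq quantification

**Counting.**  Footprints are P-site-assigned (5' end + a per-length offset,
default 12 nt for 25–34-nt reads — a conventional yeast offset; only
relative positions matter for the statistics computed here).  RPF counting
excludes the first and last nucleotide triplets of 5'UTRs and the first 20
codons of mORFs, suppressing initiation/termination artifacts; mRNA counting
uses full spans.  5'UTRs shorter than 6 nt count as 0 and are flagged rather
than erroring, since real annotations contain such UTRs.  No sub-codon frame
filter is applied to uORF counting.

**Filtering.**  A feature enters TE analysis only if its host mORF has
≥ 128 total mRNA reads across the four samples (2 genotypes × 2
replicates); uORF and 5'UTR features additionally need ≥ 8 total RPF reads
of their own.

**TE.**  TE(feature) = normalized feature RPF / normalized host-mORF mRNA,
with median-of-ratios size factors computed per assay over mORF rows
(geometric mean 1 within assay).  Point estimates add a pseudocount of 0.5
to numerator and denominator and take the geometric mean over
replicate-paired ratios; inference never uses the pseudocount.

**Differential TE.**  Per feature, raw counts across all eight libraries
are modelled with a negative-binomial GLM, design
`1 + assay + genotype + assay:genotype`, offsets log size factors; the
interaction coefficient (converted to log2) is the TE change in the mutant.
Dispersions are method-of-moments estimates per feature, shrunk 50/50
toward an `a0 + a1/mean` trend fitted across all features.  Wald statistics
are referred to a *t* distribution with moderated degrees of freedom
`df_resid · (1 + (1−w)/w)` (df = 8 at the default shrink weight w = 0.5):
in calibration experiments on 2000 null NB features (dispersion 0.1, mean
≈ 200), a plain normal reference rejected ~8% at α = 0.05 and the bare
residual df ~1.5%, while the moderated df lands at ~4.5%.  BH adjustment
runs in two families — mORF (with 3'UTR) features and uORF/5'UTR features —
because distinct FDR thresholds are applied to each family downstream.
Dependence classes use |log2ΔTE| ≥ log2(fold) *and* FDR < threshold, with
defaults (1.5, 0.05) for mORFs and (2.0, 0.01) for uORFs.

**CRD.**  The center of ribosome density is the smallest position whose
cumulative footprint count reaches half the transcript total (a ceiling
convention; the 50% definition is ambiguous for even totals and a
deterministic tie rule is required).  ΔCRD = (mean mutant CRD − mean WT
CRD)/length; the length normalization is applied by default because the
interpretive convention ("negative = 5'-ward shift") is stated on the
normalized scale, and can be disabled.  CRD uses all reads on the
transcript, not only mORF-mapped reads.

**Metagene.**  Around the mORF start, each transcript with ≥ 32 reads in
the window contributes its density divided by its own window mean; the
profile is the position-wise mean, so uniform coverage gives a flat profile
of 1.

## PARS structure scores

Windows downstream of a uORF start are specified as 1-based inclusive
offsets from the +1 nucleotide (the A of the start codon): (16, 45) covers
30 nt.  Missing scores impute as 0 with the covered fraction reported;
below 80% coverage the score is NA.  Max30 is the maximum 30-nt sliding
window sum inside the 5'UTR (whole-UTR sum when shorter than 30 nt).
Cohort splits between "high" and "low" structure use the median, the
neutral two-group rule.  Computing PARS from raw nuclease data, RNAfold
ΔΔG and G-quadruplex prediction are out of scope; such scores enter as
precomputed per-UTR values through the same binning operations.

## FACS-uORF MPRA statistics

Each uORF is represented by a paired reporter: WT (native uORF) and MUT
(start codon → AAG).  Cells are sorted into 8 bins of increasing
YFP/mCherry fluorescence and each bin sequenced.

**Expression.**  A reporter's expression is the read-weighted mean of the
bin values.  Bin values default to indices 1..8: gate boundaries are never
published, indices preserve the ordering (all a rank test uses) and make
expression a bounded score.  Index-valued expression is monotone but
*compressed* relative to true fluorescence; recovery claims are therefore
stated on the effect-ratio scale, where the compression largely cancels,
and fluorescence-valued bin means are supported where quantitative recovery
matters (the worked single-uORF example uses them).

**Testing.**  The WT-vs-MUT comparison within a replicate is a Wilcoxon
rank-sum test on the binned read populations, computed in closed form from
the two 8-bin count vectors (midranks, tie-corrected variance, continuity
correction) — with only eight distinct values no expansion is needed.  The
source protocol's phrase "mean YFP values … compared by rank-sum test per
replicate" is ambiguous (a mean is a scalar); testing the bin-sorted read
populations is the natural reading and is flagged as an interpretation, not
asserted as the original procedure.  A per-reporter read cap (default
10,000, deterministic proportional downsampling) bounds the influence of
sequencing depth; expression estimates are scale-invariant so the cap never
moves point estimates.  Per replicate, p-values are BH-adjusted across the
library; a uORF is consistently significantly repressive (CSR) when every
replicate with data (≥ 2 required) is significant at FDR < 0.05 with the
same direction, "repressive" meaning the start-codon mutant is expressed
higher.

**Effects.**  The uORF effect is +uORF/−uORF expression (< 1 = repression),
computed from replicate-pooled counts (estimation and testing kept
separate).  The mutant/WT ratio of effects classifies Ded1 modulation at a
1.33-fold threshold: ratio < 1/1.33 → Ded1-suppressed (the uORF bites
harder when the helicase is impaired), > 1.33 → Ded1-enhanced, else
neutral.

## Synthetic data

The generators produce every input the pipeline consumes, at the study's
own design: 2 genotypes × 2 assays × 2 replicates for Ribo-Seq, 2 strains ×
3 replicates × 8 bins for the MPRA.  All are bit-reproducible under a fixed
seed, and truth tables record every planted parameter.

**Ribo-Seq simulator.**  Transcript architecture is log-normal around
yeast-like medians (5'UTR 60 nt, mORF 330 codons, 3'UTR 120 nt); 40% of
transcripts carry 1 + Poisson(0.4) uORFs of 2–10 codons.  mRNA abundance is
log-normal (σ = 1, mean-normalized); counts are NB (dispersion 0.1) around
abundance × TE × length-share means, scaled to ~200 mORF reads per sample
at unit abundance — a desk-scale depth that keeps the full calibration and
recovery runs inside seconds while leaving per-feature counts in the regime
the thresholds (128 mRNA / 8 RPF) were designed for.  Genotype effects
multiply TEs by 2^(planted log2ΔTE), either Gaussian with a configurable
uORF–mORF correlation ρ or discrete planted sets.  P-sites scatter
uniformly within features.  The optional cycloheximide-style artifact adds
an NB pileup over the first five mORF codons with density
`chx_intensity` (default 10) times the *baseline* mORF body density —
proportional to abundance and baseline TE but independent of the genotype
effect, because the pileup is an initiation-site phenomenon.  That is what
lets the artifact couple ΔCRD to mORF ΔTE: when body reads drop in the
mutant the pileup does not, the CRD shifts 5'-ward, and the spurious
positive ΔCRD–ΔTE correlation appears; with the artifact off the
correlation collapses.  With tracks enabled the returned count table is
produced by running the real counting code (exclusions included) on the
tracks; in table-only mode counts are drawn directly at feature level with
full-span semantics.

Not emulated: alignment and rRNA contamination, isoform heterogeneity,
nonuniform codon-level ribosome dwell times, UMI/PCR duplicates.  Passing
tests therefore demonstrate correctness of the statistics under the assumed
generative model, not robustness to those real-data artifacts.

**PARS simulator.**  Background scores N(0, 1) per nucleotide; a planted
stem adds +3/nt over the 16–45 window downstream of chosen uORF starts
(block mass 90, far above the noise scale of a 30-nt window sum, σ ≈ 5.5).

**FACS simulator.**  Cell log10 fluorescence is Normal with mean = gene
offset (σ 0.3) + strain effect (default mutant/WT = 0.7, matching the
~30% global expression drop of a helicase mutant) + uORF effect (WT variant
only; default 30% of uORFs repressive at effect 0.6) + strain×uORF
interaction, and σ_cell = 0.15 log10 units.  There is no replicate-level
mean jitter by default — replicate scatter comes from finite cells and
reads, keeping the per-replicate rank tests exchangeable under the null
(an optional `rep_sigma` knob exists for robustness experiments).  Gates
are the 8 pooled quantiles per (strain, replicate) — sorting acts on the
pooled culture, not per reporter — so marginal bin occupancy is uniform by
construction; reads are multinomial (default 2000) over each reporter's
cell-occupancy fractions (default 5000 cells in the headline runs, 2000
otherwise).  The worked single-uORF scenario plants the schema values
exactly (WT strain 1.0/2.0; mutant 0.5/1.8, i.e. a 0.9× strain effect and a
5/9 interaction) with σ_cell = 0.05 and fluorescence-valued bins, so the
estimator converges on effects 0.5 and 0.278 and ratio 0.556.

Not emulated: plasmid copy-number variation, sorter impurity and gating
optics, regrowth after sorting, library-prep PCR structure.

## Numerical choices and degenerate inputs

* TE pseudocount 0.5 (point estimates only); zero mRNA in all replicates →
  feature reported FILTERED, never a crash.
* CRD tie rule: smallest position with cumulative ≥ half (ceiling).
* GLM non-convergence → NA p-value with a convergence flag; BH is
  NaN-tolerant.
* Rank-sum degeneracies: shared point mass → p = 1, direction none;
  under-read reporters → NA with no call.
* Downsampling to the read cap floors scaled counts and assigns the
  remainder to the largest fractional parts — deterministic, no RNG.
* Mann-Whitney switches to exact enumeration at combined n ≤ 12 without
  ties (deterministic small-sample behaviour); quartiles are type-7 with
  the 1.58·IQR/√n notch, the convention of the common boxplot tools.

## Known limitations

* Median-of-ratios normalization assumes most features unchanged and
  roughly symmetric changes; with a strongly one-sided planted TE shift
  (e.g. 20% of mORFs all down 2-fold) the null log2ΔTE estimates acquire a
  bias of ~+0.15–0.2 — visible in recovery experiments and inherent to the
  estimator, not a defect of the GLM.  Balanced designs are unbiased.
* Bin-index expression is compressed; per-strain effect estimates from
  index bins are pulled toward 1 for reporters far from the pooled center.
  Ratios of effects are robust to this; absolute effects are not.
* The NB test's calibration is demonstrated at the simulated conditions
  (8 libraries, moderated dispersion); with many more replicates the
  moderated-df reference becomes mildly conservative.
* CSR calling treats reads as independent draws from the sorted cell
  population; overdispersion between replicate cultures beyond sampling
  (if present in real data) would inflate the per-replicate significance,
  mitigated but not eliminated by the all-replicates-consistent rule.
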