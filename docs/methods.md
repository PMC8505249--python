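# Methods

## Scope and model

`celldmr` analyzes enrichment-based promoter methylation data: per-probe
scores from methyl-CpG-binding-domain (MBD) capture hybridized to a promoter
tiling array, compared against a whole-genome-amplified (unmethylated)
reference, for two FACS-sorted cell populations (neuronal, nonneuronal) in a
case/control cohort with duplicate technical experiments. Enrichment signal
is monotone in methylation density but not an absolute methylation level, so
all inference is interval-based: methylated regions per sample, differential
regions between groups, and overlap/enrichment statistics on interval tracks.

Coordinates are 0-based half-open throughout (BED convention); every written
track states this in a header comment. Promoter tiles span TSS−7500 ..
TSS+2500 on the plus strand and mirror around the TSS on the minus strand.
Probes are 25-mers placed every `probe_spacing` bp (default 35), giving
`floor(tile_width / spacing)` probes per tile (285 at the defaults); the last
probe always ends inside its tile.

## Signal model (synthetic data)

The generator plants, per (promoter, cell type):

- a **baseline state** — methylated with probability 0.30 (neuron) / 0.38
  (nonneuron), the methylated promoters carrying a "core" segment of
  ~0.8–2 kb around the TSS at enrichment level 1.0 (unmethylated baseline
  0.0). These defaults encode the observed direction of the cell-type
  difference (fewer methylated promoters in sorted neuronal nuclei); the
  absolute values are fixture choices, not estimates.
- per-subject **core activity**: each non-DMR core is present in a given
  subject with probability `core_active_prob` (default 0.9), which creates
  subject-to-subject methylation-burden variability; an optional confounder
  coupling shifts this probability linearly with a chosen covariate's z-score.
- **DMRs**: a fraction (default 0.08) of promoters per cell type, hypo with
  probability 0.7 (hypomethylation-dominant, matching the disease setting the
  package emulates), with effect sizes drawn from a configurable grid in
  units of the probe-noise SD (default 3/4/6). Hypo DMRs occupy the
  methylated core and subtract `effect × noise_sd` (clipped at the core
  level) from patient samples; hyper DMRs occupy a TSS-proximal segment of an
  unmethylated promoter and add the shift. Cores carrying a planted DMR are
  always active — the planted contrast is the ground truth the callers are
  scored against, so it is not diluted by the burden-variability mechanism.
  A configurable fraction (default 0.35) of a second cell type's DMR
  promoters is shared with the first (same gene and direction) to mimic the
  partial cross-cell-type overlap seen in sorted-nuclei studies.
- signal per probe/column: baseline + group shift + a per-sample offset
  (SD 0.05, shared by the two replicates) + i.i.d. Gaussian probe noise
  (SD 0.25 per replicate). The duplicate experiments share all biology and
  the sample offset but not probe noise.
- **auxiliary tracks**: drug-induced DMRs for six conditions (three mood
  stabilizers × min/max concentration) that overlap planted disease DMRs at a
  configurable concordance fraction (default 0.35) and flip direction with
  probability 0.9, plus background drug regions on non-DMR promoters;
  HMR flags with an odds boost (default 1.5) on DMR promoters; GWAS loci
  placed by weighted sampling without replacement of anchor promoters with
  weight equal to the configured enrichment odds on DMR promoters (odds 1 is
  exactly uniform; for modest sampling fractions the realized odds ratio
  approximates the configured value).
- an RRBS-style per-CpG table: CpGs every ~150 bp inside cores and DMR
  regions, pooled methylated/unmethylated counts at ~60 reads per group,
  true fractions 0.8 (methylated) / 0.1 (unmethylated), case fractions
  shifted by ±0.15 inside DMRs. The mapping from enrichment effect size to
  methylation difference is a configuration choice, not an inference.
- covariates: age ~ N(45,10) truncated ≥18, PMI ~ N(30,10) truncated ≥1,
  pH ~ N(6.5,0.25); onset, duration and lifetime antipsychotics for cases
  only. These are arbitrary, documented fixture distributions.

Every operation seeds `numpy.random.default_rng` from the config seed plus a
fixed per-operation salt, so each output is deterministic given the config
alone and all text outputs are byte-reproducible.

## MR calling

Probe scores (sample minus mean reference) are smoothed per promoter tile
with a 10 %-trimmed mean over a ±300 bp window (truncated at tile edges; with
10 % trimming an 11-probe window drops its single most extreme value per
tail). The two replicate experiments are window-scored independently and
averaged before thresholding. The threshold is a robust z-score: median +
z × 1.4826 × MAD of the sample's own score distribution (default z = 2). A
mean/SD z-score would fail here — the score distribution is bimodal, and the
methylated mode would sit above mean + 2 SD — so the location/scale are taken
robustly; an absolute-threshold mode is available. Runs of qualifying probes
are merged across sub-threshold gaps of ≤ `max_gap` bp (default 110 bp,
measured from the end of one qualifying probe to the start of the next, i.e.
up to two skipped probes at 35 bp spacing and 25-mer probes); runs with fewer
than `min_probes` (default 4) qualifying probes are discarded. Regions never
cross tile boundaries.

At the default z = 2, window-score autocorrelation (adjacent probes share
most of their window) produces a sizable population of short noise regions on
top of the planted cores. This mirrors the behavior of permissive peak
callers on tiled arrays; MR counts are therefore meaningful comparatively
(between groups and cell types), not absolutely, and analyses that need
burden to track the planted core count should raise z (the confounder tests
use z = 4).

MR-count statistics: two-sided Mann–Whitney for the four standard contrasts
(cell types within each group; case/control within each cell type), using
exact permutation enumeration of all C(n, n1) splits for combined n ≤ 12
(valid under ties) and the tie-corrected normal approximation otherwise;
Spearman rank correlation (average ranks, pairwise NaN dropping) for each
covariate against MR count per cell type.

## DMR calling

Per cell type and replicate experiment, a Welch t statistic is computed per
probe on the smoothed window scores (patients vs controls, ≥3 samples per
group enforced). Runs of same-sign probes with |t| ≥ 3 are merged with the
same gap/min-probe logic as MR calling; requiring a consistent sign makes the
hyper/hypo label (sign of patient-minus-control mean) automatic. The
per-region score is the mean probe t; a descriptive region P is derived from
it with the mean Welch degrees of freedom. No cross-probe multiplicity
correction is applied; specificity comes from the replicate intersection.

Replicate intersection keeps base-pair intersections of same-direction
overlapping pairs only; opposite-direction overlaps are dropped, counted and
logged. Intersection pieces are merged within direction, so the final set is
sorted and non-overlapping.

Gene association attaches every gene whose promoter tile overlaps a DMR by
≥1 bp. Cross-cell-type overlap percentages are reported with the smaller set
as denominator (the union-based percentage is emitted alongside, since the
convention is not universal); a gene with DMRs of both directions appears in
both direction sets.

## Context annotation and gene-set enrichment

CpG context: islands are merged (joining touching fragments, which makes
labels invariant to island fragmentation); shores are the 2 kb flanks
measured from island boundaries, shelves the next 2 kb. Labels are assigned
by ≥1 bp overlap with precedence island > shore > shelf > open sea; a
midpoint mode is available. Gene context uses precedence promoter > 5'UTR >
exon > intron > 3'UTR > intergenic on the same overlap rule. Composition
differences between DMR sets are tested per context with the two-sided exact
test on (in-context vs not) × (set A vs set B); no multiplicity correction by
default (a Benjamini–Hochberg flag exists at the API level via statsmodels
conventions in downstream code), matching the reporting style of the studies
this package emulates.

Gene-set enrichment over user-supplied GMT sets is a one-sided
hypergeometric over-representation test against an explicit background
(default: all genes on the array); gene sets are intersected with the
background first and queries outside the background are rejected with the
offending ids. Results optionally carry a per-stratum partition of member
genes (e.g. neuronal / nonneuronal / common) and sort ascending by the chosen
stratum's percentage, reproducibly (ties broken by term name).

## Overlap, concordance, validation

Track overlap is counted at region level (a DMR either overlaps a track by
≥1 bp or not), matching how such percentages are reported in practice;
`any_condition` mode unions the condition tracks first, so per-condition
percentages never exceed it. Directional concordance contrasts disease-DMR
directions by overlap with each track direction in a 2×2 exact test; a DMR
overlapping both track directions is counted in both tables and flagged
ambiguous. Per-CpG validation tests each covered CpG with the two-sided
exact test on pooled (methylated, unmethylated) × (patients, controls)
counts; a DMR validates when ≥1 contained CpG is significant with a
difference sign matching the DMR direction, sign-discordant-only DMRs are
flagged, and DMRs with no covered CpG are excluded from the denominator and
counted separately. Validated counts are monotone in alpha by construction.

## GWAS enrichment

The promoter table counts promoters overlapped by (DMR, locus, both,
neither); the exact test is computed by integer hypergeometric enumeration
(odds ratio (a·d)/(b·c) with zero/infinity flagged). The resampling null
redraws matched-size promoter sets uniformly without replacement — promoters,
not base pairs, are the resampling unit, preserving the universe and the
observed set size; a length-preserving interval-shuffle mode is available as
a sensitivity analysis. Empirical P uses the +1 correction and both tails
are reported, with the direction chosen by observed vs null mean. Default
n_iter is 10,000; calibration tests use 2,000 for speed.

## Numerical choices and problem sizes

- Exact 2×2 P values are computed with exact integer weights (no pmf
  tolerance factor); ties in table probability are exact.
- The exact Mann–Whitney branch uses the symmetric deviation
  P[|U−μ| ≥ |U_obs−μ|] over all splits of the observed values, which remains
  a valid permutation P under ties; the branch boundary (combined n = 12,
  ≤ 924 splits) keeps enumeration trivial.
- Degenerate inputs return flagged results rather than exceptions: zero
  margins give P = 1 with a `degenerate` flag, constant samples likewise.
- Window trimming truncates (`int(trim × width)` per tail); edge windows are
  computed exactly on the truncated support.
- Test and demonstration runs use scaled-down study sizes — 1,000 promoters
  and 10+10 subjects for the end-to-end pipeline, 80–400 promoters for
  recovery/power studies, 2,000 iterations for calibration — chosen so each
  Monte-Carlo study has adequate support while the whole suite stays cheap;
  the generator's cohort defaults (34 patients, 35 controls) match the
  emulated study design.

## What the synthetic tests do and do not show

Passing the recovery, calibration and concordance suites shows the callers
and tests are correct against the generator's model: additive Gaussian
enrichment noise, rectangular planted effects confined to promoter tiles,
independent probe noise, and exchangeable samples. Real tiling-array data
violate all of these to some degree — probe affinity and GC effects, spatial
noise correlation beyond the smoothing window, batch structure, cellular
heterogeneity within sorted fractions, and LD-structured GWAS loci are not
modeled; absolute MR/DMR counts from permissive thresholds are
caller-parameter-dependent. Conclusions about real data therefore rest on
the comparative structure (directions, enrichments, concordances), not on
the synthetic absolute numbers. LD-aware locus expansion, SNP-level
colocalization, array normalization and read-level bisulfite processing are
out of scope.
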