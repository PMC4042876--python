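# Methods

This note documents the models, parameter choices and numerical decisions
behind `ctdseq`, and what the synthetic-genome validation does and does not
establish.

## Coordinate and track model

All internal coordinates are 0-based half-open; BED stays native, GFF3
(1-based closed) and wiggle (1-based starts) are converted at the I/O
boundary only. A `GenomeTrack` holds one value per fixed bin (default 50 bp
for profiling, 10 bp for maximal-peak analyses); bin *i* covers
`[i·b, (i+1)·b)`. Per-bin values are mean per-bp coverage, so
`Σ values · b` equals total fragment mass. Oriented windows are always
expressed in the gene's own 5'→3' frame: `TSS−a` means `a` bp 5' of the
TSS on the gene's strand; for minus-strand genes the antisense window lies
genomically downstream of the TSS. Replicate tracks are merged by bin-wise
mean (a config choice; sum is available).

## Tag processing

* **Pile filter.** Duplicate tags at one `(chrom, pos, strand)` beyond a
  cap k are removed. With `k="auto"`, k is the smallest integer whose
  Poisson tail probability at the genome-wide per-position density falls
  below 1e−6 — deeper piles are PCR or collapsed-repeat artifacts rather
  than sampling fluctuations. The filter is idempotent.
* **Fragment length.** Estimated as the shift in `[read_length,
  max_shift]` maximizing the Pearson correlation between forward-start and
  shifted reverse-start densities on a 10-bp grid; ties break to the
  smallest shift, which also makes the degenerate all-coincident case
  return the read-length lower bound.
* **Elongation & binning.** Single-end tags are extended 3'-ward to the
  estimated fragment length; pairs are used as spans. Mass is conserved to
  1e−9 except for fragments truncated at chromosome ends (logged).
* **Input subtraction.** The input is scaled to the sample's genome-wide
  mass, subtracted bin-wise, and negatives are clipped to 0 — downstream
  mixture fits and profile means assume non-negative occupancy. A
  per-million variant exists.
* **MNase.** *Density* = fragment-span coverage without input subtraction
  (occupancy); *midpoint* = unit mass at `⌊(start+end)/2⌋` (dyad
  positioning). Orphan single-end tags are connected using the estimated
  fragment length.

## Two-Gaussian mixture threshold

Signal distributions of per-gene mean values are modeled as
π₁N(μ₁,σ₁²) + π₂N(μ₂,σ₂²), fitted by EM with a deterministic start
(means at the 25th/75th percentiles, both sds at half the pooled sd, equal
weights), tolerance 1e−8 on the log-likelihood, ≤ 500 iterations. The
selection threshold is **τ = μ₂** — the mean of the upper (bound)
component. The fit runs on raw values (log-space by flag); zero-mean genes
are kept by default (flag to drop).

Two consequences of τ = μ₂ worth stating plainly:

* When the data are genuinely bimodal (background plus bound), τ sits at
  the center of the bound component, so roughly the upper half of bound
  genes passes — a deliberately stringent selection.
* The **degeneracy flag**: EM on a unimodal sample still yields two means.
  Empirically, on a single Gaussian the fitted separation `(μ₂−μ₁)/sd`
  stays ≤ ~1.35 (from this initialization), while a genuinely 5-sd
  separated balanced mixture gives ≥ 1.85; `min_separation` defaults to
  1.5 to sit between those regimes. Degenerate fits refuse to produce a
  threshold unless the caller overrides (e.g. τ = 0 for the relaxed
  selection of weakly bound genes).

The same machinery gates "significant antisense RNA" in the spatial
analysis. Because τ = μ₂ keeps the upper half of whatever its second
component models, AS-dominant recovery on a full genome is intrinsically
~50 % when those genes form their own tight cluster — matching the
original analysis, which retained roughly half of its class-I genes at
this step. The fitted threshold is therefore computed over the *whole
filtered annotation* (silent genes included), where the upper component
models ordinary promoter-associated AS levels; planted high-AS genes then
sit in its upper tail.

## Statistics

* **AS/S**: per-gene antisense and sense means (500 bp either side of the
  TSS, oriented). Upper IQR outliers (`x > Q3 + 1.5·(Q3−Q1)`, type-7
  quartiles) are filtered per side; a gene survives only if kept on both
  sides. The paired two-sided t test runs on AS−S. Min-max scaling of the
  pooled values is affine and cannot change t or p (verified by test);
  the Pol II-normalized variant divides both sides by the gene's Pol II
  mean, dropping zero normalizers. A Shapiro–Wilk p of the differences is
  recorded as a diagnostic and never gated on. Note that filtering
  outliers before testing makes the procedure mildly anticonservative
  under the null: the measured type-I rate at α = 0.05 is ≈ 0.056 (vs
  0.047 for the unfiltered paired t on the same draws) — a property of
  the filter-then-test design, inherited from the original workflow.
* **Nonparametrics**: Mann-Whitney-Wilcoxon (enhancer-vs-promoter levels,
  per-gene AS>S, tissue enrichment) and two-sample Kolmogorov–Smirnov
  (distance distributions) via scipy; tests cross-check U against
  exhaustive pair counting and KS D against the ECDF supremum on small
  instances.
* **Expression**: replicate matrices are averaged per probe, the median
  across a gene's probes is attributed to the gene, and L/M/H strata are
  quantile cuts (defaults 0.60/0.82, reproducing the published stratum
  proportions; the original boundaries are not recoverable).

## Promoter classes and spatial analysis

Rows of the TSS±1000 matrix are ranked by the offset of their maximal
column (ties to the 5'-most; all-zero rows dropped). Class cuts default to
(−100, +100) bp — class I strictly upstream, class II the closed interval,
class III strictly downstream; the published class counts imply cuts that
`back_solve_cuts` can reproduce from target proportions. Mark maxima are
searched within ±100 bp of the Tyr1P peak; the signed distance to Pol II
is positive when the mark lies past Pol II *away* from the TSS (the
leading edge of antisense transcription), and |d| ≤ one 10-bp bin counts
as colocalized.

## Peak calling and enhancer workflows

Peaks are maximal runs of bins ≥ threshold, merged across gaps < max-gap
bp, summit at the highest bin (leftmost tie). Default per-mark thresholds
(5 signal units ≈ 25× the background rate) and max-gaps (300–1000 bp) are
config. "Combined enrichment" is implemented as ≥ 1 bp triple overlap with
the merged footprint as candidate. Gene distance is the minimal interval
gap (0 when overlapping); H3K36me3 exclusion is peak presence within
2 kb of the candidate boundaries. τ_ratio defaults to the 5th percentile
of annotated-promoter H3K4me3/me1 ratios — reproducible and conservative
toward excluding promoter-like intergenic regions (the original threshold
was drawn by eye); regions with zero H3K4me1 mean are dropped and logged.
Every stage logs counts in/out, mirroring the E/P stage bookkeeping.

## Synthetic genome

Defaults (the study conditions): 2 chromosomes × 2 Mb, 120 expressed +
60 silent genes (3–12 kb, both strands, > 4 kb apart), 40 enhancers and
15 lincRNA-like distractors (≥ 5 kb from genes), class proportions
0.575/0.3125/0.1125 matching the published class sizes. Summits are
Gaussian (sd 150 bp, the fragment scale) with a narrow apex (sd 10 bp) at
the planted position so the maximal bin is well defined at 10-bp
resolution; the apex carries ~3 % of window mass. Classes are planted on
the **Tyr1P** offset (the sorted mark): class I −700..−150, II −100..100,
III 150..700 bp, on a 10-bp grid; Pol II and the other isoforms are placed
through signed distances (0 or 20–50 bp) drawn from per-mark
before/colocalized/after probabilities. Each isoform gets a mirrored AS/S
summit pair at ±|offset| whose antisense amplitude is raised by a per-mark
δ (Tyr1P +10, Ser7P +2 of a 30-unit summit): with δ = 0 the construction
is AS/S-symmetric up to the apex mass, so the planted δ alone controls the
AS/S statistic. Short-RNA levels are lognormal (median 2.5, σ = 0.3) with
a 4× AS boost for the AS-dominant half of class I; the canonical TSS sense
species is planted at the base level for every gene so total short-RNA
output is independent of dominance (otherwise the IQR outlier filter would
preferentially remove one group). Enhancers carry H3K4me1 40 / H3K4me3 8
(ratio 0.2), promoters the reverse (ratio 5); distractors add an H3K36me3
body within 2 kb; half the enhancers get H3K27ac; enhancer Tyr1P is 0.9×
the summit amplitude (the planted "Tyr1P marks enhancers" signature).
Nucleosome dyads sit at −550/−350/−180/+130 bp. Noise is Poisson per bin
(rate 0.2 per 50 bp) with optional Gaussian jitter; the input track is
pure noise. The expression atlas is probe-level (70/20/10 % of genes with
1/2/3 probes), 84 tissues, with a planted 4× boost in one tissue for
enhancer-flanking genes. All outputs are bitwise reproducible under a
fixed seed.

What the generator does **not** emulate: mappability and GC bias,
replicate-level biological variability, overlapping/nested gene models,
continuous pausing-strength variation, and enhancer–promoter contact
structure. Passing the planted-truth tests shows the implementation
recovers the structures it models at realistic noise, not that the
biological conclusions transfer to arbitrary real data.

## Problem sizes

The validation suite uses genomes of 4–10 Mb with 120–500 genes and
100–1000 seeded replicates per statistical calibration, chosen so the full
suite and the acceptance script each complete in minutes while leaving
every recovery margin (3 SE bands, ≥ 95 % hit rates) driven by the planted
effect sizes rather than by sample size.

## Known limitations

* Anchored-matrix columns are bin centers; a planted position is recovered
  to within half a bin, with adjacent-bin flips at the per-mille level
  when Poisson noise breaks a boundary tie.
* The local bin-score rescaling the original processing mentions is folded
  into the global equal-mass scaling; no separate locus-level reweighting
  is implemented.
* The exact pile-threshold rule and scaling constant of the original
  scripts are not recoverable; both are config-exposed
  (`max_per_position`, scaling mode) with the defaults above.
* The K27ac workflow centers on the H3K4me3 summit; with very broad
  promoter H3K4me3 the center can sit tens of bp from the true TSS.
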