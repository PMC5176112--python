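# Methods

This note documents the models and procedures implemented in `dupscape`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and sizes

All intervals are 0-based half-open internally (BED convention); GFF3 and
VCF conversion happens only at I/O boundaries. Locus size is `end − start`.
Note that for a region reported with 1-based inclusive coordinates the same
span prints one basepair smaller under this convention; we standardize on
`end − start` everywhere.

## Consensus discovery

**Breakpoint confidence intervals.** Each caller archetype has a resolution
profile applied around both breakpoints: PE+SR callers 50 bp outwards /
100 bp inwards, read-depth callers 1 kb outwards / 400 bp inwards,
split-read callers ±10 bp. CIs are clamped at chromosome bounds so short
scaffolds never produce invalid intervals.

**Within-tool merge.** Two calls link when their start CIs intersect *and*
their end CIs intersect; events are the transitive closure (single linkage)
of that relation. Representative coordinates are the median of member
starts/ends — robust and reproducible; for even-sized clusters the tie
between the two middle values goes to the member from the
finest-resolution method (SR > PE+SR > RD), then to the lower coordinate.
After forming events we re-cluster the representatives (with envelope CIs)
until a fixed point, which makes merging idempotent: merging the merged set
changes nothing.

**Support filter.** PE+SR calls require ≥ 3 supporting read pairs with
mapping quality strictly greater than 20 ("higher than 20" is read as a
strict inequality).

**Ubiquitous-locus filter.** A merged event present in every
reference-species sample is more plausibly a reference assembly error or a
genuine deletion in the reference than a duplication segregating in all
individuals; such events are removed before cross-tool consensus.

**Cross-tool consensus.** Events cluster at reciprocal overlap
≥ 0.9 (min of the two mutual overlap fractions) and survive only when the
cluster spans ≥ 2 distinct method archetypes — distinct *methods*, not
distinct calls. The cross-species merge of the two genotyping sets uses a
strict > 0.9 threshold; the within-species consensus uses ≥ 0.9. Both
thresholds are parameters.

**Deletions, inversions, translocations** emitted by callers are ignored on
ingest; the pipeline is about duplications.

## Dominant genotyping

Genotypes are presence/absence only: 1 when a sample has more copies of the
locus than the reference, 0 when the same, never a heterozygote call. The
external genotyper is replaced by a transparent threshold rule — a sample is
a carrier when ≥ 3 read pairs support the locus — because downstream
analyses use only the binary state, so any calibrated evidence threshold
preserves their semantics. Missing evidence (no record) is distinguished
from absence internally; exports can collapse missing → 0 behind a flag.
Median read support is computed over non-missing samples only; loci with
median support > 500 (high-copy repeats) and loci genotyped in no sample are
dropped.

## Long-read breakpoint validation

A tandem duplication aligned to a non-duplicated reference splits a spanning
long read into segments with one of two signatures: **R1**, two segments
covering overlapping reference sections (the read spans the whole duplicated
unit), or **R2**, a later read segment mapping strictly upstream of an
earlier one without overlap (the read starts inside the first copy and ends
inside the second). Adjacent split pairs become breakpoint candidates whose
junction positions (the facing segment ends) are extended by a slope
(default ± 1000 bp). A locus is validated by a candidate whose two junction
windows intersect the locus's start and end CIs *and* whose source read
carries an R1/R2 signature; one supporting read suffices (configurable).
Only same-strand splits are considered — tandem-duplication geometry implies
same orientation — and segments shorter than 100 bp (configurable) are
ignored to suppress spurious micro-splits. "Upstream/downstream" refer to
reference coordinates in the read's own segment order.

## Feature overlap and the placement null

Overlapping duplication intervals are merged (union) before this analysis.
Categories use a fixed precedence: any CDS overlap ⇒ CDS; else intron; else
UTR; any of the three also sets the gene flag, and containing a complete
gene span sets the complete-gene flag. Intron-before-UTR is the default
where both overlap without CDS — the opposite ordering is available via
`utr_first`, since annotation conventions differ. Introns are derived as
gene span minus (CDS ∪ UTR ∪ exon) intervals.

The null hypothesis is "duplications land anywhere": the same interval sizes
are re-placed uniformly at random into non-overlapping genome-wide positions
(chromosome chosen ∝ length, start uniform over the valid range, rejection
resampling on overlap with a cap of 10 000 tries per interval) for
`n_iter = 10 000` iterations, and a category is flagged depleted/enriched
when the observed count falls below the 2.5 % or above the 97.5 % null
quantile. Placement is genome-wide, not per-chromosome. The sampler places
draws in parallel batches with conflict resolution, falling back to strict
largest-first sequential rejection above 30 % genome occupancy where batched
redraws can fragment the remaining space.

Because counts are integers, the quantile test is slightly conservative:
its achieved two-sided type-I rate sits a little below the nominal 5 % and
approaches it as the per-category counts get smoother. The calibration
fixture (`gen_calibration_fixture`) was therefore designed with three gene
archetypes (tiny single-exon genes, long-UTR genes, intron-rich genes) and
250 loci per run so that every category has moderate occupancy; on it the
pooled per-category type-I rate lands in the 4–5 % range, within the 3–7 %
band asserted by the tests.

## Population genetics on dominant markers

Presence frequency is used directly as the marker frequency (no zygosity
deconvolution — the markers are dominant by construction). F_ST is the
Hudson-type two-population estimator with finite-sample correction given in
the README; it is 1 exactly at fixed differences, symmetric under group
exchange, undefined (and signalled) when both groups are fixed for the same
state, and negative estimates from sampling noise are reported raw.

The outlier scan permutes group labels jointly across loci (whole sample
columns), preserving inter-locus correlation in the null — conservative for
linked loci. The default p-value is the standard conservative
`(1 + #{F_perm ≥ F_obs}) / (n_perm + 1)`; because binary markers make the
statistic heavily tied, these p-values are discrete and super-uniform, so an
optional randomized tie-break (uniform split of the tie mass) is provided
that is exactly uniform under exchangeability — used by the uniformity
property test, while the conservative default is what the scan reports.
Benjamini–Hochberg controls the FDR (default 0.05). With ~500 loci, planted
fixed differences reach the BH threshold only when `n_perm` is large enough
that `1/(n_perm+1)` clears `fdr·k/m`; the default `n_perm = 10 000` is the
smallest round value that does.

PCA mean-imputes missing cells per locus, centres loci, and decomposes the
sample × locus matrix (full SVD); a constant matrix is signalled and returns
zero variance fractions. Importers for external Bayesian scanner tables
(log₁₀ posterior-odds and XtX columns; thresholds 1.0 and 7.9 by default)
let the two-method outlier intersection be replayed from user-supplied
outputs without re-implementing their MCMC.

## Synthetic study generator

The generator emulates the study design end to end with full determinism
(fixed seed ⇒ byte-identical files; each stage draws from an independent
seeded substream):

- **Genome/annotation**: 21 chromosomes, mean 13 Mb (≈ 275 Mb total), gene
  models with UTR–CDS–intron structure at 30 % genomic density.
- **Truth duplications**: 744 loci by default; sizes log-normal with median
  5 693 bp clipped to [228, 207 510] bp (σ = 1.1 fits that range for ~750
  draws); placed without overlap.
- **Samples**: 20 + 14 individuals of two species across three locations
  (10 + 10 focal individuals at the first location are the discovery
  populations), with the published location coordinates carried as
  covariates.
- **Frequencies**: carrier counts follow a neutral-like 1/i spectrum
  (singleton fraction ≈ 25–30 %, matching the study regime), with a
  per-location log-scale perturbation (sd 0.15) that gives the PCA a
  geography axis; 4 planted divergent loci are absent in species A and at
  frequency 0.96 in species B (the "0 vs 13-or-14-of-14" pattern).
- **Caller noise**: per-method Gaussian breakpoint jitter well inside each
  CI (PE+SR 15 bp, SR 3 bp, RD 100 bp), 5 % false-negative rate per method,
  5 % single-method false positives, 2 % of PE+SR calls below the support
  filter, and 1 % reference-artifact loci emitted with PE+SR and SR signal
  in *every* focal sample (removable only by the ubiquitous filter).
- **Genotyping evidence**: carriers draw 3 + Poisson(5) supporting pairs,
  non-carriers ≤ 2; 1 % of cells flip across the threshold, 1 % are missing,
  and 2 % of loci are high-copy (all supports + 600) to exercise the
  median-support filter.
- **Split reads**: each locus is covered with probability 0.95; covered
  loci get an R1 read plus alternating R2 reads (R2 segments shorter than
  the minimum segment length — loci under ~250 bp — are caught by the R1
  read).

What it does **not** emulate: read-level sequences (no FASTQ/BAM), repeat
content, linked selection, reference bias, or caller-specific systematic
artifacts beyond the declared noise model. Passing tests therefore
demonstrate the pipeline's correctness and calibration under the declared
noise model, not caller performance on real genomes.

## Problem sizes used in tests and the acceptance script

Simulated studies in tests run at desk scale as the package's own choice of
test conditions: genomes of 4–6 chromosomes × 2–4 Mb, 80–250 truth loci,
and the full 34-sample design. The permutation-test calibration uses 200
runs of 1 000 placement iterations (scaled down from the analysis default of
10 000) with 250 loci per run; the outlier-recovery check runs 50 replicates
of 505 loci at the full 10 000 permutations. The acceptance script mirrors
these scales and completes in a few minutes on one CPU.

## Known limitations

- Reciprocal-overlap clustering at 0.9 can split a truth locus detected with
  large read-depth jitter on very small events; the consensus then rests on
  the PE+SR/SR pair (by design — two methods suffice).
- The conservative permutation p-values understate significance at heavily
  tied loci (very rare or very common markers); the randomized variant
  quantifies the gap.
- BEDPE cannot carry read coordinates, so re-imported split reads get
  synthesized read offsets in line order; signatures are preserved, exact
  read-coordinate gaps are not.
- The placement null treats chromosomes as homogeneous; no GC, repeat or
  accessibility stratification.
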