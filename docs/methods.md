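# Methods

This note records the models behind each pipeline, the parameters that
matter (with defaults and why), what the synthetic generators do and do not
emulate, and the numerical choices made where the design was genuinely
open. Every quantitative statement here is recomputed by the test suite or
by `scripts/acceptance.py`; none is asserted from memory.

## Adhesion imaging

**Model.** A scanned agar plate transmits less light where more cells sit,
so cell density is proxied by inverse pixel intensity. Each image is
normalized by its own darkest pixel: density(p) = (white − p) / max(white −
p). Per-image normalization makes pre- and post-wash scans comparable even
when the scanner drifts between scans (occasionally washed colonies scan
slightly darker; ratios above 1 are therefore reported and flagged, never
clipped). The adhesion score of a position is the ratio of its
background-corrected mean density after washing to before washing.

**Layout construction.** The 8×12 grid is built once from an example plate
with growth at every position: row and column sums of the inverted image
are smoothed (Gaussian, σ = pitch/10) and the 8 (or 12) most prominent
peaks are taken as grid lines. Because colony profiles are flat-topped,
each raw peak is refined by an iterated local intensity centroid (3
passes, window = ±pitch/2); peak positions are then regularized to an
equal-pitch grid by least squares, and equal-size boxes are centered on the
grid. Equal box areas keep per-square means comparable; midpoint-tiled
boxes of unequal size biased edge squares by ~3% in development and were
rejected.

**Layout fitting.** The reference layout is fitted to each prewash image
by an exhaustive integer-translation search (default ±20 px) maximizing
total in-box inverse intensity; rotation and scale are not fitted (flatbed
scans are rigid). The score uses boxes shrunk by 10% per side: colonies
sit inside their squares with a margin, so full boxes produce a flat score
plateau around the optimum, while inset boxes peak sharply (sub-pixel-free
fits recover planted shifts exactly on the synthetic benchmark). The
prewash fit is reused unchanged for the paired postwash image — the pair
comes from one physical plate on one scanner and is assumed mutually
aligned. A best offset on the search boundary raises a warning.

**Measurement rules.** Background is the mean density over the plate's
empty (negative-control) squares and is subtracted everywhere; corrected
values are floored at 0 so densities stay in [0, 1]. A position with
prewash density < 0.1 is considered not growing and gets no ratio; a strain
whose mean prewash density is < 0.1 is excluded entirely. Edge colonies
are systematically more adhesive and less reliable, so summaries offer an
interior-only mode that keeps the middle 60 of 96 positions. Pre/post
image folders are paired by identical filenames; any mismatch is an error,
never a guess.

## Flocculation

Flocs sediment and clump, so the optical density of a well measured at
many points (n×n grids, e.g. 15×15 = 225 points) is spatially
heterogeneous. After subtracting the mean OD600 of the negative-control
well (background light absorption of medium and plastic), the score is the
coefficient of variation σ/μ of the readings. The population standard
deviation (ddof = 0) is used — the grid is the complete set of
measurements, not a sample — and is configurable. A well whose corrected
mean is ≤ 0 has no biomass signal to normalize by; its CV is reported
missing and flagged rather than negative. "Normalized optical density"
means background-subtracted OD; no per-well rescaling is applied before
the CV (CV is scale-invariant anyway). A one-hot n×n well has
CV = √(n²−1), ≈ 14.97 for n = 15, which the suite checks to 6 digits.

The filter assay complements the CV: flocs are retained on a coarse
filter while single cells pass, and the flocculating fraction is
OD(B)/(OD(A)+OD(B)).

The scan CSV dialect (one row per well: well id, then n² comma-separated
readings) is this package's own documented fixture format; plate-reader
exports vary by instrument and are trivially converted.

## Screen statistics

* **Strong-adhesion call**: ratio strictly greater than 0.2.
* **Percentile threshold**: linear-interpolation (type-7) percentiles;
  documented because cutoff analogues (e.g. a 95th-percentile value of
  0.086) depend on the convention.
* **Elbow threshold**: sort descending, return the value at maximum
  perpendicular distance to the chord between the first and last points
  (kneedle-style). On a two-component mixture the elbow lands at the
  corner of the null tail, so every strong value sits above it while at
  most ~1% of nulls leak over; degenerate inputs (all equal, linear ramp)
  warn and return the common/middle value.
* **Hit confirmation**: a replicate is valid when pre > 0.1 and
  post > 0.05 (both sufficient for robust quantification); a strain is a
  hit with ≥ 5 valid replicates (default) and mean ratio over valid
  replicates above the cutoff. Whether the mean or every replicate must
  clear the cutoff is genuinely ambiguous; the mean reading is the
  default and a per-replicate mode is provided.
* **Permutation test**: statistic = difference of group means (monotone
  in the t statistic for fixed group sizes under pooled relabeling in the
  equal-variance case; chosen for determinism and speed). All C(n, n₁)
  relabelings are enumerated when they fit the permutation budget,
  otherwise relabelings are sampled; p = (1 + #extreme)/(1 + draws), so p
  is never 0 and the test is valid at finite permutation counts.
  Calibration: empirical size at α = 0.05 over 2,000 null runs (n = 50 per
  group) lies within (0.035, 0.065).
* **Corrections**: Bonferroni (min(1, m·p)) and Benjamini–Hochberg
  step-up q-values (cross-checked against statsmodels in the suite).
* **Size factors**: median-of-ratios — per sample, the median over genes
  (nonzero in all samples) of count / geometric-mean reference. The
  median is taken on the ratio scale, matching the stated formula;
  log-scale medians differ in the 5th decimal at even gene counts.
* **Expression–phenotype correlation**: rank-based (Spearman) by default —
  robust to the nonlinear relation between assay scales — with Pearson
  optional; p-values from the t transform of r with n−2 df; constant
  genes are reported missing and excluded from the FDR.

## Variant consequences

Coordinates follow GFF3 (1-based, inclusive) and VCF (1-based position,
anchored ref/alt for indels, as in "II:2316851 TA > T"). A variant is
mapped into spliced CDS coordinates strand-aware; the edit is applied to
the coding sequence; reference and edited CDS are translated with the
standard nuclear code up to the first stop; protein lengths exclude the
stop. Categories: indels are frameshift iff |Δlen| mod 3 ≠ 0, else
in-frame; substitutions are synonymous / nonsense / missense by protein
comparison. Variants outside the CDS, spanning an exon boundary, or
inserting at an exon edge are conservatively `non_coding` with a warning —
their effect depends on splicing behavior the model does not capture.
When a gene carries several transcripts the longest CDS is used.

Haploid-sequencing QC: heterozygous-flagged calls are artifacts in a
haploid and are dropped. Missing genotypes whose nearest called markers on
both sides carry the same parental label are imputed with that label;
disagreeing flanks and chromosome ends stay missing; imputation is
idempotent and never alters a called genotype (verified against an
independent outward-scan recomputation on random matrices).

The 228→77 aa frameshift worked example runs on a synthetic
reconstruction (`synth.srb11_like_case`): a constructed cyclin-C-like gene
with the same geometry — a 228-codon reference frame and an anchored TA>T
deletion whose shifted frame terminates after exactly 77 residues. The
sequence is not the real genomic sequence (the build environment is
offline); only the coordinate arithmetic and translation geometry are
exercised.

## Random-forest QTL mapping

**Blocks.** After imputation, adjacent markers with identical genotype
columns across all segregants merge into haplotype blocks; residual
missing calls are filled per strain with the nearest called genotype on
the chromosome (the linkage-faithful guess; majority filling was tried and
rejected because it corrupts chromosome-end markers into spurious
singleton blocks). The reduced matrix has one 0/1 column per block.

**Selection frequency.** The importance of a block is the fraction of
trees, over an ensemble of `n_forests × n_trees` bootstrap regression
trees, that split on it at least once. The default tree is a greedy
single-split stump considering every block (`max_depth=1`,
`max_features=1.0`): in the few-block regime this package targets, the
frequency then measures how stably a block provides the best split across
bootstrap resamples. Deep trees with √-feature subsampling — the classic
forest — saturate here: with a handful of blocks nearly every block is
used somewhere in nearly every deep tree, for permuted phenotypes too, and
the statistic loses all contrast (measured during development: planted-QTL
frequency 0.3–0.6 against null maxima 0.6–1.0). For dense panels with
hundreds of blocks the deep/subsampled configuration is the right one and
remains available via `max_depth`/`max_features`/`min_samples_leaf`. For
the default stump configuration on binary blocks the ensemble is computed
exactly in closed form (weighted variance reduction under multinomial
bootstrap weights), which makes 10⁶-tree studies take seconds; every other
configuration uses scikit-learn forests. Identical seeds give identical
profiles; frequencies are invariant under affine phenotype transforms.

**Significance.** The null re-computes selection frequencies under random
phenotype permutations (label shuffling — chosen over data bootstrapping
as the stated significance mechanism; a per-permutation single 100-tree
forest keeps large nulls affordable at the cost of a slightly wider,
conservative null). Per block, p = (1 + #{null ≥ observed})/(1 + n_perm),
Bonferroni-corrected by the block count. Since the smallest attainable p
is 1/(n_perm+1), genome-wide significance requires
n_perm > n_blocks/α (`min_permutations`); `map_qtl` warns when the budget
cannot clear that bar.

## Synthetic study conditions

All generators are deterministic given their seed and emit sidecar truth
tables that fully determine expected downstream output.

* **Plate pairs**: 96 positions on a 36-px pitch, each a 7×7 arrangement
  of 4-px colony patches (≈60% square coverage, as pinned colonies leave a
  margin), per-patch darkness jitter (σ = 3%) shared between pre and post
  so planted ratios are exact pre-noise, background inverse intensity
  10/255, colony amplitude up to 240/255, Gaussian pixel noise σ = 3/255,
  1-px soft blur. A 6×6 black fiducial in the margin moves rigidly with
  the plate and pins per-image max normalization, playing the role of the
  dark plate rim in real scans. Not emulated: vignetting, glare, colony
  morphology, rotation/scale misalignment — so passing recovery tests
  demonstrates the segmentation/normalization arithmetic, not robustness
  to optical artifacts.
* **Well scans**: baseline 0.5 OD per well plus background 0.05 and noise
  σ = 0.01; three clumps per well each adding `clump_parameter × baseline`
  (±20%) at random grid points, so the CV grows monotonically with the
  parameter. The control well contains background only.
* **Cross**: 100 segregants, 200 markers on 3 chromosomes (80/70/50,
  2.5 kb spacing), per-interval recombination 5×10⁻⁵, one QTL of effect
  2 phenotype-SD, phenotype noise SD 1, 2% missing calls. The low
  recombination makes markers collapse to ~3–7 blocks genome-wide,
  emulating SNP sets in tight linkage; it also keeps the 200-permutation
  significance study self-consistent with the n_perm > n_blocks/α rule
  (at real-cross block counts, hundreds of blocks would require >10⁴
  permutations, which is what the 16,060 worked example expresses).
  Detection is measured as the planted block being Bonferroni-significant;
  rare seeds where an almost-identical sibling block absorbs the signal
  count as misses.
* **Toy genome**: 3 chromosomes, 12 genes on both strands (single- and
  two-exon, 60–200 codons), ≥ 200 variants (SNPs, 1-bp and 3-bp indels
  strictly inside exons, intergenic SNPs) labeled at construction time by
  direct genome surgery — the chromosome string is edited, intervals are
  shifted, and the re-spliced CDS translated — an independent code path
  from the caller's CDS-space editing, so agreement is a genuine
  cross-check of the coordinate arithmetic.
* **Screen**: 3,600 strains × 6 replicates, 5% planted adhesives
  (ratio 0.30 ± 0.05 vs 0.03 ± 0.012 residual), prewash density
  0.45 ± 0.10 with 2% failed pinnings.

## Known limitations

* Translation-only layout fitting; a plate scanned at a different
  resolution or rotated needs external registration first.
* The consequence caller handles one variant at a time; compound variants
  in one codon and splice-site disruptions are out of scope.
* Selection-frequency importance is regime-dependent (see above); no
  explicit epistasis statistic is computed — interactions influence tree
  structure only.
* The permutation null re-uses the observed group sizes and assumes
  exchangeability under the null; strong variance heterogeneity between
  groups distorts the test as it does any pooled relabeling scheme.
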