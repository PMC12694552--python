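# Methods

## Grain phantom

A grain is modeled as nested ellipsoidal solids, matching the anatomy
visible in micro-CT reconstructions of hulled grass grains: an outer hull
shell of constant thickness, an air shell (the cavity) of constant gap,
and an inner caryopsis ellipsoid split into an embryo polar cap and
endosperm. The embryo occupies a stated fraction of the caryopsis long
axis at the +z pole; the caryopsis coat is not modeled as a separate
tissue (it is poorly contrasted in real scans and its voxels are absorbed
into endosperm). Voxel labels are assigned at voxel centers, so volumes
converge to the analytic ellipsoid-shell values as the voxel size shrinks.

Intensities are per-tissue means plus seeded Gaussian noise clipped to the
bit range. The default ordering is cavity < hull < endosperm < embryo
(air darkest); it is a modeling choice, user-overridable together with the
segmentation `TissueRule`. Default 16-bit means are 4000 (background air),
7000 (cavity), 26000 (hull), 44000 (endosperm), 58000 (embryo) — gaps of
4σ or more at the 5% noise level used throughout, the regime in which a
global threshold plus edge-guided region growing is the appropriate tool.

**Scale.** The default phantom has semi-axes 300/240/190 µm, hull 12 µm,
cavity gap 15 µm, embryo fraction 0.22, at 3 µm voxels — a ~210×170×140
voxel stack. This is a ~0.4× linearly scaled grain at the real scanning
resolution: it preserves the population's volume-ratio structure (embryo
≈ 0.09, endosperm ≈ 0.60, cavity ≈ 0.16, hull ≈ 0.15 of whole-grain
volume) while keeping a full segmentation + morphometry pass at a few
seconds per grain, which is what makes cohort-level testing practical.
A full-size grain (~3 mm³) at 3 µm would be ~200M voxels per grain and
adds nothing methodologically: every estimator is scale-equivariant and
is validated for convergence on analytic solids.

**Cohorts.** `make_phantom_cohort` draws one lognormal size factor per
grain with CV = `variation_cv` applied to volume (semi-axes scale by its
cube root), so the ground-truth K-Volume CV equals `variation_cv`
directly; hull thickness and cavity gap draw independent lognormal factors
with the same CV. In the pipeline's simulate stage an additional per-line
linear-size factor is driven by the standardized genetic value of the
planted locus (`geometry_coupling_cv`), which is what makes the measured
traits genuinely heritable.

What the phantom does **not** emulate: partial-volume blur at tissue
interfaces, beam hardening, ring artifacts, hull ornamentation, and the
caryopsis coat. Passing tests therefore demonstrate correctness of the
segmentation/morphometry machinery under controlled contrast and noise,
not robustness to every artifact of real scans.

## Segmentation

The chain is Otsu → per-slice Canny → 3D region growing → tissue pooling
→ overrides.

- **Otsu.** Implemented directly (histogram with `histogram_bins` bins,
  between-class variance σ²_b(t) = ω₀ω₁(μ₀−μ₁)², argmax over bin edges,
  ties to the lowest threshold, class 0 = intensities ≤ threshold), so
  tests can require exact agreement with an exhaustive-search oracle. The
  threshold's only pipeline role is background identification.
- **Canny.** `skimage.feature.canny` supplies the standard four stages;
  the `canny_low_frac`/`canny_high_frac` parameters are fractions of the
  maximum smoothed-Sobel gradient magnitude, converted to the absolute
  thresholds skimage expects. Edges are detected per slice (2D), matching
  how CT cross-sections are processed, and stacked into a 3D barrier mask.
- **Region growing.** Deterministic flood fill (numba kernels): seeds in
  lexicographic (z,y,x) order, FIFO queue, a voxel joins if connected
  (6/26), non-barrier, and |intensity − region running mean| ≤
  `growth_tolerance` (default 7000 ≈ 2.1σ at 5% noise — small enough that
  adjacent tissues separated by ≥ 14000 cannot merge through the
  barrier-free z-direction, large enough to keep fragmentation low).
  Barrier voxels and fragments below `min_region_vox` (27 = a 3³ speckle)
  are merged into the adjacent region with nearest mean intensity.
  Growth is 3D by default for cross-slice label coherence; `grow_2d`
  restricts moves to within-slice for strict per-slice fidelity.
- **Tissue pooling.** Background = face-touching regions with mean below
  the global Otsu threshold. The remaining regions are partitioned into
  four contiguous intensity bands by an exact weighted 1-D
  dynamic-programming split of the sorted region means (minimizing
  within-band weighted SS — the multi-class Otsu objective evaluated on
  region statistics; a histogram-based multi-Otsu can misplace cuts when
  the foreground histogram is a few isolated spikes). Bands map to tissues
  via `TissueRule.ordering`.
- **Topology checks.** A cavity component in substantial contact with
  background is outside air and becomes background; embryo/endosperm
  components in substantial contact with background become hull. "In
  substantial contact" means >10% of the component's voxels touch
  background: a single noise-breached pinhole through the thin hull must
  not evict the genuine cavity.
- **Overrides** reproduce the capability of manual threshold adjustment:
  ordered (intensity-range, from-label, to-label) reassignments, validated
  against contradictory overlaps, idempotent on reapplication.

## Morphometry

- Volumes: voxel count × (voxel edge)³. The whole grain K is the union of
  the four tissues, so ratios sum to exactly 1. (Commercial workflows that
  leave the thin caryopsis coat unsegmented report ratio means summing to
  slightly under 1, ~0.99; the exact-partition convention is used here.)
- Surface areas: marching cubes at level 0.5 on the mask cropped to its
  bounding box and Gaussian-smoothed with σ = 1 voxel. Meshing the raw
  binary overestimates a smooth surface by ~9% (staircase facets); with
  smoothing the digitized r = 300 µm sphere at 3 µm voxels is recovered to
  ~0.3%. Regions too small to survive smoothing are meshed on a
  2×-upsampled binary instead. A shell contributes inner + outer surface.
- Hull thickness: Euclidean distance transform of the hull mask sampled at
  its local maxima (26-neighbour plateaus included), doubled and scaled to
  µm — the local-thickness (largest-inscribed-sphere) estimator. On a
  30 µm shell at 3 µm voxels it is accurate to ~1%; on slabs of odd voxel
  thickness it can read one voxel high (distances are measured to
  background voxel centers). H-A-T is reported in µm (values of tens of µm
  are only plausible in that unit).

## Trait statistics

Sample SD (n−1); CV = 100·SD/mean; adjusted Fisher–Pearson G1 and
bias-corrected excess kurtosis G2 (`scipy.stats.skew/kurtosis` with
`bias=False`) — the conventions of mainstream statistics packages;
Shapiro–Wilk from scipy. The normality *screen* (|G1| < 3 and |G2| < 10)
is reported separately from the formal test, because moderately skewed
phenotypes routinely fail Shapiro–Wilk at n = 100 while remaining
acceptable for linear QTL models. Correlations are Pearson on complete
cases with two-sided t-test p-values.

## QTL mapping (ICIM-ADD)

Genotypes are coded A → +1, B → −1 (fully inbred RILs, no heterozygote
class), missing values mean-imputed per marker for selection.

1. **Cofactor selection.** Forward–backward stepwise regression: at each
   step the candidate marker with the smallest partial-F p-value enters if
   p ≤ PIN (default 0.01); included markers with partial-F p > POUT = 2·PIN
   are removed. Ties break toward map order, duplicated (cosegregating)
   markers select once. Deterministic.
2. **Scan.** On a step-1-cM grid (marker positions included), the
   phenotype is adjusted by all selected cofactors *except* those on the
   two markers flanking the scanned interval (the ICIM background
   control). The expected QTL dosage given the flanking genotypes treats
   the chromosome as a two-state Markov chain in RIL recombination
   fractions, R = 2r/(1+2r) with Haldane r; at a marker position the
   dosage reduces exactly to the marker codes, so the LOD equals the
   single-marker regression LOD there (tested). LOD =
   −(n/2)·log₁₀(1−ρ²) from the simple regression of adjusted phenotype on
   dosage — the Haley–Knott regression approximation; the EM mixture
   refinement of full ICIM is omitted as the regression form is standard
   and adequate at RIL scale.
3. **Calling.** Peaks are local maxima above `lod_min` = 2.5; peaks within
   20 cM merge (higher kept). The support interval spans the outermost
   grid positions with LOD ≥ peak − 2; physical intervals come from
   piecewise-linear cM→Mb interpolation of the map, clamped at chromosome
   ends. PVE = 100·(1 − RSS₁/RSS₀) at the peak on the adjusted phenotype;
   Add = half the difference of raw phenotype means between imputed
   genotype classes, parent-A allele positive (a convention; reported
   effect signs are only meaningful relative to it). Loci are named q +
   trait initials +
   chromosome (qKV2 = K-Volume on chromosome 2).
4. **Permutation threshold.** The phenotype is permuted (seeded), the
   *entire* procedure (selection + scan) re-runs per permutation, and the
   (1−α) type-7 quantile of the genome-wide max LOD is returned. Both
   thresholds are surfaced: calls use the fixed 2.5 rule, the permutation
   threshold is reported alongside. Under the null the permutation
   distribution has a heavy right tail (occasional runaway stepwise
   selection inflates LOD at cofactor intervals), so the permutation
   threshold is conservative; genome-wide type-I error at α = 0.05 is
   controlled (tested: false-call rate ≤ 10% over 50 null replicates).

**Simulation contract.** `simulate_ril_population` scales the noise so
the *realized* genetic-variance fraction equals the target heritability:
the noise draw is orthogonalized against the genetic values in-sample and
rescaled to the exact variance ratio. Power statements at "planted PVE
15%" therefore test the mapping method at that operating point rather
than the compound lottery of method noise plus simulation drift.

## Candidate genes

DEG filter: |log₂FC| ≥ 1 (inclusive) AND raw p < 0.05 (exclusive), raw
rather than adjusted p as that is the thresholding rule being reproduced.
Gene position is a single Mb midpoint; QTL intervals are closed at both
ends. One record per (gene, locus) pair; non-overlapping chromosome id
sets raise a naming-mismatch warning.

## Problem sizes and numerical choices

- Default phantom ~5M voxels: segmentation ≈ 3 s/grain, full trait set
  ≈ 3 s/grain (single CPU). The bundled study uses 40 lines at a mid-size
  phantom; the QTL power/calibration experiments use n = 100 lines,
  9 × 100 cM chromosomes, markers every 5 cM, 50 replicates, 200
  permutations — a deliberate scale-down of the conventional 1000
  permutations for the replicated calibration experiments (the threshold
  estimate's quantile noise at 200 is already well inside the ±10% band
  being tested; single production runs default to 1000).
- Region means and DP pooling are exact arithmetic on float64; ties in
  Otsu and stepwise selection break deterministically (lowest
  threshold/index); the region grower's seed order is lexicographic, so
  all segmentation outputs are bit-reproducible.
- Degenerate inputs raise typed `DomainError`s: constant volumes (no
  contrast), all-barrier masks (no seed), geometries whose tissues vanish
  at the voxel size, zero-variance phenotypes, heritability 1 with no
  genetic variance.

## Known limitations

- The phantom's sharp interfaces make segmentation easier than real CT
  with partial-volume blur; Dice near 1.0 here is an upper bound, not a
  field expectation.
- The thickness estimator inherits a ±1 voxel quantization; hulls thinner
  than ~3 voxels are at the edge of its validity.
- ICIM here is the regression (Haley–Knott) form; LOD values can differ
  slightly from mixture-model implementations, most visibly at low
  heritability.
- The permutation threshold's conservatism under heavy stepwise selection
  means real loci near the threshold may be retained by the fixed 2.5
  rule but not by the permutation rule at small n; both numbers are
  always reported.
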