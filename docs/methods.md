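# Methods

## Scene segmentation

The acquisition protocol fixes most of the imaging problem: dark, matte
leaf sheaths lie flat on a near-white board, so segmentation is a
dark-foreground problem.  The color image is converted to luminance with
the BT.601 weights (0.299, 0.587, 0.114) and thresholded adaptively: a
pixel is foreground iff it is darker than the mean of its `window_px`
square neighbourhood by more than `offset` gray levels.  Defaults are
`window_px = 101`, `offset = 10`; the window must exceed the thickness of
every object of interest (sheath width, marker diameter, checker height)
so that each object's neighbourhood always samples board background.  For
objects thicker than the window only the rim is guaranteed, so connected
components are hole-filled by default before measurement.  On two-level
images this rule selects the same pixels as global Otsu thresholding away
from a one-pixel boundary band, which the tests use as an independent
oracle.

Components smaller than `min_area_px = 500` px² are discarded: the
protocol pins sheaths to the board, and pins, pin shadows and dust are
far below this size at typical resolutions while the smallest sheath is
far above it.

Boundaries are traced with marching squares at the 0.5 level and
simplified by Douglas–Peucker at 1 px tolerance.  The simplification
matters: the raw staircase polygon overestimates the perimeter of smooth
shapes by ~5–6 %, while the simplified polygon is within ~1 % for disks,
rectangles and trapezoids at the scales used here.

**Role classification.**  The scale marker is the contour with
circularity 4πA/P² ≥ 0.85 (a digital disk measures ≈ 0.99, a sheath
≈ 0.2–0.7) and a near-uniform interior (gray SD ≤ 25).  The checker is
the contour whose bounding box, split into a small grid (2–6 rows by
2–6 columns, best split wins), yields at least 6 cells that are
internally uniform (SD < 12) while their means spread by more than 20
gray levels; a uniform sheath or the marker fails the inter-cell spread,
a textured region fails the within-cell uniformity.  Each role is
assigned at most once; ties go to the best score with a warning.  All
remaining contours are sheaths.

A missing marker degrades gracefully: traits are emitted in pixel units
and every trait vector carries a `units` flag (`cm` or `px`).  The pixel
density is px/cm = 2 r / d with r the marker's equal-area radius and d
its configured physical diameter (`marker_diameter_cm`, default 2 cm).
White-balancing against the brightest gray checker patch is implemented
but off by default, since nothing in the acquisition protocol requires
it and it would alter color traits.

## Organ dissection

The largest sheath contour is the sixth leaf sheath (at V6 the newest
fully expanded sheath is the largest).  Every other contour is tested in
descending area order: it must be elongated — minimum-area *rotated*
bounding rectangle length/width ratio strictly greater than
`ratio_min = 3.0` — and its centroid must lie strictly within
`dist_factor = 0.5` times the sixth sheath's box length of the sixth
centroid.  Contours failing either test keep a generic "other sheath"
label and still contribute to all whole-plant aggregates.  The rotated
(rather than axis-aligned) rectangle is used because sheaths lie at
arbitrary angles on the board.  Ties in maximal area break to the lower
contour index; both thresholds are strict inequalities.  A trace records
the centroid (`C_cdit`), distance (`D_cent`), ratio and decision for
every candidate, so each labeling is auditable.

**Bounding-rectangle estimation.**  For rasterized contours the rectangle
is fitted to the convex hull of the pixel centers and widened per
dimension by (|cos φ| + |sin φ|)/2 at the fitted orientation φ — the
midpoint between the pixel-center support and its Minkowski sum with the
unit pixel square, between which the continuous shape must lie.  This
estimator depends only on the pixel set, so it is exactly equivariant
under 90° image rotations, and its worst-case error is half a pixel per
side (≤ 2 % for the ≥ 40 px widths measured here).

## Traits

Exactly 85 image traits per sample:

| scope | morphology | color |
|---|---|---|
| whole plant (suffix `_SS`) | 18 = 4 size measures × {Avg, Sd, Sum} + 3 shape measures × {Avg, Sd} | 30 |
| sixth sheath (suffix `_S0`) | 7 raw measures | 30 |

Size measures are Area, Length, Width, Perimeter (cm when calibrated);
shape measures are the dimensionless L/W ratio, compactness P²/(4πA)
(1 for a disk) and rectangularity A/A_box (1 for a rectangle).  `Sd` is
the sample standard deviation across sheaths, defined as 0 for a single
sheath.

The 30 color traits per scope are the mean and pixel-level sample SD
(suffix `_S`) of the raw R, G, B channels and of 12 comprehensive
indices.  ExG = 2g − r − b, ExR = 1.4r − g, ExB = 1.4b − g,
ExGR = ExG − ExR operate on chromatic coordinates r = R/(R+G+B) etc.;
CIVE = 0.441R − 0.811G + 0.385B + 18.78745 operates on the raw 8-bit
channels (pure green evaluates to −188.01755); VARI, NGRDI, GLI, MGRVI,
RGBVI, IKAW and RGRI are ratio indices on raw channels.  Every ratio
index returns 0 on a zero denominator (the guard count is tracked for
diagnostics).  The index roster is a registry and can be replaced from
configuration.  Whole-plant color is computed over the pooled pixel union
of all sheath contours, and `_S` denotes dispersion across *pixels* (not
across sheaths) in both scopes — the two conventions the design left
open.

Trait names are scoped (`CIVE_SS` vs `CIVE_S0`, `T_Length_Avg_SS` vs
`T_Length_S0`) so the 85 names are unique; a registry table maps every
name to its object scope, category and aggregation.

With manually weighed `DryWeight` and `FreshWeight` (grams) the
assembled table has 87 trait columns plus sample/line/replicate/
subpopulation metadata.  Accuracy of the imaging pipeline is validated
by ordinary least squares of each weight on the total image-derived
sheath area (`T_Area_Sum_SS`); the reported R² measures how well a
single photograph predicts destructive biomass.

## Phenotype statistics

**Correlation and clustering.**  Pairwise-deletion Pearson correlation
with two-sided p-values; constant columns are recorded as undefined.
Traits are grouped by partition-around-medoids on the distance
d = 1 − r, with k chosen over a range (default 2–10) to maximize the
average silhouette width — the pamk behaviour.  PAM uses the
deterministic BUILD + SWAP algorithm (ties to the lowest index), so the
grouping is reproducible without a seed; an average-linkage dendrogram
on the same distance is emitted alongside for plotting.  Because d
depends only on r, the grouping is invariant to affine rescaling of any
trait.

**Subpopulation ANOVA.**  One-way ANOVA per trait across the germplasm
subpopulations (NSS, SS, TST, Mixed), with Tukey HSD pairwise
comparisons at α = 0.05 as the post-hoc method; per trait the number of
subpopulations each group differs from is tabulated.  Subpopulations
with fewer than two samples are dropped with a warning.  Under a null
simulation the type-I rate at α = 0.05 is calibrated (5 % ± 2 % over
1,000 traits in the acceptance suite).

**PCA.**  Columns are standardized (zero mean, unit population SD);
constant columns are dropped with a warning.  Variance fractions sum to
1 and the loadings are orthonormal, so the standardized matrix is
reconstructed exactly from all components.  An optional mode partitions
the samples into two groups by PAM on the first two scores and reports
the average silhouette width.

**Heritability.**  Inbred lines are genetically homogeneous, so the
between-line variance of replicated measurements is genetic.  A one-way
random-effects decomposition with line as the random factor gives
σ²_e = MS_within and σ²_A = max(0, (MS_between − MS_within)/n₀), with
n₀ = (N − Σn_i²/N)/(a − 1) the effective replicate number for unbalanced
designs; H² = σ²_A/(σ²_A + σ²_e), clamped to [0, 1] and defined as 0
when both components vanish.  Note the denominator is σ²_A + σ²_e (not
σ²_A + σ²_e/r): H² here is the repeatability of a *single* measurement,
the convention adopted throughout.  Method-of-moments is used for all
designs; a REML fallback was considered and dropped, as the n₀-corrected
moment estimator recovers the generating H² within ±0.05 at 400 lines ×
3 replicates even with a third of the replicates deleted, and a second
estimator would add a code path without adding accuracy at these sample
sizes.  All lines having a single replicate is an error (σ²_e is then
inestimable).

**Key-trait selection.**  Traits with H² above the threshold (default
0.3) are screened for genetic mapping.  Morphology and biomass
survivors are kept as-is; the many surviving color traits are reduced
per object scope by standardized PCA, and the first two score vectors
per scope are appended as pseudo-traits (`Sum_PC1`/`Sum_PC2` for the
whole plant, `Sixth_PC1`/`Sixth_PC2` for the sixth sheath).  A scope
with fewer than two surviving color traits contributes no components
(warning).  The selection is a pure function of the H² table, the
threshold and the trait matrix.

## GWAS post-processing

The six multi-locus association methods themselves (mrMLM, FASTmrMLM,
FASTmrEMMA, ISIS EM-BLASSO, pLARmEB, pKWmEB) are external; this package
consumes their result tables (TSV with columns snp_id, chrom, pos,
trait, method, p_value, effect, pve).

* **Genotype filters:** minor allele frequency strictly above 0.05 and
  call rate strictly above 0.9, computed from 0/1/2 dosages with
  missing calls excluded.  Genotypes load from TSV or VCF (GT field).
* **Significance:** two-step screen, p ≤ 0.5/N genome-wide (N the total
  SNP count; at N = 794,722 the effective cutoff is 6.29e-7) followed by
  the final threshold p ≤ 2e-4.  Both thresholds are configurable and
  the effective cutoff is reported.  Non-positive p-values are rejected
  as malformed.
* **Consensus:** per trait and method, Top1 is the minimal-p record
  (ties to the lower (chrom, pos)); `multi` holds SNPs reported by ≥ 2
  distinct methods for the same trait; `high_confidence` is their
  union and `both` their intersection.
* **Annotation:** genes from a GFF3 whose 1-based inclusive span
  contains the SNP are `within` hits at distance 0; genes within
  `window_bp` (default 10 kb, the window the upstream annotation tool
  left unstated) on either side are `upstream`/`downstream` hits at
  their bp distance, all ordered by distance then gene id.  Strand is
  ignored: "upstream" means the SNP precedes the gene start in genome
  coordinates.  Chromosomes absent from the annotation yield empty hit
  lists with a warning.
* **Network:** trait–gene edges from the consensus SNPs' annotations and
  optional gene–pathway membership edges, exported as deduplicated
  node/edge CSV tables and SIF.

All stages are deterministic: identical inputs and configuration give
byte-identical outputs.

## Synthetic data

`generate_scene` rasterizes a vector scene — white board (RGB 245),
one gray disk marker, one 4×6-cell checker with a dark six-color
palette, and sheaths drawn as tapered quadrilaterals (center, length,
end widths, angle) — by filling pixels whose centers fall inside each
shape, with no anti-aliasing, then adds optional seeded Gaussian pixel
noise (default SD 2, mild sensor noise).  Ground truth (shoelace areas,
perimeters, minimum-rectangle dimensions, centroids, expected organ
labels, implied px/cm) comes from the vector geometry *before*
rasterization, so segmentation accuracy is measured against an
independent analytic answer; pixel-center coverage keeps raster areas
within 2 % of the shoelace areas for shapes ≥ 5,000 px².  Overlapping
shapes or sheath fills lighter than the board violate the scene
contract and raise.  The default scene (900×620 px, marker radius 45 px,
six sheaths with one dominant) mimics a real acquisition layout at
reduced resolution so a full extraction runs in well under a second.

`simulate_phenotypes` draws y_ij = μ + a_i + e_ij with a_i ~ N(0, σ²_A)
and e_ij ~ N(0, σ²_e) — the exact model under which H² = σ²_A/(σ²_A +
σ²_e) — for a chosen number of lines and replicates, assigning lines to
the four subpopulations with panel-like proportions (124:31:164:99).
`simulate_association_tables` lays planted significant SNPs over a
Uniform(0,1) p-value background per method.

What the generators do *not* emulate: lighting gradients and shadows,
lens and perspective distortion, overlapping or touching sheaths,
texture and venation, genotype-phenotype linkage (phenotypes and
association tables are simulated independently), and linkage
disequilibrium.  Passing tests therefore demonstrate the correctness of
the measurement and statistical machinery under the stated acquisition
contract, not robustness to poorly controlled photography.

## Problem sizes

Scenes are rendered at 900×620 px (a ~6× linear reduction of a full
camera frame) with object thicknesses scaled to stay below the
threshold window.  Statistical checks use 400 lines × 3 replicates for
heritability, 1,000 simulated traits for ANOVA calibration, n = 5,000
for the PCA closed form, and toy panels (thousands of SNPs, a handful
of genes) for the GWAS oracles — sizes at which every published
formula's expected value is recoverable to the tested tolerance while
the whole suite runs in seconds to minutes.
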