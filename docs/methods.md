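# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `histoquant`, and what the passing test suite
does and does not demonstrate about real tissue.

## Optical-density model and color deconvolution

Brightfield absorption is modeled as Beer–Lambert mixing in optical
density: `OD_c = -log10((I_c + 1)/I0_c)` with per-channel background
`I0_c` and an intensity offset of ε = 1 gray level inside the logarithm
to keep OD finite at `I = 0`. Negative OD (pixels brighter than the
background) is clamped to zero. The forward model used for synthesis is
the exact inverse, `I_c = I0_c · 10^(-Σ_s a_s V_sc) − 1` plus optional
Gaussian read noise, rounded to 8 bits. Writing the forward model with
the same ε makes forward → inverse round trips limited only by 8-bit
quantization (≈ `0.5 / ((I+1)·ln 10)` OD, i.e. worst at the darkest
pixels); without it the ε mismatch alone contributes ~0.017 OD at OD 1,
larger than the quantization bound the tests assert.

Deconvolution solves `a = (Mᵀ)⁻¹ OD` where M's rows are unit stain
vectors. Default H-DAB vectors are the Ruifrok–Johnston values,
hematoxylin (0.651, 0.701, 0.290) and DAB (0.269, 0.568, 0.778).
Two-stain profiles are completed with a third *residual* vector, the
normalized cross product of the two stains. The residual keeps its mixed
signs: forcing it into the positive orthant (as one might by analogy
with real stains) makes the matrix nearly singular and amplifies read
noise into concentration swings of ±10; only genuine stains are required
to have non-negative components. Concentrations are not clamped at
deconvolution time — clamping at zero happens where intensity statistics
are computed, so tests can see the raw algebra.

Stain-vector estimation is Macenko-style: stained pixels
(`‖OD‖ > 0.15`) are projected onto the plane of the top two singular
vectors, and the directions at the 1st/99th percentile of the angular
distribution are taken as the pure-stain extremes. Names are assigned by
minimal total angle to the reference vectors, which makes the assignment
invariant to which stain dominates the region. Fewer than 100 stained
pixels is an error. Background estimation averages each channel over the
pixels in the top 5% of luminance; because that is a tail selection, read
noise biases it upward by roughly two noise standard deviations — ±2 gray
levels of accuracy should be expected at realistic noise, not exactness.

## TMA dearraying

The slide overview (cores 20–100 px across) is thresholded by Otsu on
inverted luminance, opened at radius diameter/8, and connected
components within [0.2, 2.0]× the nominal core area become candidate
cores. Their centroids are clustered into rows and columns by 1-D
sorting with a new cluster opened whenever the gap to the running
cluster mean exceeds 0.6× the median nearest-neighbor spacing; per-row
and per-column medians define a regular grid, detected cores snap to
their nearest cell, and unfilled cells are materialized as cores flagged
`missing` at the interpolated position (grids stay rectangular for
export). Labels are rows A.. top-to-bottom, columns 1.. left-to-right.
Row-clustering instability under ±10% gap changes triggers a warning.
Rotated or sheared grids are out of scope.

## Cell detection

Fast counting deconvolves, smooths the chosen detection channel
(hematoxylin, or hematoxylin + DAB where the chromogen displaces the
counterstain) with a Gaussian of σ = 1.5 µm, and takes local maxima
above 0.1 OD with ≥ 4 µm separation; a peak is positive when the
smoothed DAB there exceeds 0.2 OD.

Full detection thresholds the same smoothed image, splits touching
nuclei by watershed seeded at the smoothed maxima, and then refines each
nucleus to its half-maximum contour: for a step-edge nucleus blurred by
a symmetric Gaussian, the half-max level crosses exactly at the true
boundary, so this undoes the systematic dilation a fixed low threshold
applies to smoothed objects (without it, nuclear areas run ~2× high).
Nuclei outside [5, 400] µm² are dropped. Cells are the nuclei expanded
by 5 µm under a nearest-nucleus (Euclidean Voronoi) constraint
(`expand_labels`), so cell polygons are pairwise disjoint and meet at
perpendicular bisectors.

The 33-measurement catalog is six morphology measurements for the
nucleus and for the cell (area, perimeter, circularity = 4πA/P² capped
at 1, moment eccentricity, max/min Feret calipers on the convex hull),
the nucleus/cell area ratio, and {mean, sd, min, max, range} of the
clamped hematoxylin and DAB concentrations over nucleus and cell pixels.
The identity of the full catalog beyond the four canonical measurements
(nucleus area, circularity, per-stain staining intensity, nucleus/cell
ratio) is this package's choice. Local density counts neighboring cell
centroids within 25 µm per mm². Smoothed features are the
Gaussian-weighted *mean* over neighbors within 3σ (σ = 25 µm default),
including the object itself: the normalized form is a convex combination
(sharp test bounds) and does not confound neighborhood density with the
feature value; `normalized=False` gives the literal weighted sum. All of
these defaults are exposed in `DetectionParams` / workflow config.

## Superpixels and texture

SLIC (localized k-means in CIELab + position, via scikit-image, masked
to the annotation, grid spacing 50 µm, compactness 10) is followed by an
in-package post-pass that splits any 4-disconnected label and merges
fragments below a quarter of the median area into their largest
4-adjacent neighbor, so the partition and 4-connectivity invariants hold
by construction. Each superpixel gets a saturation-weighted circular
mean hue (gray superpixels report 0 with a flag) and the 13 classical
Haralick statistics of a symmetric, normalized co-occurrence matrix
accumulated at distance 1 in four directions over pixel pairs that both
lie inside the superpixel, averaged across directions. Quantization is
32 levels over a fixed OD range [0, 2.5] on the mean-OD plane, keeping
features comparable across images and stains. Correlation (and the
information measures) are reported as 0 for constant patches where they
are undefined. Sum variance is centered on the sum average; entropies
use the natural logarithm.

## Classification and scoring

The random-trees classifier is a seeded scikit-learn random forest (100
trees, unlimited depth, √p features per split, bootstrap with
out-of-bag accuracy reported). The default tumor-cell feature list is a
16-measurement subset (4 nucleus shape, nucleus/cell ratio, 5 nucleus
hematoxylin stats, 3 nucleus DAB stats, 2 cell DAB stats, local
density) plus the smoothed counterparts — overridable, since the
empirically chosen subset used in practice is not fixed by any
specification. Intensity sub-classification applies fixed thresholds to
one measurement, gated on a base class; boundary values take the lower
grade everywhere in the package (sub-classification and survival
cutoffs alike). Default thresholds are placeholders that users calibrate
per stain batch, as in real IHC practice.

Scores follow the standard definitions: positive density
(positives/mm²), H-score (1·%weak + 2·%moderate + 3·%strong over graded
tumor nuclei), percent positive (exclusion class removed from the
denominator), TSP = AS/(AE+AS)·100 over classified superpixel areas with
non-tissue area ignored. Degenerate cores (no tumor cells, zero tissue)
yield flagged-invalid scores rather than exceptions so batch runs
complete; patient scores are medians over valid cores (mean of the
middle two when even).

## Survival

Kaplan–Meier uses the product-limit estimator with events preceding
censorings at tied times; the log-rank test accumulates hypergeometric
score and variance at each event time and refers `U'V⁻¹U` (first G−1
groups) to χ²(G−1), with no continuity correction. Both match lifelines
to ~1e-14 on simulated data; the null rejection rate at α = 0.05 over
1000 exponential replicates falls in [0.03, 0.07]. Stratification
supports median, tertile and custom cutoffs (e.g. H-score 10/160 for
separating aberrant-negative, wild-type and aberrant-positive tumors).

## Synthetic study conditions

The generators emulate the acquisition conditions of a scanned colon
cancer TMA cohort: 1 mm circular cores, 0.25 µm/px scan resolution (the
spec default), jittered rectangular grids, and H-DAB or H&E staining
rendered through the same Beer–Lambert forward model the analysis
inverts. IHC cores place non-overlapping elliptical nuclei (radius
N(3, 0.4) µm, ≥10 µm center separation) with class-dependent
hematoxylin/DAB absorbances (default 70% negative / 30% positive,
DAB N(0.05, 0.02) vs N(0.8, 0.1)) over a faint 0.05-OD cytoplasmic haze,
plus Gaussian read noise (sd 3 gray levels). H&E sections carve
epithelium/stroma/other compartments from thresholded Gaussian random
fields (the stroma share among tissue is set by quantile, so the true
TSP matches the target to <0.5 points), render epithelium as dense round
hematoxylin nuclei over an eosin ground and stroma as sparse elongated
eosin fibers. Survival tables are exponential with independent
exponential censoring.

Tests and the acceptance checks run these generators at reduced spatial
scale — 300–500 µm cores at 0.5–1 µm/px and 384–512 px sections at
2 µm/px — which preserves every contract being tested (counts, areas in
physical units, scores) while keeping the default suite fast; the
generator defaults remain the full-scale conditions.

What the synthetic data does **not** contain: overlapping and clumped
nuclei, stain-vector variation within a slide, uneven illumination,
tissue folds and artefacts, scanner-dependent point-spread functions, or
biologically realistic spatial correlation between marker expression and
morphology. Passing recovery tests therefore demonstrates correctness of
the algorithms under their stated model, not segmentation performance on
difficult real tissue; on real cohorts the interactive steps the
workflows assume (threshold calibration, classifier training, grid
review) remain essential.

## Numerical conventions

- Coordinates are continuous 0-based pixels, x right / y down; physical
  quantities convert through the isotropic pixel size at measurement
  time.
- Spatial containment (queries, training-label inheritance, core
  assignment) is by ROI centroid, so each object contributes to exactly
  one region.
- Query results and batch outputs are ordered by insertion id; reruns
  with identical inputs are byte-identical, and per-image tasks are
  independent of execution order.
- Forward/inverse stain accuracy is bounded by 8-bit quantization; tests
  assert 1e-2 on fields with OD ≤ ~0.8 and 2e-2 where synthetic
  absorbances approach OD 1.
- GeoJSON round trips are vertex-exact; ellipse/rectangle ROIs carry
  their exact parameters in feature properties alongside a polygon
  approximation for interoperability.

## Known limitations

- The dearrayer assumes an axis-aligned grid; rotation/shear is not
  fitted.
- Membrane-specific segmentation and fluorescence channels are out of
  scope; PD-L1-style membranous staining is approximated by whole-cell
  maximum DAB, as in the emulated workflow.
- The exact 33-measurement identities, the 16-feature subset, SLIC/GLCM
  parameters and all detection defaults are this package's documented
  choices where the emulated platform leaves them unstated; they are
  validated by ground-truth recovery, not by numerical agreement with
  any other implementation.
- `estimate_background` is biased high by tail selection under read
  noise (see above); for synthetic work the known background can be
  passed directly.
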