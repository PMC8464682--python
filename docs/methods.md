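# Methods

`edemarad` implements a radiomics pipeline for peritumoral edema on
T2-weighted breast MRI: the edema segmentation is refined with a 3D convex
hull, a 253-entry feature vector is extracted per lesion on the raw 16-bit
gray levels, and five dichotomous histological labels (histological type,
grade, ER, PgR, Ki-67) are predicted with a random forest on
wrapper-selected features, comparing a semantic-only model against
semantic + edema-radiomics on identical cross-validation folds.

## ROI refinement

Manual edema segmentations tend to have jagged edges and concavities where
edema abuts tissue of similar signal. The refinement replaces the mask by
its voxelized convex hull: a voxel belongs to the output when its **center**
lies inside or on the hull of the input voxel centers, with an inclusive
tolerance of 1e-9 voxel units so boundary centers are kept. The operation is
a superset of its input, idempotent, and by design slightly expands the ROI
to include a perimeter margin of adjacent tissue.

Two choices were genuinely open and are fixed as follows:

* **Index space, not millimeters.** The hull is computed on voxel indices,
  which makes the result independent of (anisotropic) voxel spacing and
  exactly reproducible; `physical=True` switches to millimeter coordinates.
  For a convex-hull membership test the two differ only through the
  tolerance, since the coordinate map is affine.
* **Degenerate masks.** Point sets of affine rank < 3 (single voxel,
  collinear, coplanar) are handled by projecting onto the SVD basis of the
  point set and testing the low-dimensional hull directly (identity /
  segment-parameter / planar triangulation).

The full-rank hull membership is delegated to Qhull (via
`scipy.spatial.Delaunay`); correctness is checked in the test suite against
an exhaustive half-space / linear-programming point-in-hull oracle on small
grids.

## Feature bank

253 features in four blocks, in a frozen canonical order
(`feature_manifest.json`):

* **11 semantic** pass-through descriptors (age, menopausal status, family
  history, hormone therapy, location, stadiation, margins, dimensions,
  morphology, kinetic-curve type, edema type), numerically encoded.
* **12 first-order** statistics of the ROI intensity histogram with 2^16
  identity bins — no gray-level reduction anywhere: mean, SD, skewness,
  kurtosis (both 0 for a degenerate histogram), energy, entropy (bits),
  maximum probability, its position (ties to the smallest bin), energy in a
  window around the maximum, range, number of relative maxima, and energy
  around the relative maxima. The window half-width `w` defaults to 5 gray
  levels (configurable); relative-maxima detection runs on the sequence of
  non-empty bins, so empty bins between peaks are ignored, and a flat
  plateau counts once. Moments are computed on the normalized histogram over
  bin values, which under identity binning equals voxel-level moments; the
  same 12 statistics are reused verbatim on LBP code histograms.
* **48 LBP-TOP**: classic radius-1 / 8-neighbor local binary patterns, no
  interpolation, computed in the three orthogonal planes of the volume.
  Bit k is set when neighbor_k >= center (ties set the bit, for
  determinism); the ring starts at the +first-in-plane-axis neighbor and
  proceeds counter-clockwise. Four code variants — basic (256 codes),
  rotation-invariant (36), uniform (59), rotation-invariant-uniform (10) —
  each produce three per-plane histograms that are **concatenated** (XY,
  XZ, YZ), normalized, and summarized with the 12 first-order statistics on
  the concatenated bin index: 4 x 12 = 48. A ROI voxel is coded in a plane
  only if its full 3x3 in-plane neighborhood exists in the *grid* (not the
  ROI): the hull-expanded ROI intentionally contains perimeter tissue, so
  borrowing adjacent gray values is consistent.
* **182 3D-GLCM**: directed co-occurrence tables at interpixel distance 1
  for all 26 unit offsets of the 3D neighborhood (each +-pair is its own
  direction; no symmetrization), indexed by raw 16-bit gray values and held
  **sparsely** — only observed pairs are stored, so no 65536^2 matrix ever
  exists. Per direction, 7 statistics on the normalized table:
  autocorrelation, covariance, inertia, absolute inertia, inverse inertia,
  energy, entropy. Thin ROIs can produce an empty table for some direction;
  its 7 features are 0 with a logged warning. Directions are ordered
  lexicographically over (dz, dy, dx).

Degenerate inputs are defined everywhere: a 1-voxel ROI has a valid
histogram, empty pair tables (zeros) and no codable LBP voxel (the LBP
block falls back to zeros with a warning), so every feature is finite for
every non-empty ROI.

## Modeling

Labels are dichotomized from the raw histology fields: ILC vs IDC, G3 vs
G1+G2 (grouping the smaller grades), ER and PgR positive at >= 1%
immunoreactive cells, Ki-67 high at >= 14%. Because different cut points
for receptors (10%) and Ki-67 (20%) are in circulation, all three
thresholds are configurable; the synthetic generator draws raw percentages
away from all contested cut points so its labels do not depend on the
choice.

**Feature selection** is a forward best-first wrapper: subsets are scored
by the mean held-out AUC of a random forest under internal stratified
cross-validation on the training data only; the open list is expanded by
adding one unused feature to the best open node; the search stops after
`patience` consecutive expansions that fail to improve the best merit by
more than 1e-4. Defaults: 5 internal folds, 100 trees, patience 5, no cap
on subset size (the downstream forest performs its own intrinsic
selection); all are configurable, and ties resolve to the earlier feature
in canonical order so the search is deterministic under a seed.

**Evaluation** is stratified 10-fold cross-validation with selection run
*inside* each training fold (no information from the held-out fold reaches
the selector). Held-out probabilities are pooled into one ROC curve per
experiment (a single AUC and confusion matrix at probability 0.5, rather
than fold-averaged metrics); rates with a zero denominator are reported as
0 and flagged. The paired comparison evaluates each label twice — the 11
semantic columns only, then all 253 — on identical folds, and reports
per-label deltas. The classifier is a random forest with 100 trees and
sqrt(p) split candidates per node, fully grown, seeded per fold.

A note on wrapper merit: on pure-noise data the search's internal merit is
optimistically biased (a max over many noisy CV scores). The unbiased
quantity is the held-out pooled AUC of the outer cross-validation, which is
what all calibration checks use.

## Synthetic cohorts

The generator emulates the structure of a ~127-lesion single-center cohort:
edema-type frequencies 49/20/13/18% (peritumoral/pre-pectoral/subcutaneous/
diffuse), label prevalences 13.4% ILC, 47.2% G3, 79.5% ER+, 36.2% PgR+,
66.1% Ki-67-high, age ~ N(54.9, 11) clipped to 30–84, lesion diameter
lognormal with median 19 mm clipped to 9–60 mm, and category frequencies
for family history, hormone therapy, margins and kinetic curves matching
the emulated population. Labels are independent Bernoulli draws at their
prevalences; raw histology fields are then drawn consistently with the
binary labels.

Images are smoothed Gaussian random fields: white noise convolved with an
isotropic Gaussian kernel of sigma = correlation length (voxels),
standardized, mapped to mean +- SD, clipped and rounded to 16-bit. This is
the simplest stationary texture whose co-occurrence and LBP statistics
shift monotonically with its two parameters, giving a controllable ground
truth. Baseline parameters (package choices; they are calibration knobs,
not clinical claims): background mean 1200, SD 300, correlation 1.0 voxel;
edema mean 3000 (bright on T2), SD 600, correlation 1.5 voxels. Masks are
ellipsoids with semi-axes ~14–24% of the grid and a seeded short-range
boundary jitter (relative amplitude 0.2, field sigma 1 voxel) that creates
the jagged, locally concave outlines hull refinement exists to fix.

Class signal enters **only inside the edema mask** (the background is
statistically identical for all lesions): a lesion positive for a label
with `texture_effect` gamma gets its edema correlation length increased by
gamma voxels and its noise SD scaled by (1 + 0.25 gamma). Default effects
are ordered like the gains the combined model is expected to show
(grading 1.0, histology 0.6, PgR 0.6, Ki-67 0.4, ER 0.2); a separate
`semantic_effect` (default 0.3 per label) couples the semantic descriptors
to the labels through a logistic tilt of category probabilities and a shift
of age/diameter, so that the combined-beats-semantic direction is
reproducible while the semantic arm stays weakly informative. Setting every
effect to zero yields a fully null cohort.

What the generator does **not** emulate: breast anatomy, bias fields or
acquisition artifacts, spatially varying edema signal, correlated labels
(real receptor statuses are strongly dependent), inter-reader segmentation
variability, or DCE/DWI content behind the semantic descriptors. Passing
tests therefore demonstrate that the pipeline measures what it claims on
controlled textures — not that edema radiomics predicts histology in
patients.

## Problem sizes used by tests and the acceptance script

Statistical checks run at reduced scale, chosen to keep a full run at desk
scale while leaving the contracts intact: 16^3 grids, 100–127 lesions per
cohort, 4–5 outer folds, 2 internal folds with a 6-tree evaluator, search
patience 2 with the subset cap at 3, and a 10–20-tree classifier. Oracle
comparisons use exhaustive brute force on grids <= 8^3 and n <= 50. The
null-calibration check asserts each label's mean cross-validated AUC over
four 127-lesion null cohorts lies within 0.5 +- 0.1 (pooled AUC for a rare
label such as ILC at 17 positives has SD ~ 0.08, so per-run bounds at this
scale would be dominated by sampling noise rather than miscalibration).

## Known limitations

* The best-first wrapper is O(expansions x p) random-forest CV fits; at
  p = 253 and 10 outer folds a full-scale run is hours of CPU, which is
  inherent to wrapper selection, not to this implementation.
* LBP-TOP uses grid neighbors (no sub-voxel interpolation) and treats the
  anisotropic axis like the in-plane axes, as does the GLCM over all 26
  directions; orientation-sensitive features are meant to be filtered by
  the selection stage, not resampled away.
* The rotation-invariant LBP variants are invariant to ring rotations
  only, not reflections; mirror-symmetry checks hold statistically on
  isotropic textures, not exactly.
* Empty co-occurrence tables and uncodable LBP planes fall back to zeros;
  for sub-3-voxel ROIs large parts of the radiomic vector are therefore
  constant.
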