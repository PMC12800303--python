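# Methods

## Problem and measurement model

In vivo confocal microscopy (IVCM) of the corneal subbasal nerve plexus
produces 8-bit grayscale frames, 384 × 384 px covering 400 × 400 µm
(0.16 mm²). Two biomarkers are extracted per participant, each averaged
over that participant's graded frames (typically 10, five per eye):

* **CNFL density** (mm/mm²): mean total nerve fiber length per frame,
  divided by the frame area;
* **DC densities** (cells/mm²): mean dendritic cell count per frame, per
  morphology class (cells *with* dendrites — bodies with radiating
  processes — and compact *without*-dendrites cells), divided by the frame
  area; the total density is the exact sum of the two.

All unit conversions live in `ivcmquant.units`: pixel pitch is µm/px
(default 400/384), lengths are mm, densities mm/mm² or cells/mm². With the
default geometry one cell per frame equals exactly 6.25 cells/mm².

## Segmentation models

Both segmentation tasks use one parameterized residual U-Net family
(`ivcmquant.segmentation`): pre-activation residual blocks
(BN → ReLU → 3×3 conv, twice, plus a projected identity), 2×2 max-pool
downsampling, nearest-neighbour upsampling with skip concatenation, and a
1×1 head — one sigmoid logit for binary nerve masks, three softmax logits
(background / with dendrites / without dendrites) for cells. The family
default is depth 5 with 16 base channels; all tests and the shipped
pipeline use desk-scale configurations (depth 3, 8–16 base channels, 96 px
frames) chosen so that a full train/evaluate cycle runs in minutes on one
CPU core. The networks run on a small reverse-mode autodiff engine over
numpy float32 (`ivcmquant.nn`) — deterministic given the seed, with
initialization, shuffling and optimizer state all derived from it.

Training uses Adam with a compound Dice + cross-entropy loss by default
(Dice alone, BCE alone and CE alone are selectable). Dice counters the
severe foreground/background imbalance of thin fibers and sparse cells; the
cross-entropy term stabilizes early training. No data augmentation is
applied. Binarization uses probability ≥ 0.5; the 3-class head takes the
per-pixel argmax.

Model evaluation is **subject-stratified k-fold cross-validation**: folds
are assigned to subjects (sizes differing by at most one), never to images,
so no participant's frames appear on both sides of a split.

## Per-image nerve length

The *algorithmic* estimator (`ivcmquant.cnfl`) measures a predicted binary
mask in four steps:

1. **Regularization** — morphological closing (3×3), hole filling, and
   removal of components under 16 px. Ragged mask borders and interior
   holes otherwise skeletonize into loops and spurs that can double the
   measured length; ground-truth rasterized masks pass essentially
   unchanged.
2. **Thinning** to a 1-px skeleton (topology-preserving, scikit-image).
3. **Spur pruning** — skeleton endpoints are eroded for 2 iterations (the
   stroke half-width of the 4-px training masks), suppressing rasterization
   spurs at caps and joints at the cost of ~2 px per genuine fiber end.
4. **√2-weighted link counting** — each unique 8-neighbour adjacency
   contributes 1 px (orthogonal) or √2 px (diagonal), converted to mm by
   the pixel pitch.

For predominantly vertical, gently curved fibers (the regime in which
frames are selected for nerve grading, and which the synthetic generator
produces), this estimator stays within 5% of the analytic arc length; the
systematic components (chain-code overestimation of oblique runs, endpoint
loss from thinning and pruning) partially cancel. A simpler proxy —
foreground pixel count divided by the nominal stroke width — is available
behind `method="pixel_area"`.

The *regression* estimator shares the U-Net encoder, adds global average
pooling and a two-layer dense head with a softplus output (lengths are
non-negative), and is trained with MSE on lengths in mm. It exists because
skeleton measurements are sensitive to segmentation breaks, while a learned
regressor can compensate for them. `select_estimator` picks the method with
the lower MAPE against ground truth (ties: lower MAE, then the algorithmic
method as the simpler one).

## Cell counting

Counts are 8-connected components of each class channel with area ≥ 10 px
(so isolated-pixel noise never counts); both thresholds are configurable.
Touching cells of one class merge into a single count — a known limitation
shared with manual grading of crowded frames, documented rather than
patched. Border-touching components are counted.

## Synthetic data generator

`ivcmquant.synth` emulates the image properties the pipeline depends on,
with exact ground truth:

* **Nerves** — cubic-spline fibers spanning the frame vertically, with
  horizontal drift (slope SD 0.12 per px of vertical travel) and disjoint
  starting bands so fibers run roughly parallel without crossing, as
  subbasal nerves do in frames selected for grading. The dense sample
  polyline *is* the ground-truth tracing, so the "analytic" arc length is
  exact by construction. When a per-image target length is requested,
  fibers are added and the last one trimmed so the total matches exactly.
* **Cells** — irregular ovoid 12-gons (radius 3–6 px); with-dendrites
  cells additionally get 2–5 radiating processes (5–12 px) that are
  rendered but not part of the annotation polygon. Cells are placed with a
  minimum separation so generated cells never merge, making perfect-mask
  count recovery exact.
* **Noise** — Gaussian blur (σ 0.8) over the rendered structures on a dark
  background (mean 40), multiplicative speckle (SD 0.10) and additive
  Gaussian noise (SD 9). This is an invented noise model: it makes
  segmentation non-trivial but does not attempt photorealism. It contains
  no oblique sections, epithelial cells, keratocytes, or other corneal
  layers, and no annotation errors — so passing desk-scale tests
  demonstrates that the pipeline's machinery recovers known quantities, not
  that it matches clinical-grade performance on real images.
* **Cohorts** — two groups with subject-level latent densities drawn from
  group distributions truncated at zero (defaults: CNFL 17.3 ± 3.8 vs
  19.4 ± 4.0 mm/mm²; DC with dendrites 11.6 ± 14.1 vs 6.6 ± 6.0 cells/mm²;
  DC without 59.8 ± 53.4 vs 36.0 ± 42.0 cells/mm², matching manually graded
  symptomatic-vs-control cohorts). Per-image nerve-length targets jitter
  around the subject mean by 5%; per-image cell counts are Poisson around
  the subject mean. Every draw derives from one seed.

## Agreement and group statistics

`ivcmquant.metrics` implements pixel metrics (Dice, recall, precision,
specificity; comparing two empty masks counts as perfect agreement),
MAPE/MAE (zero-reference pairs are excluded from MAPE with a warning),
Bland-Altman (sample SD, limits at bias ± 1.96·SD — the normal multiplier,
appropriate at the sample sizes involved), the two-way absolute-agreement
ICC with the standard F-based interval (single-rater ICC(A,1) by default,
average-measures ICC(A,k) selectable; verified against pingouin), and
Pearson correlation with the Fisher-z interval.

`ivcmquant.stats` offers Levene's test (classic centre = mean by default;
Brown-Forsythe selectable), the pooled-variance t-test (raw vectors or
published summary statistics), pooled-SD Cohen's d, and Benjamini-Hochberg
adjustment (via statsmodels). The supported group-comparison path operates
on per-participant densities: the per-participant averaging already
collapses the repeated-measures structure, so no mixed-effects model is
fitted; analyses of per-image data with subject random effects are out of
scope and would need a dedicated mixed-model tool.

## Numerical conventions

* Coordinates: x = column, y = row, origin at the top-left pixel centre,
  0-based, everywhere.
* Stroke rasterization: a width-w polyline marks pixels whose centre has
  normal offset in [−w/2, w/2) (half-open, so a width-4 stroke through
  integer coordinates covers exactly 4 rows) and tangential position in
  [0, L] (butt caps); interior joints get half-open disks. Tracing points
  may lie in the closed box [0, W] × [0, H], so a full-height fiber spans
  exactly H px.
* Polygon fill: even-odd rule on pixel centres, half-open, so abutting
  polygons never double-cover and an s × s axis-aligned square fills
  exactly s² pixels. Cross-class overlaps resolve by draw order,
  last-drawn wins.
* NDF round-trips are bit-exact for the supported dialect; unknown header
  lines are preserved.
* Sub-pixel tracing coordinates are accepted and only discretized at
  rasterization.

## Desk-scale problem sizes

The shipped tests and the acceptance script train depth-3 / 8-channel
networks for 25 epochs on 36 frames of 96 × 96 px (8 subjects, two groups,
6 frames each; subject-stratified splits), evaluate on held-out subjects,
and run the geometry oracle on 100 full-size (384 px) fibers. These sizes
were chosen as the smallest at which the recovery properties are stable;
they are design choices of the package, and the pipeline accepts larger
cohorts, deeper models and full-size frames through the same
configuration objects.

## Known limitations

* Chain-code length estimation biases upward for fibers far from the
  vertical/diagonal directions; the 5% recovery guarantee holds for the
  generator's predominantly vertical regime, not for arbitrary curves.
* Merged same-class cells count once; very high densities underestimate.
* The synthetic generator does not model annotation error, image-quality
  variation, or other corneal layers; desk-scale metrics should not be
  read as clinical performance.
* Training is CPU-bound numpy; clinical-scale training (thousands of
  384-px frames) is out of scope.
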