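# Methods

## The problem

T2-weighted (T2W) prostate MRI is acquired in arbitrary, scanner- and
protocol-dependent intensity units: the same tissue can map to wildly
different numbers across vendors, coils and sites, which breaks any
analysis that compares intensities across patients (radiomics, lesion
classification, longitudinal follow-up). `autoref` normalizes a 3D T2W
volume onto a *pseudo-T2* scale in milliseconds by anchoring two
automatically detected reference tissues — periprostatic/subcutaneous fat
and the levator ani muscle — at their 3 T literature T2 values.

## The normalization model

Let `I(x,y,z)` be the preprocessed volume, `I_fat` the 90th percentile of
the pooled fat-ROI voxels and `I_muscle` the 10th percentile of the pooled
muscle-ROI voxels. The dual-reference map is the strictly increasing
affine transform

    pT2 = (I - I_muscle) / (I_fat - I_muscle) * (T2_fat - T2_muscle)
          + T2_muscle,

with `T2_fat = 121 ms` and `T2_muscle = 40 ms` (3 T literature values;
both config-overridable for other field strengths). By construction a
voxel at the muscle reference maps to 40 ms and one at the fat reference
to 121 ms. Because the map kills any affine intensity transform of its
input, the whole pipeline is invariant to scanner gain/offset changes as
long as the same ROIs are found. Voxels darker than the muscle reference
map below 40 ms and may be negative; they are kept (an optional flag
clips at 0 for display).

A muscle-only variant scales proportionally through the origin,
`pT2 = I / mean(muscle ROI) * T2_muscle`. Note the deliberate asymmetry:
the dual-reference map uses percentile references while the muscle-only
map uses the ROI *mean*; the two conventions are implemented exactly as
defined, not harmonized. Three standard comparison normalizers are
provided: min–max stretching, histogram equalization (CDF matching at 64
levels by default) and z-score ("Gaussian kernel") normalization.

## Pipeline

1. **Preprocess** — N4 bias-field correction (3 fitting levels, 50
   iterations/level; the field is estimated on a 4× in-plane-shrunk copy
   and resampled, a standard cost/accuracy trade-off), then clipping and
   division at the volume-wide 99th percentile, then per-slice bilinear
   resampling to 0.5×0.5 mm and a centered crop/pad to 384×384 pixels
   (odd crop/pad differences go to the high-index side). Slice count and
   spacing are untouched. Percentiles use linear interpolation throughout
   the package.
2. **Detect** — two aggregate-channel-features (ACF) detectors, one per
   reference tissue, score sliding windows on every transverse slice
   inside tissue-specific *focus regions*: fat in the posterior 50% of
   rows within the inferior 75% of slices; muscle in the middle
   (posterior–anterior) 50% of rows within the middle 50% of slices.
3. **Select & extract** — the three slices with the highest-scoring box
   per tissue are kept; inside each box, Otsu thresholding (256 bins over
   the box range) keeps the bright (fat) or dark (muscle) side, a
   morphological opening with a one-pixel-radius disk removes speckle,
   and the largest 8-connected component becomes the ROI. ROI voxels are
   pooled across the (≤3) slices before taking the 90th/10th percentile.
   If a tissue yields no usable ROI, or `I_fat ≤ I_muscle`, the case is
   flagged unusable with a machine-readable error; there is no silent
   fallback.
4. **Normalize** — the chosen transform above.

## The ACF detector

Channels per slice: the z-scored intensity (per-slice normalization makes
all detector features exactly invariant to global affine intensity
changes — the detector must run *before* normalization), the gradient
magnitude, and six unsigned-orientation channels that soft-bin the
gradient magnitude (they sum per pixel to the magnitude). Channels are
4×4 sum-pooled and box-smoothed; a detection window of 48×48 px (24 mm at
the 0.5 mm grid) covers 12×12 aggregated cells × 8 channels = 1152
features. Scales {0.75, 1.0, 1.25} are handled by resampling the slice,
stride is one aggregated cell (4 px), and greedy per-slice non-maximum
suppression drops boxes overlapping a kept box at IoU > 0.5.

Training is a two-stage boosted cascade: stage 1 fits SAMME AdaBoost
(depth-2 trees, shrinkage 0.1, 128 trees) on positives versus randomly
sampled in-focus-region negatives (IoU < 0.2 against annotations, 150
per volume); stage 2 retrains with 256 trees after adding hard negatives
— false positives of the stage-1 detector (capped at 5000). Positives
are candidate-grid windows with IoU ≥ 0.4 against the annotation boxes,
so positive features come from exactly the path detection uses.

The boosting is implemented in-package as an exhaustive weighted-Gini
split search over 256-bin-quantized features; each tree searches a
random quarter of the feature set (a standard randomization for boosted
detectors that also keeps trees diverse when a single tree already
separates the training set — without it the ensemble margin would be
binary and localization would collapse). Perfectly separating trees get
an error floored at 1/(2n) so boosting continues. Everything is
deterministic given the seed; the fitted ensemble is stored as flat
arrays (features, thresholds, children, ±1 leaf votes, tree weights) in
a compressed-JSON `.acf` file, and reloaded models reproduce scores
bitwise. Window scoring is branchless: each depth-2 tree reduces to
three shifted-plane comparisons on the aggregated channel image,
vectorized over all trees, so no window features are materialized at
detection time.

All detector hyperparameters above (window geometry, tree counts,
shrinkage, sampling caps, IoU bands) are package defaults exposed in
`DetectorConfig`; they are stand-ins chosen to cover the posterior fat
pad and levator ani extents at 0.5 mm resolution.

## The synthetic phantom

The generator renders what the pipeline needs and nothing more: an
ellipsoidal "prostate" slightly anterior of center, a dark muscle band
posterior to it inside the muscle focus region, a bright posterior fat
pad inside the fat focus region, on a mid-gray pelvic background —
24 slices of 192×192 at (3.0, 1.0, 1.0) mm, so the resampling path is
exercised. Default intensity means (au): background 300, muscle 120,
fat 900; case-to-case tissue-mean jitter sds 15/6/45. The prostate mean
is *anchored*: it is placed on the fat/muscle intensity axis at the
position encoding T2 = 80 ms (≈505 au for the default means), so a
correct normalization must recover 80 ms; supplying an explicit prostate
mean instead records the implied encoded T2 in the truth structure.

Corruptions, applied in order: a smooth multiplicative bias field
(Gaussian-smoothed white noise rescaled to [1−a, 1+a], default a = 0.2),
a per-case random gain in [0.7, 1.3] and offset in [−30, 30] au
(simulating scanner/protocol variation), and additive Gaussian noise
(sd 10 au). Noise is Gaussian rather than Rician by default (a Rician
option exists): the pipeline's invariances are affine, and the Rician
floor would confound the analytic fixed-point tests; at the phantom's
SNR (≥12 in the darkest tissue) the difference is marginal anyway.
Geometry jitter moves band/ellipsoid positions by ±4 px and radii by
±8%, bounded so every ground-truth box stays inside its focus region.
Truth records realized means, gain/offset and encoded T2s; annotations
are tight per-slice bounding boxes of each band.

What the phantom does *not* emulate: pulse-sequence physics, coil
sensitivity profiles (in particular endorectal-coil gradients, which the
method explicitly does not correct), anatomy-conforming tissue shapes,
partial-volume mixing, or motion. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithm — detection,
ROI extraction, the affine model, the statistics — not clinical
performance on real cohorts.

## Evaluation statistics

Inter-case agreement is the histogram intersection Σᵢ min(H₁(i), H₂(i))
of in-mask intensity histograms at n = 100 bins, each normalized to its
own in-mask voxel count. Bin edges are a policy choice the metric is
sensitive to; the package uses, per pair, common equal-width edges
spanning the union of both masked samples (symmetric and well-defined
minima), with an optional fixed range (e.g. 0–300 ms for pseudo-T2
maps). On jittered phantom cohorts the median pairwise intersection of
raw volumes is near zero (disjoint intensity ranges) and rises above 0.8
after dual-reference normalization.

The classification surrogate fits an unregularized single-predictor
logistic regression (region-mean intensity → healthy/malignant) under 10
iterations of stratified 5-fold cross-validation; each iteration's AUC
comes from the pooled held-out predictions, and the reported 95% CI is
the normal approximation mean ± 1.96·sd/√10 across the 10 iteration
AUCs (the CI could also be taken across pooled folds; across-iterations
was chosen as the more conservative, split-variance-aware reading).
Regularization is deliberately off: with one predictor it would only
bias the slope.

## Numerical and degenerate-input choices

- Percentile convention: linear interpolation between order statistics,
  everywhere.
- Otsu: 256 bins spanning the sample min–max; threshold at the center of
  the variance-maximizing bin; exact ties between splits (empty bins
  between modes) are resolved toward the lower bin. A constant sample is
  an error; a constant detection box yields an empty ROI plus a warning.
- Constant volumes: bias correction and histogram equalization warn and
  pass through; stretching and z-scoring raise (undefined).
- Flat slices produce no detections (no structure to detect).
- Reorientation to the canonical frame (slices inferior→superior, rows
  anterior→posterior, columns right→left) is a pure axis permutation/flip
  from direction-cosine metadata; volumes without orientation metadata
  must be asserted canonical by the caller or fail loudly.
- Written volumes are 32-bit float, masks 8-bit; non-default units
  ("ms") travel in a JSON sidecar.
- Seeds: one master seed; per-stage and per-case seeds are derived by
  hashing, all below 2³¹.

## Problem sizes used in the test suite

Detectors are trained on 20 phantom cases and evaluated on 10 held-out
cases; the affine-invariance check uses 5 cases × 3 random gain/offset
pairs; parameter recovery uses 10 noise-free cases; the
normalization-effect comparison uses a 10-case jittered cohort. These
sizes give stable statistics on the phantom while keeping a full run of
the suite on a single CPU in the tens of minutes.

## Known limitations

- Pseudo-T2 is not a measured relaxation time; accuracy inherits the
  assumption that fat and levator ani T2 are stable across subjects.
- The detector defaults are tuned to the phantom's geometry scale
  (24 mm windows); real cohorts would need retraining on annotated
  rectangles and possibly different window geometry.
- Endorectal-coil sensitivity gradients are out of scope by design.
- No fallback exists when a reference tissue cannot be found; such cases
  abort with a machine-readable error.
- N4 bias correction is not affine-equivariant, so exact end-to-end
  affine invariance holds for the pipeline with bias correction
  disabled; with N4 enabled the invariance is approximate.
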