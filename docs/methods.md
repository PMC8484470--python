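# Methods

## Problem and approach

`wbckit` classifies single white blood cells (WBCs) from stained
peripheral-blood smear crops into the five peripheral types —
lymphocyte, monocyte, neutrophil, eosinophil, basophil.  The method is
deliberately training-free on the segmentation side and shallow on the
classification side: a color-arithmetic nucleus segmenter, a convex-hull
proxy for the cytoplasm, 51 hand-designed features, and a class-weighted
SVM.

## Nucleus segmentation

Giemsa-type stains make chromatin dark purple while cytoplasm is pale
pink-violet, red blood cells (RBCs) salmon-gray and background
near-white.  The segmenter turns this chemistry into plane arithmetic:

1. **Color balancing.** Each RGB channel is multiplied by
   `mean(gray) / mean(channel)` (gray = 0.299 R + 0.587 G + 0.114 B),
   rounded, clipped to [0, 255].  A zero-mean channel is left unchanged.
   This pins all three channel means to a common value, canceling global
   stain/illumination casts; it is idempotent up to rounding.
2. **Planes.** On the balanced image (channels scaled to [0, 1]):
   `K = 1 − max(R,G,B)`, `M = (1 − G − K)/(1 − K)` (M = 0 where K = 1),
   and HLS saturation `S = (max − min)/(1 − |max + min − 1|)`.
   The purple nucleus is bright in M and S; RBCs and cytoplasm are
   brighter in K than in M; background carries almost no saturation.
3. **Soft map.** `clip(min(M, S) − clip(K − M, 0, 1), 0, 1)`.  The first
   term keeps nucleus evidence, the second subtracts RBC/cytoplasm
   evidence.  Negatives are clipped: a negative difference carries no
   nucleus evidence, and clipping keeps the map nonnegative so Otsu is
   well posed.
4. **Otsu threshold.** 256 uniform bins over [0, 1]; exhaustive
   between-class-variance maximization; ties resolved to the lowest
   qualifying split; foreground strictly above the returned bin edge.
   A single-occupied-bin map has no threshold and yields an empty mask.
5. **Post-processing** (the crop is a single-cell image with a central
   target): fill interior holes, drop components under 1% of the image
   area, keep the component whose centroid is closest to the image
   center.  A `keep_all_components` switch retains every surviving
   component instead, for heavily lobed nuclei whose lobes disconnect.

Everything is deterministic; identical inputs give byte-identical masks.

## Cytoplasm proxy (ROC)

True cytoplasm segmentation is avoided.  The convex hull of the nucleus
pixel set (pixel-center rasterization, computed over the union of all
lobes) is taken, and the *representative of the cytoplasm* is
`ROC = hull AND NOT nucleus`.  Lobed nuclei trap a large ROC between
their lobes; round nuclei leave a small one.  A perfectly convex raster
nucleus has an empty ROC, which downstream features encode as zeros.

## Features (51)

Order is fixed: `solidity, convexity, circularity`, then for each of the
12 canonical planes (R, G, B, H, S_hsv, V, L_lab, a_lab, b_lab, Y, Cr,
Cb — HSV from the standard conversion, LAB under D65 with the 8-bit
rescaling L\*/100 and (a\*+128)/255, YCrCb per BT.601 full range) the
four ratios mean(nucleus)/mean(hull), std(nucleus)/std(hull),
mean(ROC)/mean(hull), std(ROC)/std(hull).

* Shape: `solidity = A_n/A_h`, `convexity = P_h/P_n`,
  `circularity = P_n² / (4π A_n)`.
* Area is the pixel count; perimeter is the traced outer-contour polygon
  length through boundary pixel centers (Moore tracing, steps 1/√2,
  summed over components).  A 10×10 square measures exactly 36.  On
  smooth curves this estimator carries the classical +5–8% chain-length
  bias, so the circularity of a rasterized disk lands near 1.05–1.09
  rather than 1; tests band it accordingly.  Corrected chain estimators
  would de-bias circles but break the exact square identity, so the
  plain traced length is kept and documented.
* Statistics are population (divide by n).  Guards: a hull statistic
  below 1e−6 zeroes the ratio; an empty ROC zeroes ratios 3–4.  Vectors
  are therefore always finite.
* Color features are measured on the **original** crop, not the balanced
  one: balancing is a segmentation aid, and raw stain color (eosinophil
  granules, basophil darkness) is class signal.
* All features are invariant to flips and exact 90° rotations (< 1e−3).

## Classification

Min–max normalization is learned on the training set only (constant
features map to 0; test-time values are clamped to [0, 1]).  The SVM is
one-vs-one with per-class weights {neutrophil: w, others: 1} —
neutrophil errors dominate real differential counts, so their cost is
tunable.  Hyperparameter search: stratified five-fold CV over
3 kernels (linear, RBF, degree-3 polynomial) × weights {1,2,5,10,15,20}
× C {1,2,4,6,8,10} = 108 configurations; the argmax of mean fold
accuracy wins, ties toward smaller C, then smaller weight, then kernel
order linear < rbf < poly3.  Normalization is refit inside each training
fold; fold assignment is seeded.  The shipped default is poly3, C = 6,
weight 10.  Kernel auxiliaries use mainstream defaults
(`gamma = 1/(n_features · var)`, `coef0 = 0`).  Models persist as
versioned joblib blobs embedding the normalization statistics and a
feature-order fingerprint.

## Augmentation

Class balancing uses label-preserving geometric transforms only:
horizontal/vertical flips, rotation uniform in [−90°, +90°], rescale
uniform in [0.8, 1.2], and random two-transform compositions.  Rotation
and rescale are bilinear, keep the canvas size, and fill exposed canvas
with the per-channel median (≈ background in a smear crop).  Sources and
transforms are drawn uniformly with a seeded generator; provenance
(source index + transform chain) is recorded per synthetic image.

## Evaluation

Segmentation: precision TP/(TP+FP), sensitivity TP/(TP+FN), and
DSC = 2TP/((TP+FP)+(TP+FN)) per image.  Convention for degenerate
cases (not implied by the formulas): both masks empty → 1; a zero
denominator otherwise → 0.  Classification: one-vs-rest precision,
sensitivity, F1 (0 when P+S = 0), overall accuracy, and the full
confusion matrix.

## Synthetic study conditions

The generator renders 128×128 crops: pale background (235,230,225),
4–8 grayish-pink RBC disks (205,168,162) kept clear of the cell so
ground truth stays exact, a cytoplasm blob, and a rasterized nucleus
whose geometry *is* the ground-truth mask.  Class conditions:

| class | nucleus | radius (px) | cytoplasm |
|---|---|---|---|
| lymphocyte | 1 round lobe | 20–26 | thin rim (r+5–9), pink-violet |
| monocyte | 1 lobe, kidney bite 0.45–0.65 r | 24–29 | abundant (r+8–12) |
| neutrophil | 3–5 overlapping lobes | 9–12 (spacing 1.3–1.6 r) | 34–38 |
| eosinophil | 2 lobes | 11–14 | pale salmon + red granules |
| basophil | whole cell, dark + granules | 26–30 | whole-cell truth |

Outlines carry low-harmonic radial waviness (amplitude 0.03, harmonics
2–3; basophil cell outline 0.09 with harmonics 5/7/9 for its shaggy
granulated rim).  This matters: perfectly elliptical nuclei make the ROC
exactly empty, zeroing 24 of 51 features for every convex-nucleus class
and collapsing the very mechanism the feature set relies on; real
outlines are never perfectly convex.  Illumination cast is a per-channel
gain in [0.95, 1.05]; pixel noise is uniform integer ±3.

RBC tone is deliberately grayish-pink rather than saturated salmon: in
a color-balanced smear the RBCs carry little magenta/saturation, which
is the premise that lets min(M, S) suppress them; a strongly saturated
red RBC would violate that premise (and does not match Giemsa crops).

What the generator does **not** model: cells touching or occluding the
target, uneven focus/blur, chromatin texture inside the nucleus,
staining debris, and resolution variation.  Passing the synthetic suite
therefore demonstrates the internal consistency and the color-geometry
mechanism of the pipeline, not clinical-grade accuracy on real smears;
on real data the published figures of merit for this family of methods
(DSC in the mid-0.9s, accuracy in the low-to-mid 90s) are the realistic
expectation, and near-perfect synthetic scores simply reflect the
generator's idealizations.

## Problem sizes and numerical choices

The bundled test suite and the acceptance script use 100-crop datasets
(20 per class) at 128×128 and 5-fold × 108-configuration grids over
150-sample feature sets; these sizes exercise every code path while
keeping a full run in seconds-to-minutes on one CPU.  Degenerate inputs
are handled explicitly everywhere: blank images yield empty masks (with
a warning, not an exception), empty masks yield empty hull errors, a
nucleus under 16 px is rejected as unmeasurable, and single-class
training sets are refused.

## Known limitations

* The CMYK convention (K = 1 − max, normalized M) and the luma
  grayscale in the balancing step are the standard textbook choices; a
  pipeline calibrated against different conventions will produce shifted
  soft maps.
* The center-most-component rule assumes the target cell is central; on
  off-center crops use `keep_all_components` or re-crop.
* Circularity inherits the chain-length bias described above; compare
  circularity values only against measurements using the same estimator.
* Basophil "nucleus" masks are whole-cell masks (granules obscure the
  true nucleus), so basophil shape features describe the cell outline.
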