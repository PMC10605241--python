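# Methods

## Pipeline overview

A tile image (TIFF/PNG, 8-bit, RGB or grayscale) passes through:

1. **Color normalization** — gray-world white balance (each channel rescaled
   so all channel means equal the global mean) and optional Reinhard-style
   stain normalization (per-channel mean/std matched to a reference tile).
   Both operate in RGB, clip to [0, 255], and are idempotent up to rounding.
2. **Grayscale conversion** — BT.601 luminance (0.299 R + 0.587 G + 0.114 B).
3. **Quantization** — the observed intensity range (restricted to the ROI
   mask when one is given) is binned uniformly into `Ng` gray levels,
   1-based; pixels outside the mask get level 0 and are ignored everywhere
   downstream. Binning over the per-image min–max rather than a fixed 0–255
   range makes the features invariant to global brightness and gain, which
   matches the intent of the normalization step. `Ng = 8` by default (the
   classical choice keeping an 8×8 co-occurrence matrix well populated);
   16 and 32 are supported.
4. **Texture matrices and features** — GLCM and GLRLM at the four unit
   displacements (0,1), (−1,1), (−1,0), (−1,−1), features averaged over
   directions. The GLCM is symmetrized before normalization, so features are
   invariant to the sign of the displacement.
5. **Classification** — either the fixed 15-rule threshold classifier or one
   of five trained families; evaluation via confusion metrics at the 0.5
   score threshold, empirical ROC with trapezoidal AUC, and DeLong tests for
   AUC differences.

## Numerical conventions in the feature formulas

- All entropy-type features use log base 2 (bits) with 0·log 0 ≡ 0. The
  second information measure of correlation uses the same base throughout:
  `imc2 = sqrt(1 − 2^(−2(HXY2 − HXY)))`, clipped at 0 before the square
  root. With a different `log_base` the same base is used in both places.
- The two correlation variants are the mean-subtracted and the
  product-moment forms; both are 0 (with a warning) when a marginal standard
  deviation vanishes (e.g., a constant tile), where the ratio is undefined.
- `imc1` is 0 when `max(HX, HY) = 0` (single-level image).
- Sum variance is computed about the sum average (not about sum entropy,
  which appears in some transcriptions of the classical formulas).
- GLRLM gray-level weightings use the 1-based quantized level directly
  (`LGRE` divides by g², so level 1 carries weight 1); run lengths are
  counted in pixels along the scan direction, with masked-out pixels
  terminating runs. A run direction and its negation are the same direction.
- Degenerate ratio metrics (precision with no positive predictions, etc.)
  are reported as 0 and flagged in the report's `undefined` list.
- Scores exactly at the 0.5 decision threshold classify as GBM, and a
  feature value exactly at a rule cutoff votes GBM; the tie rule favors
  sensitivity in a screening setting.

## The threshold rule set

Fifteen features carry published cutoffs: twelve GLCM (contrast, difference
variance, entropy, sum entropy, difference entropy, dissimilarity, energy,
maximum probability, homogeneity 1 and 2, IDN, IDMN) and three GLRLM (GLN,
LGRE, LRLGE). Where the two classes were reported with a gap between their
ranges (e.g., maximum probability > 0.5 for normal vs. < 0.43 for tumor),
the rule retains both printed bounds and decides at their midpoint. The
difference-variance cutoff was reported only qualitatively (as behaving like
contrast); it defaults to 0.4. Rules are plain frozen dataclasses,
exportable to CSV, and are never re-estimated from data — a separate
`separation_report` quantifies how well they transfer to any labeled feature
table.

## The five model families

DT is a CART decision tree; EB gradient-boosted trees; RF a 500-tree random
forest; SVM an RBF-kernel SVM on z-scored features; LM logistic regression
on z-scored features (trees are scale-invariant and consume raw features).
Every family emits a score in [0, 1] for the tumor class: vote fractions for
the trees, the boosted ensemble's logistic output, the SVM decision distance
squashed through a logistic, and the regression probability. Hyperparameters
default to the library defaults (plus the 500-tree forest); a small
validation-grid search per family is available but off by default, so the
validation split normally serves as an untouched sanity check. Splitting is
stratified 70/15/15 at image level with floor rounding and the remainder to
training; an optional patient-level grouping assigns whole patients to one
partition, since image-level splitting lets a patient straddle splits.
Cross-validation uses stratified 10-fold with shuffling, all seeds explicit.

## ROC comparison

Differences between ROC curves are tested with DeLong's nonparametric
method. For paired curves (two scoring rules on the same cases) the variance
of the AUC difference comes from the empirical covariance of the
structural components (one per positive and per negative case); for
independent cohorts the two variances add. The squared z statistic is
reported as a 1-df chi-square with a two-sided p. Degenerate variance
returns p = 1 with a warning. The empirical AUC itself is the trapezoidal
area under the threshold-swept ROC, which equals the Mann–Whitney statistic
with half credit for ties; the test suite verifies this equality against an
O(n²) pair-count oracle and the DeLong p against a label-swap permutation
test.

## Synthetic cohorts

The generator replaces patient images with a parametric texture model. Each
tile is a sum of:

- a tile-scale background field of fixed amplitude (sd 2 intensity units) —
  smooth illumination/density structure shared by both classes that anchors
  the quantization range so `contrast_amplitude` controls genuinely local
  variation (a pure amplitude rescaling would be invisible to per-image
  min–max binning);
- a Gaussian random field smoothed at `correlation_length` pixels and scaled
  to `contrast_amplitude` (the cellular texture);
- at least two and on average `blob_density` per 10⁴ px² dark disk "nuclei"
  with radii in `blob_radius_range` and depths 90–210 intensity units (the
  floor of two reflects that real tissue tiles always contain nuclei and
  keeps the intensity range anchored by the darkest structures);
- pale, nearly featureless plateaus covering `necrosis_fraction` of the tile
  (necrotic tissue reads as pale/yellow in H&E, with the viable tumor mass
  darker around it);
- i.i.d. Gaussian pixel noise of sd `noise_sd`, optionally with a per-tile
  lognormal jitter (`jitter_cv`) on amplitude and noise modeling
  slide-to-slide variability.

The grayscale field is clipped to [0, 255] and mapped through a fixed
purple-to-pink palette so tiles are 3-channel H&E-lookalikes; the luminance
conversion downstream inverts this monotonically. Generation is a pure
function of (parameters, seed, size); cohorts derive per-image seeds from a
master seed and group tiles five to a synthetic patient. The default tile
size mirrors the 1304×839 capture resolution of the source microscopy;
tests and the acceptance script use 256×256 tiles at 200 per class, which
keeps the full pipeline run to a few minutes on one CPU while leaving the
feature statistics well estimated.

**The separable presets.** `default_separable_presets()` encodes a bright,
homogeneous, finely textured normal class (high energy/homogeneity, low
entropy) and a dark, rough, noisy tumor class with necrotic plateaus (high
contrast/entropy/LGRE/LRLGE, because the cellular bulk occupies the lowest
gray levels while the pale necrosis anchors the top of the range). The
presets were calibrated once so that, at Ng = 8 with four directions on
256×256 tiles, all 15 rule directions hold on class means and the per-tile
feature values straddle the published cutoffs; they are fixed constants, not
fitted quantities. One rule cannot transfer to this tile size at all:
gray-level non-uniformity is bounded by the pixel count (GLN ≤ Np = 65 536
at 256×256), which is below the published 10⁵ tumor cutoff estimated from
~1.09-megapixel tiles; that rule therefore contributes chance-level
concordance (0.5) on synthetic cohorts, and the measured mean concordance of
~0.96 reflects near-perfect agreement on the other fourteen rules.

**The hard presets.** `hard_presets()` gives both classes the same texture
parameters except a 5% shift in amplitude and noise, buried under a 40%
per-tile lognormal jitter, so the class-conditional feature distributions
overlap heavily. Every model family drops to chance-level accuracy on this
cohort, which is the negative control showing the pipeline measures texture
signal rather than any leakage through the split or the generator.

**What passing tests do and do not show.** The generator targets
feature-direction fidelity and cutoff placement, not visual realism: it has
no stain physics, no cell morphology, no spatial organization of nuclei, no
scanner artifacts, and its two classes are far better separated than real
cohorts (where a deployment accuracy near 93% — not 100% — is the realistic
outcome). Perfect accuracy on the separable presets validates the machinery
(features, splits, training, scoring, evaluation), not clinical performance;
transfer to real slides depends on staining variability and tumor
heterogeneity the model does not emulate.

## Known limitations

- Whole-slide (.svs) pyramids are out of scope; the pipeline starts from
  flat tiles.
- No stain deconvolution; features are computed on luminance.
- The quantization level count, direction handling and intensity-range
  policy are conventions (8 levels, 4 averaged directions, per-image
  min–max); other choices change absolute feature values, and published
  cutoffs assume a compatible configuration.
- The binormal ROC fit behind the original curve-comparison software is not
  reproduced; DeLong's test is the standard, reproducible substitute for
  curve-difference significance at α = 0.05.
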