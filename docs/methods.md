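# Methods

## The soft-reference idea

Quality assessment of a lesion ultrasound image has no reference image to
compare against. The package's central device is to use the lesion's
segmentation mask as a *soft* reference: re-segment the lesion with a
fixed, quality-sensitive algorithm (Otsu histogram thresholding) and treat
the agreement between the two segmentations, together with lesion contrast,
as the quality signal. Otsu thresholding assumes a bimodal intensity
histogram; a sharp, well-contrasted lesion produces exactly that inside a
local window, while blur, noise and contrast loss destroy it. The reference
mask may come from a manual annotation or from any upstream segmenter; the
pipeline treats it as given. The better the reference segmentation, the
more faithful the quality score — the mask-corruption test quantifies
exactly this dependence.

## Region of interest

The ROI is the tight bounding box of the reference mask expanded on each
side by `ceil(margin_fraction × extent)` pixels (default margin 0.25),
clipped to the image. The margin keeps enough surrounding tissue inside the
window for the contrast ratio's background term and for the Otsu
histogram's second mode. The margin is a free parameter of this
implementation; scores are not sensitive to it in the 0.2–0.5 range on
phantom data, but it must be held fixed between training and prediction.

All four features are computed on the ROI crop, not the full frame: the
score is meant to reflect the lesion area, and a full-frame comparison
would dilute mask disagreement by the (identical) empty background.

## The four quality parameters

With the Otsu mask A and the reference mask B rendered at {0, 255} over the
M×N ROI:

| feature | definition | orientation |
|---|---|---|
| MSE | (1/MN) Σ (A−B)² = 65025 · (mismatch fraction) | lower is better |
| PSNR | 10 log₁₀(255²/MSE), capped at 100 dB at MSE=0 | higher is better |
| CR | (Mean_B − Mean_F)/255 on the raw ROI intensities | higher is better |
| SSIM | Dice(A, B) = 2\|A∩B\|/(\|A\|+\|B\|) | higher is better |

Notes on the definitions, which are interpretations this package commits
to:

- **Mask-vs-mask MSE/PSNR.** MSE and PSNR compare the two *masks*, not the
  image against a denoised version of itself; rendering at {0, 255} makes
  the 255 peak value in PSNR meaningful and gives the closed forms
  MSE = 65025·h, PSNR = −10·log₁₀(h) for mismatch fraction h (both are
  tested).
- **CR sign.** CR is defined background-minus-foreground so that it is
  positive for hypoechoic lesions and larger for better-distinguishable
  ones; the opposite sign convention appears in parts of the literature but
  would be negatively oriented for dark lesions.
- **Background = ROI minus reference foreground**, i.e. the "surrounding
  region" local to the lesion, not the whole image.
- **SSIM here is Dice**, a structural agreement between segmentations — not
  the luminance/contrast/structure SSIM of natural-image IQA.
- **PSNR cap.** 100 dB at exact agreement keeps min–max normalization
  finite; no realistic phantom reaches it (observed maxima are ~30 dB), so
  the cap does not distort the feature scale in practice.

## Otsu re-segmentation

The threshold maximizes between-class variance over the 256-bin histogram,
classes {≤ t} and {> t}; among tied maximizers the smallest is returned,
fixing determinism. Foreground is the dark class (hypoechoic lesion). Two
cleanup steps, both configurable:

- **Median despeckling (3×3) before thresholding.** Multiplicative speckle
  fills the valley between the histogram's modes and leaves ragged Otsu
  boundaries even on otherwise pristine images; a small median filter is
  the standard remedy before histogram thresholding of ultrasound. Without
  it, a mild blur paradoxically *improves* mask agreement by acting as an
  accidental denoiser, which breaks the intended monotone relation between
  degradation level and the agreement features at the pristine end of the
  scale. The contrast ratio is still computed on the raw, unfiltered ROI.
- **Largest 8-connected component** of the foreground is kept (single-lesion
  ROIs; smaller dark blobs are noise). A constant ROI degenerates: the
  threshold is the constant value, returned with a warning.

## Quality model

Features are min–max scaled to [0, 1] per feature on the training set; MSE
is inverted (1 − scaled) so all four features are positively oriented. Test
values outside the training range are clipped; a constant training column
maps to 0.5 with a warning.

The classifier is an RBF-kernel soft-margin SVM, one-vs-one for the four
classes (the standard decomposition; the binary dual form is verified
against the stored support coefficients in a test). C and γ are tuned by
sequential model-based optimization: a Gaussian-process surrogate with an
expected-improvement acquisition over log₁₀-transformed bounds
C ∈ [10⁻², 10³], γ ∈ [10⁻³, 10²], 32 objective evaluations of which the
first third is a random space-filling design. The objective is mean
stratified four-fold CV accuracy (stratification stabilizes small classes;
the fold count drops to the smallest class size when a class has fewer
than four members). A log-grid fallback is available. After tuning, the
SVM is retrained on all training rows. The quality scores are ordinal but
the SVM treats them as nominal classes; rank metrics are computed on the
integer outputs.

Persistence: the model container is a versioned JSON document holding the
normalizer, the tuned (C, γ), search metadata and the normalized training
set; loading refits the SVM, which is deterministic given those inputs, so
predictions round-trip bit-exactly.

## Evaluation metrics

PLCC (Pearson) measures linear agreement of predicted and reference
scores, SRCC (Spearman) their monotone agreement, exact accuracy the
fraction of perfect matches, RMSE the typical score error in grade units.
SRCC is computed as Pearson correlation on average ranks, the standard
tie-aware form, since ordinal scores are heavily tied; it reduces to the
classic 1 − 6Σd²/(N(N²−1)) formula on tie-free data, and spans [−1, 1].
Constant predictions make both correlations undefined; the evaluation
report flags them rather than guessing. The 4×4 confusion matrix has truth
in rows, predictions in columns.

## Phantom generator

The generator emulates the degradations that lower perceived ultrasound
quality, at desk scale, with an exact ground-truth mask per image — the
analogue of a manual segmentation. Formation pipeline per image: two-level
map (lesion μ_F = 60, background μ_B = 140, hypoechoic by construction) →
Gaussian edge smoothing σ = 1.5 px → multiplicative gamma speckle, unit
mean, shape k = 16 → grade-dependent degradations → clip to 0..255.
Severity s = 4 − grade, jittered by ±20% per image:

| operator | schedule | emulates |
|---|---|---|
| Gaussian blur | σ = 0.5·s px | probe motion, defocus |
| contrast compression | factor 0.72^s about the image mean | gain error, dynamic-range loss |
| additive Gaussian noise | σ = 6·s intensity units | electronic noise |
| shadow band | attenuation 0.55, probability 0.3·s | acoustic shadowing |

The lesion ellipse has semi-axes 20–45 px, uniform rotation, and center
jitter ±20 px within a 256×256 frame. Gamma speckle with a single shape
knob was chosen over a Rayleigh envelope model for tunability; it is a
modeling stand-in, not a physics claim. The jitter makes neighbouring
grades overlap so classification stays nontrivial. Datasets are split
6:2:2 train/val/test, stratified by grade, deterministically by seed.

One interaction worth knowing: severe blur removes more speckle variance
than the additive noise restores, so raw ROI intensity *spread* is not a
monotone degradation signature; lesion contrast and contrast-to-noise
ratio are, and those are what the tests assert.

**What passing tests do and do not show.** The phantoms have a single
benign-looking elliptical lesion, stationary fully developed speckle, no
scan-conversion geometry, no anatomical clutter, and degradation operators
matched to the features' assumptions. Results on phantoms demonstrate the
method's internal consistency — that the features track controlled
degradation and the model recovers graded labels — not clinical
performance. Infiltrating lesions with intrinsically unclear boundaries
would depress the agreement features regardless of image quality.

## Routing framework

A detector classifies each image as lesion-positive or negative; positive
images go through segmentation → feature extraction → SVM, negative ones to
a whole-image scorer. The deep detector/segmenter/global-scorer of a
clinical deployment are interface slots; the built-ins are a
manifest-backed oracle detector/segmenter (ground-truth configuration) and
a naive global scorer (SVM over whole-image sharpness/noise/spread/mean
summaries of lesion-free phantoms), enough to make every downstream stage
testable. A positive detection with an empty segmentation falls back to
the global route with a logged warning — the local features are undefined
without a mask; this failure policy is this package's choice. Every result
carries its route and provenance.

## Numerical and degenerate-input choices

- Otsu tie-break: smallest maximizing threshold.
- Dice of two empty masks: 1.0 (perfect agreement of nothing).
- Contrast ratio on an all-foreground or all-background ROI: error.
- Empty reference mask: a dedicated error type that routing catches.
- Mask booleanization at ≥ 128, tolerating anti-aliased mask files.
- 16-bit or color PNGs: rescaled/converted with a warning.
- Hyperparameter search, folds, phantom generation: all seeded; identical
  seeds give identical results end to end.

## Problem sizes

Default experiment sizes — 50 phantoms per grade for training, 25 per
grade held out, 32 optimization evaluations, 50-pair sign tests — were
chosen so the full pipeline regenerates in seconds while leaving the
statistical checks well-powered (a 200-sample binomial band around chance
accuracy is ±6 points; the paired sign tests at n = 50 resolve the
grade-4/grade-1 differences at far beyond the 5% level).
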