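# Methods

## Problem and data model

The package segments H&E-stained bladder tissue into muscularis propria
(MP, mask value 255) and everything else (mask value 0, including the
muscularis mucosae). Inputs are RGB images with pixel-aligned binary
masks. Two cohorts are distinguished: RC (radical cystectomy, whole-organ
sections, training only) and TUR (transurethral resections, the
evaluation cohort). All geometry uses 0-based row-major coordinates with
a top-left origin and half-open rectangles; the canonical slide size is
1440×1920 (rows×cols). TUR scans arrive larger and are resized to
canonical with bilinear (image) / nearest-neighbour (mask) interpolation.
Masks read from disk are coerced to {0, 255} by thresholding at 128, the
midpoint of the 8-bit range, to absorb anti-aliased annotation exports.

## Stain normalization

Reinhard color transfer: per-channel moments in CIE Lab (D65, standard
sRGB pipeline) are matched to a reference via
x′ = (x − μ_src)·(σ_ref/σ_src) + μ_ref. Channels with σ_src < 1e−6 are
shifted only. Lab is the default space because the moment-matching
contract is identical to the original lαβ formulation and Lab is what the
common imaging stacks implement; `space="lalphabeta"` switches to the
Ruderman transform. The reference is configurable (a designated slide or
six explicit numbers); by default the first RC slide of the manifest is
used and logged.

## Datasets, weights, folds

240×240 tiles divide the canonical image exactly (6×8 = 48 tiles).
Patch-mode extraction keeps only tiles whose mask is constant (pure MP or
pure non-MP); mixed tiles are discarded. Pixel-mode extraction keeps all
48 tiles with their mask patches. The train/validation split is
stratified 80/20 (stratum = the label, or the tile's majority class in
pixel mode; the majority rule is our choice — the stratification unit for
mixed tiles is not otherwise determined). Class weights are reciprocal
class counts (patches or pixels), normalized to sum to 2 so balanced data
gets weight 1 per class; only the ratio matters to the loss.
Cross-validation shuffles the TUR ids with a fixed seed and chunks them
into 9 equal disjoint test sets; any TUR count divisible by 9 is accepted
so desk-scale cohorts (9 slides → singleton folds) run the same code path
as the full 63.

## Training contract and backends

Both tracks train by minimizing class-weighted cross-entropy with
weighted random subsampling **with replacement** each epoch (sample
weight = class weight), a static learning rate, and model selection at
minimum validation loss. Defaults: patch track SGD, lr 0.001, batch 32;
pixel track Adam (β = 0.9/0.999), lr 0.0001, batch 4; 30 epochs for both,
overridable to 50 in the config (the two defensible readings of the
source material's hyperparameter table).

Because this distribution must run CPU-only with no deep-learning
runtime, the reference backends are deliberately small, fully
deterministic models that honor the same probability interface:

* `tiny_cnn` — a logistic head over 16 patch statistics (mean and std of
  an 8-channel filter bank: RGB, smoothed luminance, local std at σ = 1.5
  and 6, and band-limited texture energy at high/mid frequency). A
  sliding-window fast path evaluates every window via integral images of
  the shared feature stack; it computes the filter bank on the full image
  rather than per crop, so window probabilities can differ from the
  per-patch path by ~1e−3 near patch borders (no tile artifacts — a
  feature, not a bug).
* `tiny_unet` — a per-pixel logistic head over the same 8 features,
  trained on 2048 randomly subsampled pixels per tile per step.

The eight named ImageNet backbones remain registered ids that raise a
clear `BackendUnavailableError` without PyTorch, keeping config files
portable to a torch-equipped deployment.

## Inference

* Patch mode: windows at stride 10 (overlap (240−10)/240 ≈ 96 %); the
  coarse map cell (i, j) is anchored at full-resolution pixel
  (10i + 120, 10j + 120) — the center of an even-sized window is defined
  as offset (120, 120). Nearest-neighbour upsampling; the first/last
  120 px replicate the outermost cells (border behavior is our choice).
  A 25×25 box filter (configurable, odd) smooths upsampling artifacts
  *after* upsampling.
* Tiled mode: per-tile probability maps placed at their origins;
  overlapping pixels averaged when an overlapping grid is requested.
* Whole mode: one forward pass, edge-padded to the backend's size
  multiple and cropped back.

All heatmap values provably stay in [0, 1]: every step is a convex
combination.

## Thresholding and cleanup

Youden's J = TPR − FPR is scanned over 256 uniform levels
{0, 1/255, …, 1} by default (matching 8-bit probability quantization;
"unique heatmap values" is available). Prediction uses ≥, and ties on
max J break toward the smallest threshold (favors recall,
deterministic). Selecting t̂ against the test image's own ground truth is
an evaluation-time oracle; `threshold_mode: fixed` (default t = 0.5)
is the honest deployment mode and reported metrics always name the mode.

Cleanup: 155×155 median → 25×25 mean → Otsu, borders replicated. On
binary input the median filter equals the window majority vote
(odd×odd windows cannot tie), which is how it is computed — bit-identical
to a rank median but orders of magnitude faster. Kernels larger than the
image are clipped to the largest odd fitting size and logged. A 155 px
majority window necessarily rounds convex corners by
~77.5·(√2−1) ≈ 32 px while straight edges stay put; the tests encode
exactly that behavior. Otsu operates on the 8-bit rounded filtered image;
a constant image short-circuits (Otsu is undefined there).

## Evaluation

Confusion counts treat MP as positive. Non-MP-class metrics evaluate the
role-swapped quadruple (TP↔TN, FP↔FN); mean Jaccard/Dice are unweighted
two-class averages. Degenerate denominators: a class empty in both
prediction and reference scores 1 (perfect vacuous agreement);
mismatched emptiness scores 0. PR/ROC curves sweep the same 256-level
grid in threshold-descending order with trapezoidal AUC; the PR curve
anchors recall 0 at precision 1. Fold metrics are averaged per image over
the fold's test slides (pixel-pooling is available via the per-image
table). Fold aggregation reports per-metric mean and population std.

## Synthetic slides

The generator states a world and keeps it fixed. The MP region is a
thresholded coarse Gaussian random field (blob scale ∝ canvas, exact area
fraction via the quantile threshold; per-slide fraction drawn from
U(0.25, 0.65)). MP texture is coarse oriented striping (wavelength 48 px)
over a deep eosin pink (RGB 180/120/155, contrast ±28); non-MP is fine
wavy striping (9 px) over a paler pink (210/165/190, ±20). Base colors
sit far enough inside the sRGB gamut that per-slide Lab stain shifts
(L ±6, a/b ±5, emulating inter-slide staining variability) survive the
round trip unclipped. TUR slides are emitted at the larger native size
(640×960 unit / 1920×2448 full) to exercise canonical resizing. Not
emulated: nuclei, glands, tears, focus blur, annotation noise — a green
end-to-end test certifies pipeline mechanics and learnability, not
clinical accuracy.

## Numerical choices

* Probabilities via tanh-based sigmoid (overflow-safe); cross-entropy
  clipped at 1e−12.
* Feature standardization uses training-set moments stored with the
  model.
* Population (ddof = 0) standard deviations throughout.
* All randomness flows from a single experiment seed expanded
  arithmetically into per-stage, per-fold seeds (< 2³¹).

## Known limitations

* The tiny backends are linear in fixed features; they need texture or
  color separation between classes and will not match deep backbones on
  real slides.
* Youden mode requires both classes in the reference; single-class slides
  must use fixed mode (enforced with a helpful error).
* The sliding-window fast path's border behavior differs slightly from
  literal per-crop evaluation (documented above).
* Whole-slide pyramid formats and stain deconvolution are out of scope.
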