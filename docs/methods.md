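# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Histopathology slides of eyelid tumors are gigapixel RGB rasters in which
three malignancies — basal cell carcinoma (BCC), meibomian gland carcinoma
(MGC) and cutaneous melanoma (CM) — have very similar morphology, and the
diagnostic lesion usually occupies a small part of the slide.  The pipeline
has four stages: (1) tile slides into patches and keep lesion-dominated
tiles; (2) train an attention-crop classifier (the teacher) on patches;
(3) distill it into a plain ResNet-style student; (4) at slide level,
classify every window with the student, vote a slide class, segment
tumor-called windows with a class-specific U-Net, and reassemble a lesion
mask.

## Patch pipeline

Windows are `[r, r+P) x [c, c+P)` on a stride grid (defaults P = 512,
stride = 256), 0-based, row-major; incomplete edge windows are dropped, not
padded — the half-window overlap already covers interiors.  A window is
kept when the annotated-region coverage is **strictly** greater than 3/4;
a window at exactly 0.75 is discarded.  Normal slides carry an all-zero
lesion mask, so at dataset assembly they are tiled against an all-ones
region mask (all tissue is the annotated class); the extraction operator
itself always honours the mask it is given.

Cleaning reproduces the "small encoded file" rule as an encoded-size
filter: each tile is encoded (PNG by default, JPEG-q95 optional) and
dropped when the byte length falls below a threshold (default 330 KiB for
512-px tiles, scaled by `(P/512)^2` otherwise).  A tissue-fraction filter
is available behind a flag as an alternative cleaning rule.  Per-channel
normalisation statistics are fitted on training patches only and applied
unchanged to validation/test data.

## Classifier family

The backbone is a ResNet50-style bottleneck network with three switches,
each preserving the output interface so that every ablation variant is
constructible from configuration alone:

* **SampleInput stem.**  The 7x7/stride-2 input convolution is replaced by
  three 3x3 conv-BN-ReLU blocks.  The stride-2 convolution is placed
  *last*: with strides (1,1,2) the composite receptive field is exactly
  7x7 while the overall downsampling stays 2.  (Stride 2 on the first
  convolution would give an 11x11 field.)  The gradient-footprint audit in
  the test suite verifies the 7x7 field with BatchNorm in eval mode,
  because train-mode batch statistics couple every pixel and would mask
  the convolutional footprint.
* **DARes stages.**  A selected stage keeps its ordinary bottleneck stack
  (the inner residual layer) and adds an outer residual: a 1x1-projected
  copy of the stage input (shallow features) and a 1x1-projected copy of
  the middle block's output (block ceil(k/2) of a k-block stage) are added
  to the stack output before a final ReLU.  This is the minimal
  double-layer nested structure that fuses shallow, middle and deep
  features; the block contains no attention of its own — attention lives
  in the BACM head.  Default placement is layer2 + layer4.
* **SPP head.**  Adaptive average pooling over grids {1, 2, 4} (defaults)
  concatenated into a fixed-length vector (channels x 21), so one
  parameter set serves any input size at least as large as the coarsest
  grid.

The stem's max-pool is 2x2/stride-2 (instead of 3x3/stride-2/pad-1); output
shapes are identical at every size used here.  Width (channel multiplier)
and depth (blocks per stage) are both scalable; the miniature preset used
by all integration benchmarks is width 1/8 (8 base channels), one
bottleneck per stage, 64-px input, SPP grids {1, 2}, 4 attention maps.

## Attention-guided cropping (BACM)

A 1x1 convolution on the last-stage feature map yields X attention maps
(default 32; miniature runs use 4 — the lineage of this head gives no
principled value).  Per image, one map is selected uniformly at random
(seeded), min-max normalised to [0, 1], thresholded strictly at theta_c
(default 0.5; the threshold was not specified upstream and is
configurable), and upsampled to image resolution by nearest neighbour.
The tight bounding box over all positive pixels crops the original image;
the crop is resized bilinearly to the network input size and passes
through the same augmentation/normalisation contract as original tiles.
The training loss is the mean of the original-pass and crop-pass losses.

Degenerate cases are defined, not fatal: a constant attention map
normalises to all zeros with a flag, the empty threshold mask falls back
to an all-ones mask (crop = whole image), and training proceeds.  For
non-constant maps the normalized maximum is 1 > theta_c, so the mask is
never empty and the mask is pointwise non-increasing in theta_c.

## Losses and distillation

* Focal loss `FL(p_t) = -alpha (1-p_t)^gamma log p_t`, defaults
  alpha = 0.25, gamma = 2; `gamma = 0, alpha = 1` recovers cross-entropy.
  p_t is clamped at 1e-12 before the log.
* Temperature softmax `softmax(z/T)`; T = 1 gives ordinary (hard-label)
  probabilities.
* Distillation loss
  `L_KD = (1-a) FL(SHP, label) + a T^2 KL(TSL || SSP)` with SHP the
  student's T=1 probabilities, SSP the student's temperature-softened
  probabilities and TSL the teacher's temperature-softened labels.  The
  source formula names the hard-label argument ambiguously (the same
  symbol is defined twice); the first occurrence is read as the hard
  prediction, matching the accompanying diagram.  The KL direction is
  KL(teacher || student), the standard distillation form; argument order
  is not stated upstream.  Defaults a = 0.7, T = 4 (not stated upstream;
  exposed in config).
* Total loss `T_loss = 1/2 L_KD + 1/2 FL(pred-on-AttentionPicture,
  label)`.  Read literally, the second term depends only on the frozen
  teacher and carries no student gradient; the default therefore feeds the
  teacher's attention crop to the *student* and penalises the student's
  prediction, which makes the term trainable.  A `literal_eq5` switch
  preserves the literal form.
* Label smoothing (factor 0.1) is provided as a comparison loss.

The optimizer is Adam (the optimizer is unstated upstream; Adam is the
common choice at learning rates of this order); the schedule is cosine
annealing with warm restarts: the rate starts at `base_lr`, reaches
`eta_min` exactly at step `T_max`, and the following step restarts the
decay from `base_lr`.  `T_max` defaults to one period spanning the whole
run.  Paper-scale defaults (50 epochs, batch 8, lr 1e-5) are retained as
the config defaults; the miniature benchmarks use batch 32 and lr 1e-3,
chosen once for the desk-scale networks and data.

Model selection keeps the best validation accuracy, ties resolved toward
the earlier epoch.  Validation always runs in eval mode with augmentation
disabled.  All run randomness derives from one seed through named streams
(data order, augmentation, attention-map selection) keyed additionally by
epoch, so runs are bitwise reproducible and resumable.

During distillation the teacher is frozen: its outputs enter the student's
graph as constants, and a checksum assertion verifies the teacher's
parameters are unchanged afterwards.

## Augmentation

Per batch and per tile, each enabled operation is independently included
with its probability (default 0.5) and applied in a fixed listing order:
random flip, random rotation, horizontal flip, vertical flip, saturation
jitter, additive Gaussian noise, outline extraction, smoothing.  Rotation
uses reflect padding with an angle drawn from ±30° (an exact 90°-multiples
mode exists for tests); "outline extraction" is a Sobel edge-magnitude map
blended with the source at weight 0.5 (the operator is unspecified
upstream; blending preserves the 3-channel contract); smoothing is a
Gaussian blur (sigma 1).  Augmentation happens in memory, never touches
labels or masks, and is excluded from evaluation.

## Slide-level inference

No mask exists at inference, so every enumerated window is classified.
The slide call is a majority vote over windows called as tumor; a slide
with only normal calls is normal; ties break by higher mean class
probability.  (The vote rule and the overlap arithmetic are this package's
choices — the source describes the stages but not the combination.)
Tumor-called windows are segmented by the U-Net trained for the called
class; per-pixel probabilities of overlapping windows are averaged and
thresholded at 0.5 (configurable).  Normal-called windows contribute
zero probability over their footprint.  Edge pixels covered by no full
window are reported as uncovered.  Attention heatmaps are assembled the
same way from per-window normalised attention maps.

## Synthetic data

The generator stands in for the private clinical dataset, which is not
available.  Each slide is a filtered-Gaussian-noise texture with a
per-class RGB tint, dominant spatial scale and contrast amplitude
(normal: pale pink, smooth; the three tumor classes: purple/green/brown
with finer texture).  Tumor slides carry one lesion — a thresholded
smoothed-noise blob, or a rectangle when exact areas are needed — whose
area fraction is drawn from the configured range and whose pixels come
from the class texture; the mask is 1 exactly there.  Everything is
deterministic in (config, class, seed).

The miniature study conditions: 256-px slides (the same tiling arithmetic
as gigapixel slides, scaled by 8), 64-px patches at stride 32, lesion
fractions 0.35–0.6 (so tumor slides yield enough fully-covered windows
under the strict 3/4 rule), 15 slides per class for the classification
benchmark (~870 training patches) and 8 per class with rectangular lesions
for the slide-level benchmark.  The encoded-size filter is disabled at
this scale — it is calibrated for 512-px tiles of stained tissue.

What passing these benchmarks shows: the tiling/cleaning arithmetic, the
attention-crop geometry, the loss algebra, the training loop and the
slide-level assembly are correct, and the architectures can learn
class-conditioned texture statistics.  What it does not show: performance
on real H&E morphology — the synthetic classes are separable by color and
texture scale alone, far easier than real tumor discrimination; there are
no staining artifacts, pyramid levels, or annotation noise.  Reported
accuracies on synthetic data therefore validate machinery, not clinical
performance.

## Numerical choices

float32 throughout the networks; He-normal initialisation; BatchNorm with
momentum 0.1, eps 1e-5, running statistics for eval; Adam (0.9, 0.999,
eps 1e-8).  Probability clamps at 1e-12 before logarithms.  Segmentation
metrics define two empty masks as IoU = Dice = 1 (logged).  Metric ratios
with zero denominators return an explicit undefined flag rather than NaN.
The deep-learning core is a compact NumPy tape autodiff whose convolution
is evaluated as kh·kw shifted GEMMs in channels-last layout; gradients of
every operator are verified against central differences in the test
suite.

## Known limitations

Single-threaded CPU training only; no mixed precision, no multi-GPU, no
ImageNet-pretrained initialisation (networks train from scratch).  The
U-Net stage uses classification-time augmentation only — geometric
augmentation is not mask-coupled.  The encoded-size cleaning rule depends
on the chosen codec; on-disk format of the original data is unknown.
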