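# Methods

## Problem and model

Moyamoya disease (MMD) staging from digital subtraction angiography (DSA) is a
three-class video-classification problem: a hemisphere's DSA run is summarised
as 10 consecutive frames starting at contrast arrival, cropped to the region
of interest and resampled to 224×224, and labelled *mild* (Suzuki 1–2),
*moderate* (3–4) or *severe* (5–6).

The classifier is a four-stage bottleneck residual network whose 3-D
convolutions are factorized into a spatial `1×3×3` operator and a temporal
`3×1×1` operator. Inside each bottleneck (`1×1×1` reduce → core → `1×1×1`
expand, skip connection, ReLU after the addition) the core takes one of three
topologies — serial `T(S(u))`, parallel `S(u)+T(u)`, serial–parallel
`S(u)+T(S(u))` — and blocks cycle through the three variants over the global
block index, crossing stage boundaries. Both operators are dilated at rate
`r`: a `k`-tap kernel covers `K = r(k−1)+1` cells, and same-padding
`r(k−1)/2` keeps feature resolution, so the receptive field grows without
parameter cost or pooling. The default dilation rate is 2.

## Architecture defaults and parameter accounting

* Layout (3, 8, 36, 3), widths 64/128/256/512, expansion 4 → 50 blocks.
* Stem: `1×7×7` conv, stride (1,2,2), 64 channels, then `1×3×3` spatial
  max-pool, stride (1,2,2). No temporal mixing before the blocks.
* Stride: the first block of stages 2–4 downsamples spatially by 2; the stride
  sits on the entry pointwise conv so all three variant topologies keep
  addable branch shapes. No temporal downsampling: a 10-frame input keeps 10
  frames until the global average pool.
* Temporal convolutions are enabled per stage, default `(on, on, on, off)`:
  the final stage uses frame-wise 2-D bottlenecks. This follows the widely
  used public implementation of the pseudo-3D family, in which the last stage
  is purely spatial, and it is the configuration that reproduces this
  architecture's canonical count of 65,678,787 ≈ 65.68 M. With temporal
  convolutions in all four stages the count would be 68.04 M.
* Normalisation/activation: batch normalisation (learned scale/shift, running
  statistics) after every convolution and ReLU activations, with the final
  ReLU after the residual addition — the standard residual-unit convention.
  Convolutions carry no bias (redundant with the normalisation shift), which
  keeps parameter counts well-defined.
* Head: global average pool over (T,H,W), one affine layer with bias.
* Input channels default to 3 (grayscale replicated, for compatibility with
  natural-video pretrained weights); a 1-channel switch exists and is used by
  the from-scratch synthetic runs.
* The dense C3D reference (8 × 3×3×3 convs at 64–512 channels, 5 pools, two
  4096-wide FC layers over an 8192-dim feature, biases everywhere) totals
  78,008,067 ≈ 78.01 M with a 3-class head. Its final pool pads spatially so
  the canonical 112×112, 16-frame input lands on the 4×4 grid feeding fc6.

Parameter counts are pure functions of the configuration: a closed-form
per-block count is asserted against the instantiated model, dilation never
changes a count, and the per-layer inventory always sums to the live total.

## Numerical core

No deep-learning framework is used: the package implements forward and
reverse passes for 3-D convolution (arbitrary stride/dilation/zero-padding,
computed as a loop over kernel taps accumulating BLAS mat-muls), batch
normalisation, ReLU, max/average pooling and affine layers, plus momentum SGD
with L2 weight decay, in float32 numpy. Gradients are verified against
central differences, and convolutions against a scipy.ndimage dense-kernel
oracle with zero-inflated dilated kernels. Max-pool ties break to the first
tap; argmax label ties break to the lowest class index; both are
deterministic. All randomness (weight init, shuffling, augmentation,
phantoms) flows from explicit `numpy.random.Generator` seeds, so runs are
bit-reproducible on a platform.

## Preprocessing pipeline

* Ingest normalises each sequence to [0,1] by per-sequence min–max (the
  source pipeline states no normalisation; min–max is the least committal
  choice for subtraction images whose absolute scale is arbitrary).
* Start frame: manual-first (manifest field), with an advisory heuristic —
  the frame with the largest frame-to-frame decrease in mean intensity, since
  contrast arrival darkens vessels in subtraction images. A constant or
  monotonically brightening sequence returns frame 0 flagged low-confidence.
* Windowing takes the start frame plus the following nine; too-short
  sequences raise an error naming the available count rather than padding.
* Crop/resize: one box for all frames, bilinear resampling to 224×224,
  identity short-circuit when the box already matches the target.
* Augmentation is the 8-element dihedral group (right-angle rotations ×
  horizontal flip) — the only lossless symmetries of a square raster; the
  same view is applied to every frame and labels are unchanged.
* Splitting is stratified per class with largest-remainder rounding to
  6:2:2 (ties in the remainder go to train, then validation, then test, so
  class sizes 516/512/515 give train sizes 310/307/309), keyed by source id
  so augmented views can never leak across splits. Classes with fewer than
  three items go entirely to train with a warning.

## Synthetic phantom generator

The generator emulates the three stage phenotypes, not anatomy:

* **mild** — visible trunk with stenotic distal narrowing
  (`stenosis_factor` 0.55), sparse abnormal-vessel cloud (expected 15
  speckles), no collaterals;
* **moderate** — dense cloud (70 speckles) around a dimmer trunk;
* **severe** — trunk visibility 0.03 (effectively absent), sparse residual
  cloud (6), four peripheral collaterals.

Structures are drawn as Gaussian-profile polylines on a 224×224 canvas and
ramped over the 10 frames with a logistic bolus profile whose steepest
frame-to-frame increase lands exactly on the structure's arrival frame, so
the start-frame heuristic has a recoverable ground truth. Gaussian pixel
noise (σ = 0.02) is added and values clipped to [0,1]; vessels are dark on a
0.85 background (subtraction convention). Per-sample seeds derive from a
master seed, and regeneration is bit-identical.

A health gate (`separability_check`) computes two scalar features per sample
— final-frame dark-pixel count (< background − 3σ) and the frame of steepest
mean-intensity drop — and requires nearest-centroid accuracy > 0.8 with the
default parameters. What passing tests show is therefore that the *pipeline
and model learn the intended phenotypes*; they say nothing about performance
on clinical DSA, which has skull-subtraction artifacts, anatomical
variability, observer-dependent ROI choices and far subtler class boundaries.

## Training harness and the desk-scale experiment

Training is softmax cross-entropy with momentum SGD (lr 0.05, momentum 0.9,
weight decay 1e-4, ×0.1 decay late in the run), batch size 16, one random
dihedral view per sample per epoch, best checkpoint by validation accuracy
(ties prefer the later epoch, whose normalisation statistics are more
mature). The training recipe is this package's choice; every knob sits in
`RunConfig`.

The end-to-end demo generates 100 sequences per class at 10×224×224, splits
6:2:2, and trains a compact network (one block per stage, widths 8/16/32/64,
stem width 16) on frames downsampled to 56×56 — the problem size at which the
numpy core trains in a couple of minutes on one CPU while leaving the task
non-trivial. Evaluation uses 8-view test-time augmentation. Quality gates:
test accuracy ≥ 0.90 and macro AUC ≥ 0.95, required to hold for at least 4 of
the 5 default seeds.

## Metrics

Accuracy is the confusion-matrix trace over the total; per-class precision,
recall and specificity follow the one-vs-rest reading of a matrix oriented
rows = predicted, columns = actual; F1 is the harmonic mean of the class's
own precision and recall. AUC is the rank statistic
`(Σ ranks of positives − M(M+1)/2)/(M·N)` with mean ranks on ties
(Mann–Whitney convention; the bare formula is silent on ties), proven in the
tests to equal the trapezoidal ROC area and the concordant-pair fraction.
Micro-averaging flattens the one-hot label indicator matrix against the score
matrix; macro-averaging interpolates per-class TPR onto the union of FPR
breakpoints and averages with equal weight. Metrics with zero denominators
are reported as flagged-undefined (NaN), never coerced to 0, because silent
zeros corrupt macro averages. Reports keep full precision internally and
format at 3 decimals in CSV.

## Known limitations

* The phantom generator is a statistical stand-in; no hemodynamics, no
  anatomy, no artifacts, and no claim of clinical transfer.
* The numpy core is single-device and desk-scale; the full-size network is
  buildable and countable, but training it is out of scope.
* No automated artifact filtering is attempted; artifact-laden sequences
  should be excluded upstream.
* Pretrained-weight import is a name-mapped hook only; nothing depends on it.
* Only the dense C3D reference is reconstructed for parameter comparison;
  other 3-D video baselines (18-layer R3D / R(2+1)D) are out of scope.
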