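# Methods

## Overview

The package measures Parkinson-related neuromelanin loss in the substantia
nigra pars compacta (SNpc) from axial NM-MRI-like slices in three stages:
(1) a cascaded pair of U-nets produces midbrain and SNpc masks, (2) a
background-referenced intensity threshold converts the SNpc mask into a
hyperintense area in mm², and (3) an evaluation layer scores segmentation
agreement (Dice) and diagnostic performance (ROC/AUC, DeLong, group tests).
A synthetic phantom generator supplies cohorts with exact ground truth, so
every stage is testable without patient data.

## The hyperintense-area statistic

Let the midbrain mask be M and the SNpc mask S ⊆ M on the two consecutive
axial slices with the largest total midbrain pixel count (ties resolve to the
smaller slice index).  The background is B = M ∖ S; its mean signal MSI and
sample standard deviation SD (ddof = 1) are pooled over both slices — one
statistic per subject.  For a multiplier k, the hyperintense area is

    area(k) = #{ p ∈ S : I(p) > MSI + k·SD } × (pixel row spacing × col spacing)

with a strict inequality ("above the threshold" read literally).  k is swept
over {1, 1.5, 2} on a labelled cohort; the value with the highest AUC
(orientation: low area indicates PD) is frozen and can be applied unchanged to
an external cohort.  Ties in the sweep resolve to the smallest k.

Properties relied on throughout (and enforced by tests):

- area(k) is non-increasing in k;
- area/pixel-area is always the integer suprathreshold count;
- the count is invariant under any positive affine intensity map
  x → a·x + b, since the threshold transforms identically;
- the relative background variation MSI/SD (an image-quality index) is
  undefined at SD = 0 and raises.

The area is reported in mm²: two 2D slices are measured, and count × pixel
area is an area, not a volume.

## The segmentation cascade

Two structurally identical U-nets with two output classes each:

- **net 1** (input: 1 channel, the raw slice) separates midbrain from outside;
- **net 2** (input: 2 channels) separates SNpc from background *within* the
  midbrain.  Its second channel is net 1's midbrain probability map (soft
  gating, the default): a hard-masked variant exists, but soft gating keeps
  early training informative when net 1 is still noisy.

Architecture: encoder/decoder with skip connections; downsampling by 3×3
convolution with stride 2 (no max pooling); upsampling by non-overlapping 2×2
transposed convolution; ReLU activations; 1×1 output head; He-normal
initialization.  Depth and base channel width are configurable because the
original architecture's channel counts are not fixed by the recipe this
implements; two presets are provided:

| preset      | depth | base channels | crop | Adam α | input scale |
|-------------|-------|---------------|------|--------|-------------|
| fullscale  | 4     | 64            | 256  | 1e-4   | 1.0         |
| desk        | 3     | 8             | 96   | 1e-3   | 0.01        |

Training (per iteration): draw a batch of 2 random square crops, forward both
nets, compute mean softmax cross entropy per net — net 2's loss averaged only
over pixels inside the *truth* midbrain, where its task is defined — and apply
two independent Adam updates (β₁ = 0.5, β₂ = 0.999).  The two losses are
disconnected: no gradient flows from net 2's loss into net 1 (the probability
map is passed as data), and freezing either net leaves its weights
bit-identical.  Ten epochs, no early stopping.  Cross-validation is stratified
into folds with an HC:PD ratio as close to 1:1 as counts allow; the fold-1
model is the deployment model.

Inference processes full slices (reflect-padded to the nearest multiple of
2^(depth−1), then un-padded).  Per pixel, net 1's argmax decides midbrain
vs. outside; within the predicted midbrain, net 2's argmax decides SNpc vs.
background.  At exactly tied probabilities the lower class index wins, so
prediction is deterministic.

The nets run on a small numpy CNN core (`nigraseg.nn`): im2col + GEMM
convolutions, explicit backpropagation, Adam with bias correction.  Every
layer's gradient is verified against central finite differences in the test
suite (float64, relative error ≤ 1e-5).

**Desk-preset conditioning.**  The full-resolution optimizer settings (α = 1e-4 on
raw intensities of order 100) are tuned for long GPU runs on 512² images.  At
desk scale the preset applies a fixed global intensity scale of 0.01 (the same
constant for every image at train and test time — *not* per-image
normalization, so the no-normalization contract is preserved) and α = 1e-3.
These are engineering choices of this package, recorded here; the fullscale
preset keeps the original values.

## Data augmentation

Each training subject is expanded by intensity deviation A(orig + B)
(A ∈ {0.7, 1.0, 1.3}, B ∈ {−100, 0, 100}), in-plane rotation (−30°/0°/+30°)
and rescaling to 90/100/110 % of size at fixed canvas.  Images are
interpolated bilinearly, masks by nearest neighbour (the label alphabet never
grows); pixels entering from outside the canvas take the image minimum /
OUTSIDE.  Whether the original recipe crossed the three axes is not stated,
so both behaviours exist: `cartesian` (3·3·3·3 = 81 variants, the default)
and `per_category` (single-axis deviations, 13 variants).  Augmented sets are
precomputed before training (on-the-fly sampling is not used).  Because A > 0
is monotone on pixels, intensity augmentation never changes the
suprathreshold set of the quantification stage.

The desk training preset uses a reduced per-category grid (±15°, ±5 % scale,
no intensity deviation — the phantom's per-subject geometry jitter already
varies pose) to keep one training run at ~1,200 iterations, about two minutes
on one CPU core.

## The phantom generator

Each subject is a 4-slice stack of 128×128 pixels at 0.43 × 0.43 mm; the
midbrain appears on slices 1–2 as a convex "butterfly" (a tegmentum ellipse
plus two peduncle lobes), containing two crescent-shaped SNpc regions
(ellipse minus a shifted copy, one per side).  Shapes are evaluated
analytically on a coordinate grid pulled back through a per-subject
similarity transform (shift ±4 px, rotation ±8°, scale 0.9–1.1), so truth
masks are exact.  Intensities: outside 50, midbrain background 100,
hyperintense SNpc 100 + 40, additive Gaussian noise σ = 8 (a Rician option
exists but is off by default — at midbrain SNR the Gaussian approximation is
standard and keeps the noiseless oracle exact).

The disease effect acts on the *extent* of the hyperintense sub-region: a
fraction of SNpc pixels (HC 0.95, PD 0.55, per-subject SD 0.05) keeps the
hyperintense mean, the rest fall to background intensity.  The retained
pixels are the most medial ones, mirroring the preferentially lateral pattern
of nigral signal loss; an alternative mode attenuates the contrast instead.
PD subjects also receive a motor score that tracks the planted loss, so the
negative area–severity correlation is reproducible.  Per-subject seeds derive
from (cohort seed, group, index), making generation order-independent and
bit-reproducible.

What the phantom does *not* emulate: bias fields, partial-volume effects,
k-space/acquisition physics, anatomical variability beyond similarity jitter,
or inter-reader segmentation disagreement.  Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline — exact
quantification, calibrated statistics, a cascade that can learn and transfer
the task — not clinical performance on real scanners.

## Evaluation layer

- **Dice** 2|A∩B|/(|A|+|B|) per structure over the selected slice pair;
  both-empty regions score 1 (agreement on absence — the conservative choice
  for phantom slices without midbrain).  Rating scale as printed: < 0.40 low,
  0.40–0.79 moderate, ≥ 0.80 high.
- **ROC/AUC** by the rank method (ties count ½), so AUC ≡ U/(n₁·n₂); the
  optimal cut-off maximizes Youden's J with ties resolved toward higher
  specificity.  For areas the orientation is low-is-positive and the cut-off
  is reported in mm² with positivity meaning area ≤ cut-off.
- **DeLong** comparison of two correlated AUCs via placement values; the
  variance of the AUC difference combines the per-positive and per-negative
  placement covariances.  Self-comparison returns z = 0, p = 1; zero variance
  with unequal AUCs raises rather than fabricating a p-value.
- **Spearman** rank correlation (average ranks on ties) with the five-level
  strength scale on |r| (< 0.20 very weak … ≥ 0.80 very strong).
- **Group tests**: classic equal-variance Student t (not Welch, matching the
  reference analysis), two-sided Mann–Whitney U, and χ² on 2×2 tables without
  continuity correction.

## Problem sizes and determinism

Default experiment sizes are chosen so a full pipeline run trains in about
two minutes and the complete test suite in well under ten on one CPU core:
training cohorts of 16 subjects (8 HC + 8 PD), evaluation cohorts of 40
(20 + 20), desk-preset networks, 10 epochs ≈ 1,200 iterations.  All
randomness flows from explicit integer seeds through `numpy.random`
generators; phantom generation, training and inference are bit-reproducible
for a fixed seed.

## Known limitations

- The CNN core is CPU-bound numpy; the fullscale preset (depth 4, 64
  channels, 256² crops) is provided for fidelity of configuration, not for
  routine training.
- Slice thickness/gap are carried as metadata only; no volumetric
  reconstruction is attempted (two slices × pixel area is an area).
- NIfTI `pixdim[3]` stores spacing-between-slices, so thickness and gap are
  not separable on read; only in-plane spacing enters any computation.
- Left/right SNpc are not distinguished: the statistic is one area per
  subject.
- Sub-regional (posterolateral) SNpc analysis and reader-drawn mask dialects
  beyond an integer label mapping are out of scope.
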