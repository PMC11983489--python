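# Methods

## Problem setting

Microscopic hyperspectral pathology images (MHSIs) are microscope image
cubes — here nominally 512×512 pixels with ~40 contiguous spectral bands —
with pixel-level binary annotations separating lesion tissue from
background. Lesions vary in size and shape, their boundaries are often
blurred or broken, spectrally similar isolated structures sit in the
background, and the bands are strongly correlated. BE-Net is an
encoder–decoder segmentation network built to privilege boundary evidence
in this setting, using two ideas: fixed second-derivative (Laplacian of
Gaussian) structure inside learnable convolutions, and parameter-free
attention weights derived from Shannon entropy.

## The network

**Backbone.** A U-Net with stage widths (16, 32, 64, 128, 256) — one
quarter of the standard (64, …, 1024) — on inputs reduced to 2 spectral
bands by PCA. Four 2×2 max-pool downsamplings; decoder upsampling by 3×3
stride-2 transposed convolutions; a final 1×1 convolution to 2-class
logits. Spatial size must be divisible by 16.

**LoG-modulated convolution (LoGC).** The LoG operator

    LoG(p, q, σ) = 1/(πσ⁴) ((p²+q²)/(2σ²) − 1) exp(−(p²+q²)/(2σ²))

is sampled at integer offsets on a 5×5 grid (center value −1/(πσ⁴), zeros
on the circle p²+q² = 2σ²) and multiplied elementwise into a learnable
5×5 kernel on every forward pass; gradients flow into the learnable part
only. σ defaults to 1.0 (the natural scale for a 5×5 support, where the
zero-crossing circle falls inside the grid) and is configurable. The raw
sampled matrix is used by default; a `zero_sum` option subtracts the mean
so constant inputs map to zero under uniform learnable weights. `⊛` is
cross-correlation (the deep-learning convention); the LoG matrix is
symmetric, so this choice is immaterial for the fixed factor.

**Channel entropy attention (CEA).** Per channel, the (global max, global
mean) pair is softmaxed and its entropy H compared with log 2; the channel
is scaled by `W_c = 1 − H/log 2 ∈ [0, 1]`. A spatially constant channel
(max = mean) is fully suppressed; a channel with a strong localized
response is kept. Pure multiplicative reweighting, no residual (a
`cea_residual` flag adds one), computed per batch item.

**Spatial entropy attention (SEA).** Per pixel, the C-channel vector is
softmaxed and its entropy normalized by log C, giving `W ∈ [0, 1]` with
W = 1 where all channels agree — typically uncertain, boundary-like
pixels. Entropy uses natural logs; the base cancels in both ratios.
Probabilities are clamped at 1e−12 inside p·log p so exact zeros
contribute their analytic limit 0.

**LCB** (each encoder level): LoGC(5×5) → BN → ReLU → 3×3 conv → BN →
ReLU → CEA. The bottleneck LCB carries a second 3×3 conv, mirroring the
U-Net double-conv bottleneck.

**GMB** (each skip connection): concatenate the C-channel skip with the
C-channel upsampled decoder map, split the 2C channels into four groups of
C/2. The two skip-derived groups get 3×3 convolutions at dilations 2 and 3
(context for shallow features); the two decoder-derived groups get a 1×1
and a plain 3×3 (detail for deep features). Each group maps C/2 → C with a
BatchNorm after the convolution so the four maps can be summed, then ReLU,
then CEA.

**MSB** (after each GMB): a cascade of three 3×3 convolutions at dilations
1, 2, 3 — each stage consuming the previous stage's output, per-stage maps
(conv → BN → ReLU; an `hmb_literal_order` flag switches to the
BN-after-ReLU ordering) summed into the pyramid Y. Then Y′ = sigmoid(Y);
W1 = Y′ × mean of stride-1 max-pools of Y′ at kernel sizes 3/5/7 (the 5×5
and 7×7 pools are computed by nesting 3×3 max filters, an exact identity
with the −inf border convention); W2 = SEA weight map of Y (pre-sigmoid;
a flag switches to Y′); output = (W1 + W2)⊙Y + Y. Since W1 ∈ (0,1) and
W2 ∈ [0,1], the output-to-Y ratio lies in (1, 3).

With these choices the default BE-Net has **3,757,186** trainable
parameters (3.757M) and the full-width U-Net baseline **34,524,610**
(34.52M); the quarter-width baseline used for ablations has 2.16M. Where
the block placement was genuinely open (exact LCB layout, bottleneck
shape, upsampling kernel), the published parameter total was used as the
arbiter among otherwise-conventional choices.

## Training and evaluation protocol

SGD with momentum 0.9 and weight decay 1e−6, batch size 4, learning rate
0.01 (0.008 as the small-dataset alternative), 80 epochs in the full
protocol. Loss = 0.3 × two-class softmax cross-entropy + 0.7 × soft Dice
loss, where the Dice term is 1 minus the batch-mean soft Dice of the
foreground probability with smoothing ε = 1e−5 in numerator and
denominator. No learning-rate schedule and no augmentation (flags exist,
default off).

Metrics from the binary confusion matrix: OA, DSC, IoU, Precision,
Specificity, Sensitivity. Default aggregation is per-image mean, then
mean ± std across folds; a global-pooled mode is available, in which
DSC = 2·IoU/(1+IoU) holds as an algebraic identity. Undefined ratios
(zero denominator) report 1 when prediction and truth are both empty,
else 0. Five-fold cross-validation fits PCA on the training folds' pooled
pixels only and applies it to the held-out fold; bands are mean-centered
without variance scaling (they share units), and each component's sign is
fixed by making its largest-magnitude loading positive.

## Numerical implementation

The network runs on a small numpy reverse-mode autodiff core written for
this package (stride-1 dilated convolution via windowed `tensordot`,
transposed convolution as zero-stuffing + convolution, max pooling with a
separable forward filter and subgradient backward, fused BatchNorm).
Everything is float32; training is deterministic given the seed on fixed
hardware, and eval-mode forward passes are bitwise reproducible.
BatchNorm uses momentum 0.3 for its running statistics so that eval-mode
statistics track the batch statistics within the few hundred optimizer
steps a phantom run takes; with the conventional 0.1 the running
estimates lag the rapidly-moving early training distribution and
validation scores stay pinned at zero for several epochs. Max-pool ties:
the 2×2 downsampling pool routes the gradient to the first maximum in the
window; the stride-1 pools give the full gradient to every tied maximum
(ties have measure zero for the sigmoid-valued inputs they see).

## Synthetic phantoms

The phantom generator emulates the statistical structure of MHSI data at
configurable size (tests use 64×64×8): two tissue classes with smooth,
overlapping Gaussian-bump spectral signatures separated by a configurable
distance; one to four lesion blobs with anisotropy and radius wobble,
accepted only if the lesion fraction lands in [0.1, 0.5]; optional
boundary blurring that softens the spectral transition while the label
stays crisp; isolated lesion-like distractors in the background (labelled
background); per-pixel multiplicative signature jitter; and
band-correlated Gaussian noise. Two presets: an *easy* profile (high
separation, low noise, no distractors) that any reasonable pipeline
should segment, and a *boundary-blur* profile (blur σ 2.5, noise 0.15,
distractor density 3 per 64×64 tile) probing boundary robustness.

Phantoms are not real pathology: they lack stain variability, texture,
multi-scale tissue morphology and instrument effects. Passing the phantom
suites demonstrates that the architecture, loss, metrics and harness are
implemented correctly and that the boundary-oriented design helps on
boundary-degraded data — not that real-data accuracies would be
reproduced.

## Test problem sizes

The CPU test profile trains on 16 phantoms (8 validation) at 64×64×8 →
PCA 2: the learning smoke test requires seed-averaged (3 seeds) best
validation DSC ≥ 0.90 within at most 8 epochs on the easy profile; the
directional ablation requires BE-Net's mean best DSC ≥ the quarter-width
U-Net's over 3 seeds on the boundary-blur profile. These sizes are the
package's test profile; the full protocol (hundreds of images, 80 epochs)
is available through the same functions and CLI.

## Known limitations

- CPU-only; a 512×512 forward pass takes minutes, so the full-resolution
  protocol is impractical here and the harness targets small cubes.
- The published block layout is under-specified; the layout implemented
  here reproduces the published parameter count exactly, but other
  layouts with the same count are conceivable.
- FLOP figures depend on counting conventions; this package reports conv
  MACs and 2×MACs and treats published FLOPs as an order-of-magnitude
  check only.
- The `bilinear` upsampling mode named in the configuration is reserved
  but not implemented; transposed convolution is the only mode.
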