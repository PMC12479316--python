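# Methods

## Problem and model

The package translates a single-channel overhead depth image of a person
lying on a hospital bed into the 27×64 contact-pressure map an instrumented
mattress would record. Continuous pressure maps are the quantity clinicians
monitor for pressure-ulcer risk; depth cameras are cheap and contactless,
so learning the depth→pressure mapping replaces the sensor mat at inference
time.

The generator (`AttnFnetGenerator`) is a hybrid transformer/convolutional
encoder–decoder:

* A strided convolution cuts the padded depth image into patches (default
  patch size 8 on a 128×56 input → a 16×7 token grid) and projects each to a
  712-dimensional embedding. Fixed sinusoidal encodings of the flattened
  token index are added.
* 12 transformer blocks follow (pre-norm). Attention is standard multi-head
  scaled dot-product with a single residual added after head concatenation
  and output projection. The feed-forward stage has two variants: a
  token-wise MLP (`ff_variant="mlp"`, hidden width 2×d), or two 3×3
  convolutions applied to the tokens laid out on their spatial grid
  (`ff_variant="conv"`, the default), which gives the feed-forward path a
  local spatial receptive field inside each block.
* The decoder reshapes the block-12 tokens to the spatial grid and
  upsamples with transposed convolutions. Outputs of blocks 6, 8 and 10 are
  skip connections: each is 1×1-projected, bilinearly resized to the stage
  resolution, and concatenated before the stage's deconvolution, deepest
  block feeding the coarsest stage (the U-Net convention). Since all skip
  grids share one resolution, this assignment is a design choice, not
  forced by shapes. Two stages are stride-2; the third is a stride-1
  refinement so the network never upsamples past the output resolution. A
  1×1 head, bilinear resize into the 27×64 sensor frame, and a sigmoid
  produce the map in [0, 1] model units.

The discriminator is a PatchGAN: depth is resized into the pressure frame
and concatenated channel-wise with a real or generated map; three stride-2
convolutions (base 64 channels, leaky slope 0.2) and a final 3×3 convolution
emit a grid of per-patch logits. The scalar D(x|y) used in the objectives is
the mean per-patch sigmoid probability. A conventional convolutional U-Net
with mirror skips (`UNetGenerator`) provides a baseline under the same
input/output contract.

Because no deep-learning framework is part of the runtime, the models run
on a small reverse-mode autodiff engine (`attnfnet.nn`) written on NumPy:
~15 primitives (broadcast arithmetic, batched matmul, im2col convolution
and transposed convolution, softmax, reductions, shape ops, bilinear
resize) verified against central differences in the test suite. Float64
everywhere makes reruns bit-identical.

## Training objective

The discriminator minimizes label-smoothed binary cross-entropy with
targets y_real = 0.9 for real pairs and y_gen = 0.1 for generated ones,
averaged over batch and patch positions. Its minimum over (D_real, D_fake)
is exactly (0.9, 0.1), which the tests verify on a grid.

The generator minimizes

    L_G = −log D(x|G(x)) + λ · [α(1 − SSIM(y, G(x))) + β · MSE(y, G(x))]

with λ = 100, α = 300, β = 1. The pixel term is the **mean** squared error:
with a summed L2 term the stated α/β balance would depend on image size
(1728 pixels would swamp the SSIM term), whereas the mean keeps the two
terms on the intended scale and matches the MSE evaluation metric. SSIM
uses an 11×11 Gaussian window (σ 1.5), population moments, reflect
boundary, C1 = (0.01 L)², C2 = (0.03 L)² with L the model-unit range —
standard values; the window parameters are not dictated by the objective's
definition, so they are configurable in `SSIMParams`.

Optimization is Adam (β1 = 0.5, β2 = 0.999), batch size 1, one D update
then one G update per sample with a fresh discriminator evaluation for the
generator's adversarial term. Defaults: learning rate 1e-4 for the
transformer generator, 2e-4 for the U-Net baseline, 90 epochs, no learning
rate decay, no early stopping; validation MSE/SSIM are logged every epoch
so a divergence (the usual mode-collapse signature of this recipe) remains
visible in the history. Probabilities are clamped at 1e-7 for log
stability.

Two numerical choices deserve emphasis because they decide whether
desk-scale training converges at all:

* **Gradient-norm clipping (default 10).** λ·α ≈ 3·10⁴ makes raw generator
  gradients enormous early in training; unclipped they both overshoot the
  bounded output activation and inflate Adam's second-moment state so far
  that recovery stalls within a short run.
* **Pressure targets in [0.05, 0.95].** Pressure maps are mostly exact-zero
  background. Min-max normalizing them onto the full [0, 1] sigmoid range
  puts the dominant target value at an asymptote the activation can only
  approach through saturation, and a saturated background silences the
  gradients of the (few) body pixels too — the observed failure mode is a
  collapse to an all-zero map that never recovers. Keeping both extremes
  strictly inside the output range removes the trap; `denormalize` maps
  0.05 back to raw zero, and predictions are clamped nonnegative. The
  output head's bias is initialized to −3 ≈ logit(0.047), so the network
  starts at the background level rather than 0.5 (the standard prior-init
  trick for sparse targets). Depth inputs are min-max normalized to
  [−1, 1] with statistics computed on the training split only.

## Synthetic data generator

The generator emulates the structure of a real depth-camera + pressure-mat
cohort: paired samples, three postures (supine, left/right lateral),
subject identities with body mass, and a per-subject calibration scalar
converting raw sensor counts to kPa. It does **not** attempt anatomical
realism.

* **Body model.** Seven elliptical-Gaussian lobes (head, torso, pelvis, two
  arms, two legs) in normalized bed coordinates, scaled per subject by a
  length/width factor and a mass-dependent thickness (∝ mass^⅓). A 4%-of-
  peak floor is subtracted so the background is exactly zero. The supine
  layout is constructed symmetrically (paired lobes share their jitter);
  the right-lateral field is by construction the exact mirror of the
  left-lateral one, which is itself deliberately asymmetric (draped free
  arm, stacked offset legs, shoulder prominence).
* **Depth.** range = camera height (2 m) − body height, plus Gaussian noise
  (default 3 mm) and optional no-return dropout pixels set to 0, the
  camera sentinel convention.
* **Pressure.** Local pressure ∝ thickness^1.5 — any monotone map would do;
  the superlinear exponent concentrates load under the hips and shoulders
  the way bony prominences do. The field is area-average resampled onto
  the 27×64 sensor grid (interval-overlap weights, so constants and totals
  are preserved exactly), perturbed by 2% multiplicative sensor noise, and
  rescaled so that Σ p·area = m·g **exactly**. Force conservation is the
  generator's load-bearing invariant: integrating any calibrated map
  recovers the subject's mass to machine precision, which closes the loop
  with the weight-estimation metric.
* **Cohort.** Mass ~ N(70, 12²) kg clipped to [45, 110]; shape scales
  uniform on [0.85, 1.15]; calibration uniform on [0.02, 0.08] kPa/count.
  Postures cycle per subject. Splits are drawn subject-wise (default
  0.6/0.2/0.2, floor rounding for val/test, remainder to train) so no
  subject leaks across splits.

What the generator does not emulate: articulated posture variation within
a class, clothing/blanket occlusion, mattress deformation, sensor
crosstalk, or realistic depth-camera artifacts beyond dropout. Passing
tests therefore demonstrate that the pipeline is correct and that the
architecture can learn a physically coupled depth→pressure mapping — not
that it reaches any particular accuracy on real patients.

## Preprocessing

* Depth cleaning: no-return pixels are repaired by the median of their
  valid 3×3 neighbors, iterated until none remain (an all-sentinel frame is
  an error); values are clipped to a configured range and center-cropped /
  edge-padded so the patch grid divides evenly.
* Pressure smoothing: area-average resample to 27×64, then a Gaussian blur
  (σ = 1.4, truncated at 4σ, reflect boundary — the truncation and
  boundary are our stated defaults), clamped nonnegative.
* Orientation convention used everywhere: depth arrays are
  (length, width) with row 0 at the head end; pressure arrays are (27, 64)
  with axis 0 across the bed width and axis 1 along its length. Archive
  readers reject transposed pressure grids by name.

## Evaluation

Per sample: PPA (fraction of pixels within a tolerance; "correct" is
undefined in the abstract, so the default tolerance is 5% of the
ground-truth map's peak, configurable), SSIM, MSE in raw units and kPa²,
PSNR (max over the calibrated test set; identical pairs give +inf and are
excluded from the mean with a count), posture IOU (largest 4-connected
component above a threshold, default 1 kPa, in each map), and estimated
body weight Σp·1000·area/9.81. Set-level: Fréchet distance between
Gaussian fits of embedded maps with a symmetrized matrix square root. The
default embedder is a fixed, seeded Gaussian random projection so the
metric runs without downloaded weights; values are internally consistent
for comparing models but **not comparable** to Fréchet distances computed
with a pretrained network, which can be injected via `embed_fn`.

## Desk-scale preset and problem sizes

The `tiny` preset keeps the full structure at CPU scale: 8 subjects × 21
poses (the real cohort this emulates offers 45 poses per subject) at 64×56
depth resolution, 64-d embedding, 4 heads, 6 blocks with skips (3, 4, 5),
5 epochs at learning rate 2e-4, clip 10. One run takes a few minutes on a
single core. Its acceptance bar is relative, not absolute: held-out
validation MSE strictly below the constant predictor that outputs the
train-split mean map, i.e. the generator must demonstrably use the depth
image. Because adversarial training makes the per-epoch validation loss
oscillate, the bar is evaluated at the retained best-validation
checkpoint — the model a practitioner keeps — where it is met with a wide
margin across seeds; the final-epoch value is logged alongside. The
learning rate and cohort size were fixed while designing the preset; they
are ordinary config fields, not special cases in the code.

## Known limitations

* The 712-dimensional embedding is honored as specified (712 = 8 × 89
  heads×dims) though 768 is the transformer-standard width; both are just
  config values.
* The decoder's channel counts and kernel sizes, the conv-feed-forward
  width, LayerNorm placement (pre-norm) and the skip-to-stage assignment
  are this package's choices; alternatives would satisfy the same
  contracts.
* GAN training at desk scale is noisy: validation MSE oscillates between
  epochs, and the best-validation checkpoint (retained separately) is
  usually better than the final one.
* The Fréchet metric's default embedder makes its absolute values
  meaningless outside this package; only comparisons under the same
  embedder are valid.
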