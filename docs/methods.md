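# Methods

## Problem and model

The package predicts per-organelle fluorescence images — nucleus,
mitochondria, endoplasmic reticulum — from a label-free hyperspectral
stimulated-Raman-scattering (SRS) stack of C vibrational channels.  The
difficulty of the task comes from spectral overlap: each vibrational
channel mixes contributions from several molecular species, so no single
input channel isolates one organelle.

The predictor is a two-branch encoder with attention-based fusion:

* **CNN branch** — four stages of residual convolution blocks.  Stage 1
  widens channels at full resolution; later stages open with a stride-2
  convolution.  Three feature levels are exported at 1/4, 1/8 and 1/16 of
  the input resolution (`h2`, `h1`, `h0`).  The source description of the
  stage geometry is internally inconsistent (stages that halve resolution
  cannot land the second-stage export at 1/4 without an extra reduction),
  so an additional stride-2 transition sits between stages 1 and 2; this
  is the only reading under which the CNN levels align with the
  transformer decoder levels that the fusion bridge pairs them with.
* **Transformer branch** — 16×16 patches are flattened, linearly embedded
  (width S0) and given a learnable positional table; L = 8 pre-norm
  transformer layers (multi-head self-attention with per-head width
  d = S0/m, GELU MLP, dropout 0.1) contextualise the tokens.  The layer
  update is the standard `a = z + MSA(LN(z)); z' = a + MLP(LN(a))`; a
  variant that drops the first residual would disconnect each layer from
  its input's identity path and is not used.  A progressive decoder
  reshapes tokens to the 1/16 grid and emits maps at 1/16, 1/8, 1/4
  (nearest-neighbour upsample + 3×3 convolution per step) so that the
  three scales pair exactly with the CNN pyramid.
* **Fusion bridge** — per level: squeeze-excitation channel attention on
  the transformer map (reduction m = 4), pyramid spatial attention on the
  CNN map (channel mean/max maps convolved at kernel sizes 1, 3, 5, the
  three sigmoids summed, giving weights in (0, 3); an optional flag
  normalises by 3), a cross-branch bilinear Hadamard interaction
  (1×1 projections of both maps to the level width, elementwise product,
  3×3 convolution), and a concat + 3×3 convolution fuse with an additive
  1×1 projection shortcut.  The spatial-attention kernel ladder follows
  the (2k−1) formula, k = 1..3.  The bilinear term is read as
  s·W1 ⊙ h·W2 — W1's declared shape only type-checks against the
  transformer map, and a same-branch product would defeat the bridge's
  purpose.  The fuse and cascade convolutions carry batch normalisation,
  consistent with the architecture's convention that convolution blocks
  include normalisation layers; empirically this is load-bearing — the
  fusion path is multiplicative (bilinear products, attention
  rescalings), and without normalisation its feature scale grows by
  orders of magnitude within a few epochs, saturating the sigmoid head
  and stalling training at the constant predictor.
* **Gated cascade and head** — coarse fused features are upsampled and
  used as the gating context of an additive attention gate on the next
  finer fused level (q = ψᵀReLU(W_x s + W_g g + b); α = σ(q); ŝ = s·α),
  then concatenated and convolved.  The cascade ends at H/4; the
  decoder's upsampling path then jump-connects the encoder CNN's half-
  and full-resolution feature maps (two nearest-upsample + concat +
  3×3 conv-norm steps) before a 1×1 convolution and sigmoid emit the
  K = 3-channel prediction in [0, 1].  The full-resolution skip
  refinement matters: an H/4 head with a plain ×4 bilinear upsample
  cannot represent structures near the pixel scale (mitochondrial
  puncta, ER filaments), and in converged head-to-head runs such a model
  loses to the full-resolution U-Net baseline for exactly that reason.
  The head weights are scaled by 0.1 at initialisation so the sigmoid
  starts unsaturated.

The baseline is a plain 4-level U-Net (stride-2 encoder, nearest-upsample
decoder with skip concatenations, same sigmoid head contract).

Useful zero-weight anchors, used throughout the tests: with all attention
parameters zeroed, channel attention multiplies by sigmoid(0) = 0.5,
spatial attention by 3·sigmoid(0) = 1.5, and the gate by 0.5.

## Numerical substrate

The networks run on a package-internal reverse-mode autodiff core over
float64 numpy arrays (`mpfnet.nn`): batched matmul, im2col-style 2-D
convolution, elementwise nonlinearities, reductions, resampling, batch /
group / layer norm, SGD-momentum and Adam.  Every primitive's
vector-Jacobian product is validated against central finite differences
(~1e-9 agreement in double precision); the full fusion path is
gradient-checked end-to-end at 1e-4 relative tolerance.  Bilinear
upsampling is expressed through explicit interpolation matrices
(align-corners = false convention), making its adjoint exact.  Ties in
the channel-max used by spatial attention split the gradient equally.
All initialisation flows from one `numpy.random.Generator` per model
seed, so a model built twice from the same seed is bit-identical, and
eval-mode forward passes are deterministic.

## Metrics

NRMSE, SSIM, PCC, Dice and mIoU per organelle, plus pixel accuracies and
PSNR.  Conventions:

* NRMSE = RMSE / (max − min of the reference image).  The printed form of
  the source normalisation places the per-pixel max/min inside the sum,
  which is ill-defined for scalars; the conventional dynamic-range
  normalisation is used, making the score invariant to joint rescaling.
* SSIM uses an 11×11 uniform window, sample (n−1) covariance,
  C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2 and exponents m = n = p = 1
  on the luminance/contrast/structure components (configurable).  With
  defaults it agrees with `skimage.metrics.structural_similarity`
  (uniform window) to ~1e-10, which the tests assert as an independent
  cross-check.
* PCC is computed on the continuous intensities.  For binary inputs the
  same formula is the Matthews correlation coefficient; the package does
  not expose a separate MCC.
* Dice and mIoU operate on masks; continuous predictions are first
  min-max normalised and thresholded at 0.5 (Otsu optional).  A class
  absent from both images has undefined IoU and is excluded from the mean
  rather than scored zero; two empty masks have Dice 1 (vacuous
  agreement).
* Relative model-to-model changes are 100·(a−b)/b for
  higher-is-better metrics and 100·(b−a)/b for error metrics, rounded to
  2 decimals.  Applied to the published per-organelle benchmark means
  (`mpfnet.benchmarks`), this reproduces every quoted improvement
  percentage; those table means are shipped as fixed reference inputs
  because the underlying A549 SRS dataset is available only on request.

"Mean pixel accuracy" for regression outputs is defined via per-pixel
argmax over [background + 3 organelle channels], with background
1 − max(channels) and sub-threshold channels suppressed; it is logged per
epoch during training.

## Synthetic data generator

The generator emulates the statistical structure of paired
SRS/fluorescence acquisitions, not their physics:

* **Geometry** — per scene, a few non-overlapping cells: nucleus =
  random rotated ellipse (axes 8–14 % of the image side); mitochondria =
  1–3 px puncta scattered in a perinuclear shell; ER = correlated
  random-walk filaments seeded at the nuclear envelope.  Mitochondria and
  ER are excluded from the nuclear interior.  Truth channels are Gaussian-
  blurred (σ = 1 px) supports normalised to [0, 1]; the binary supports
  are kept as masks.
* **Forward model** — input channel c = Σ_o M[c,o]·truth_o + background,
  with M a C×3 nonnegative spectral-signature matrix.  The default M has
  Gaussian profiles peaked at 30/55/80 % of the channel axis with width
  18 %, giving substantial cross-talk; SRS signal is approximately linear
  in molecular concentration, so linear mixing is the appropriate
  idealisation, and the mixing is configurable because the real spectra
  are not published.  Shot noise is Poisson at 200 photons per unit
  intensity; read noise is Gaussian σ = 0.01; the result is clipped at 0.
* **Protocol** — default desk-scale images are 128×128 (acquisition scale
  512 is a flag away); 10 input channels; datasets are split 80/20 by a
  seeded shuffle, and the whole dataset is reproducible bit-for-bit from
  (config, master seed).

What the generator does **not** model: real Raman spectra, optical PSF
anisotropy, cell-to-cell intensity variation beyond geometry, motion, or
the denoising pre-processing applied to real acquisitions.  Passing tests
on this data therefore demonstrate that the architecture, gradients and
training loop are correct and that the network can unmix overlapping
linear spectral mixtures — not that it reaches the published real-data
accuracy.

## Training protocol

`TrainConfig` defaults are the published recipe: SGD, momentum 0.9,
batch 8, weight decay 1e-4, learning rate 0.001, at most 200 epochs, MSE
loss over the three channels (L1 optional), no schedule; optional early
stopping on validation loss.  The best-validation weights are kept.

The desk-scale experiments shipped with the package use deliberately
small problem sizes so they run in minutes on one CPU, and the adaptive
optimiser option, because a 200-step SGD(0.001) run — all that 4 images
allow — is a vanishing fraction of the original training budget
(960 images × 200 epochs) and collapses to the mean predictor:

* **Overfit sanity check** — 4 pairs at 64×64, reduced widths (CNN ladder
  8/16/32/64, S0 = 64, fusion widths 64/32/16), Adam 3e-3, batch 1, at
  most 200 epochs with an early stop once train PCC ≥ 0.8.
* **Architecture comparison** — 100 images at 64×64 (80 train / 20 test,
  two-cell scenes), both models trained identically (Adam 3e-3, batch 4,
  24 epochs), scored by held-out PCC.  The budget is matched between
  models by construction and chosen so both models reach their
  validation-loss plateau; comparing undertrained models mostly measures
  warm-up timing, which is seed noise.  At 32×32 the comparison is not
  meaningful for a different reason: a 32×32 input yields only 4
  transformer tokens, removing the global-context pathway the fusion
  architecture exists for.  64×64 (16 tokens) is the smallest scale at
  which the comparison exercises the architecture rather than its
  truncation.

## Known limitations

* Throughput is CPU-numpy: full-width 512×512 training is out of reach;
  the full-width configuration is constructed and tested for shape
  correctness only.
* The synthetic task is linearly solvable by design (a per-pixel linear
  regression already reaches PCC > 0.8 at zero noise — asserted in the
  tests); deep models are validated for correctness and relative
  behaviour, not for absolute superiority over classical unmixing.
* Batch-norm statistics make train-mode forward passes batch-dependent;
  group norm is available for batch-1 regimes.
* The published benchmark means are reproduced as comparative arithmetic
  only; nothing desk-scale can re-derive them without the original data.
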