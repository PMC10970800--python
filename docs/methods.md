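# Methods

## Problem setting

Single-image super-resolution (SISR) of 8-bit grayscale radiograph-like
images: given a low-resolution (LR) image produced from a high-resolution
(HR) original by bicubic downsampling at a power-of-two factor
α ∈ {2, 4, 8} — optionally followed by salt-and-pepper corruption — estimate
the HR image. Radiographs are dominated by low-frequency content (broad
attenuation gradients) with sparse mid/high-frequency structure (rib
shadows, small opacities, fine texture), so an effective network should let
low-frequency information bypass the deep path and spend its capacity on
high-frequency residuals.

## Degradation model

`bicubic_resize` follows the classical `imresize` convention: separable
resampling with the Keys cubic kernel (a = −0.5), output sample `i` centred
at `(i + 0.5)/s − 0.5` in input coordinates, weights normalized to unit sum.
When shrinking with antialiasing the kernel support is widened by `1/s`, so
the cubic acts as a low-pass filter; out-of-range taps are reflected
symmetrically (boundary handling is the one place this implementation may
differ from other imresize-family routines, which typically clamp; the
difference is confined to a 2–3 pixel border). A scale factor of exactly 1
is the identity, and constant images are fixed points at any scale.

Salt-and-pepper noise corrupts each pixel independently with probability
`d` (studied densities 0.005, 0.01, 0.02), setting it to 0 or 255 with
equal probability. Noise is applied to the LR image only — after
downsampling — and never to HR ground truth, which must stay clean for
evaluation.

Patch extraction computes the LR image once, enumerates LR origins at a
given stride, and pairs each `p×p` LR patch with the aligned `αp×αp` HR
patch. A stride-1 enumeration over realistic training sets yields far more
than the canonical cap of 102,400 pairs, so a seeded uniform subsample of
exactly `max_pairs` reconciles the two; alignment (`hr_origin = α ·
lr_origin`) is exact by construction.

## Network

Channels-last tensors, no batch normalization anywhere (training and
inference use identical arithmetic). For filter count `f`:

- **Shallow extraction** — one 3×3 convolution, 1 → f channels.
- **Residual block** — three parallel same-padded convolutions (1×1, 3×3,
  5×5, each f → f, inception style), each followed by LeakyReLU (negative
  slope 0.2, exposed in the config); the branches are concatenated (3f) and
  fused by a 1×1 convolution back to f (default), or summed when
  concatenation fusion is ablated; an optional squeeze-excitation channel
  gate (global average pool → f/r → LeakyReLU → f → logistic) rescales the
  fused map; an optional skip adds the block input; a final LeakyReLU ends
  the block.
- **Residual group** — a chain of blocks whose outputs, together with the
  group input, are concatenated ((n_blocks+1)·f channels; 320 at the
  reference configuration) and fused by a 1×1 convolution to f.
- **Trunk** — groups in sequence; group outputs concatenated (n_groups·f;
  256 at reference) and fused 1×1 to f; a long skip connection adds the
  shallow features, so with a zero-weight trunk the deep path is exactly
  the identity on shallow features.
- **Upscaler** — a 3×3 convolution f → α²·f, pixel shuffle to (αH, αW, f),
  and a final 3×3 convolution to 1 channel. For α = 8 a cascaded
  alternative (three ×2 stages) is exposed via `upsampler="cascade"`.

The reference configuration is 4 groups × 4 blocks × 64 filters with
channel attention off, concatenation fusion on and block skips on; the
ablation grid toggles those three flags.

### Initialization

Convolutions followed by a LeakyReLU use He fan-in initialization with the
LeakyReLU gain. Layers that feed no rectifier — the fusion convolutions,
the shallow, pre-shuffle and final reconstruction convolutions, and the
sigmoid-facing attention layer — use gain-1 fan-in scaling instead: with
five such layers stacked, the surplus LeakyReLU gain (≈1.92× variance each)
would otherwise inflate the initial output scale roughly 25-fold and make
early training strongly seed-dependent. The pre-shuffle convolution
additionally uses ICNR tiling (all α² sub-pixel positions share one
filter), so the upscaler begins as nearest-neighbour upsampling of the
feature maps rather than sub-pixel noise; this removes checkerboard
artifacts and most of the learn-to-upsample transient. Finally, the trunk
fusion convolution is zero-initialized (residual-branch zero init): at
initialization the network is exactly the linear shallow → long-skip →
upscaler path, and the deep trunk is grown in by training. Without these
three measures, short training runs were strongly seed-dependent — slow
seeds could fail to reach bicubic quality within a few hundred updates.
All draws come from one generator seeded by `ModelConfig.seed`, so
initialization is exactly reproducible.

## Training

L1 (mean absolute error) objective, ADAM (β₁ = 0.9, β₂ = 0.999,
ε = 10⁻⁸), batch size 32, learning rate `lr0 · decay^(⌊epoch/every⌋)` with
reference values lr0 = 2×10⁻⁴, decay 0.1 every 120 epochs. Patches are
scaled to [0, 1] during optimization; loss histories are reported on the
0–255 intensity scale. Each epoch reshuffles with a seeded generator and
drops the trailing incomplete batch so every update sees a full batch.
Training is deterministic given the model and shuffle seeds on a fixed
platform (single-threaded numpy arithmetic, fixed operation order).

The network, its reverse-mode gradients and ADAM are implemented directly
on numpy (im2col or shifted-slice GEMMs chosen per layer width); gradient
correctness is established by central finite differences, both on a
3-parameter toy layer (≤10⁻⁴ relative) and spot-checked through the full
network including attention, fusion and pixel shuffle.

### Desk-scale (tiny) regime

Full-scale training of the reference model is far beyond a single-CPU
session, so end-to-end evidence uses a scaled-down but complete pipeline:
2 groups × 2 blocks × 16 filters at ×4, 512 patch pairs (16×16 → 64×64)
drawn from 8 phantoms of 192×192, 30 epochs (480 updates), evaluated on 20
held-out phantoms. This regime uses lr0 = 2×10⁻³: the reference 2×10⁻⁴ is
tuned for hundreds of epochs at f = 64, while the tiny run has 480 steps
(a 5×10⁻³ pilot was unstable). Under these conditions the tiny model
beats bicubic interpolation by about +1 to +4 dB mean PSNR depending on
seed — the qualitative headline behaviour — while absolute values stay
below the full-scale numbers, as expected at this scale.

The single-pair memorization check (L1 < 1 intensity unit within 500
steps) uses a ×2 tiny model with lr0 = 10⁻², halved every 100 steps. The
L1 sign gradient has constant magnitude, so under ADAM the steady-state
output fluctuation scales with the learning rate; a decayed schedule
reaches ≈0.3 intensity units where any constant rate stalls above 1.

## Metrics

- **PSNR** = 10·log₁₀(255²/MSE) dB; identical images report an
  infinite-quality sentinel (`inf`).
- **SSIM** uses the standard windowed comparison
  ((2μxμy+C1)(2σxy+C2)) / ((μx²+μy²+C1)(σx²+σy²+C2)) with C1 = (0.01·255)²,
  C2 = (0.03·255)², an 11×11 Gaussian window (σ = 1.5; uniform 8×8 exposed
  as an option), population statistics, and windows evaluated only where
  they fit entirely inside the image (no padding, no border crop of the
  image itself).
- **MSIM** evaluates SSIM at N dyadic scales (2×2 block averaging between
  scales) and combines them as (∏ SSIMᵢ^αᵢ)^(1/N). Defaults are N = 5 and
  unit weights: this follows the stated formula literally — including the
  outer 1/N root, which departs from the common MS-SSIM convention of
  normalized per-scale exponents — so it carries its own parameters rather
  than borrowed ones. The outer root is applied sign-preservingly so rare
  negative products stay real. Higher MSIM is reported as better.
  Evaluation images must allow the last scale to contain the window
  (≥ 176 px for N = 5); the CLI caps N at what the image supports.

`evaluate` degrades each HR test image with the forward model,
super-resolves the LR with the model under test, and scores both the model
output and the bicubic-upscaled LR (the model-independent baseline)
against clean HR.

## Phantom generator

Each phantom is the clipped sum of four seeded layers: a broad smooth
field (three large-σ Gaussian bumps spanning ≈[30, 200]), rib-like warped
sinusoidal bands (default 12 bands, amplitude 28), sparse bright Gaussian
blobs (default 5, peak ≈30–50, σ ≈ H/64–H/32), and zero-mean white texture
(default σ = 2). Defaults were calibrated so that at ×4 the bicubic
baseline lands near 37 dB PSNR — the regime reported for real chest
radiographs — leaving realistic headroom for a learned model; band count
matches the number of rib shadows typically visible. Dimensions must be
≥ 64 and divisible by 8 so ×2/×4/×8 degradation is exact. Images are kept
at floating precision internally and quantized to 8 bits only when written
to PNG, avoiding double-quantization bias in degradation tests.

What the phantoms do *not* model: anatomical shape priors, scanner blur
and scatter, Poisson dose noise, pathology. Passing tests therefore show
that the pipeline learns genuine LR→HR structure restoration on data with
radiograph-like second-order statistics — not clinical performance on real
radiographs, which would require the original datasets and full-scale
training.

## Numerical and design choices

- Internal image dtype float64 for degradation/metrics, float32 for
  network training; float64 network mode exists for gradient checks.
- PSNR of identical images: `inf` sentinel rather than an arbitrary cap.
- Negative-SSIM products in MSIM: sign-preserving root (occurs only for
  strongly anti-correlated inputs, far from the SR operating regime).
- Branch widths in the residual block are f per branch; the ablated
  "no concatenation" variant sums the three branches, the minimal
  shape-preserving alternative.
- Checkpoints are single-file `.npz` archives holding a JSON config plus
  named weight arrays; loading rebuilds the architecture and restores
  bit-identical forward behaviour, and validates the parameter count
  against the closed-form `count_parameters`.
- The CLI exposes noise both at training time (degrade → manifest → train)
  and at evaluation time (`eval --noise`), since either protocol is a
  defensible reading of the noisy-image experiments.

## Known limitations

- The bicubic boundary convention (reflect) differs from clamp-style
  imresize implementations in a thin border.
- Determinism is a single-platform contract: different BLAS builds or
  thread counts may change floating-point summation order.
- The tiny regime's PSNR numbers are not comparable to full-scale
  radiograph benchmarks; only the ordering against bicubic carries over.
- MSIM with default N = 5 requires ≥ 176 px images; smaller evaluation
  images use fewer scales (the CLI does this automatically).
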