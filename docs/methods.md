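# Methods

## Noise model

The corruption model treats the clean magnitude image as the true signal
amplitude R with zero phase — the standard convention when only magnitude
data is available — and draws

    D = sqrt((R + ℜ)² + ℑ²),   ℜ, ℑ i.i.d. N(0, σ²)

with both Gaussian fields generated row-major from one seed, the real
field fully before the imaginary one, so corruption is bit-reproducible
across platforms. Noise levels σ (defaults 5, 10, 20, 30) are gray levels
on the fixed [0, 255] scale and are never rescaled per image. Useful exact
identities the tests rely on: E[D²] = R² + 2σ²; at R = 0, D is
Rayleigh(σ) with mean σ·sqrt(π/2); at R ≫ σ, D ≈ Normal(sqrt(R² + σ²), σ).

The density p(D | R, σ) = D/σ²·exp(−(D² + R²)/2σ²)·I₀(RD/σ²) is evaluated
with the exponentially scaled Bessel function everywhere (not just past an
overflow threshold): the RD/σ² term is folded into the exponent, so the
expression stays finite at arbitrarily large arguments where a naive I₀
overflows (around RD/σ² ≳ 709 in float64).

## Phantoms

The generator emulates the two statistics of brain MR slices the method
leans on — an exactly-zero background and a strictly positive head region
on a [0, 255] scale — with nested ellipses: a bright skull ring, a brain
ellipse with a smooth directional intensity gradient, and a configurable
number of interior tissue ellipses with their own intensity plateaus.
Default extent is 145×121, the axial resolution of the target data. All
tissue intensities live inside `intensity_range` (default 40–250, so
tissue never touches 0 or saturates 255).

What phantoms do **not** emulate: anatomy, partial-volume boundaries, bias
fields, motion or ghosting artifacts, scanner-specific intensity
distributions. Tests passing on phantoms therefore validate the noise
model, the optimization and the metric plumbing — not clinical denoising
quality on real brains.

Paired datasets derive per-sample sub-seeds through `SeedSequence([seed,
i, j])` (phantom i, noise-level index j), so any pair can be regenerated
in isolation and dataset generation is a pure function of its arguments.
A splitting utility with 8:1:1 default ratios mirrors the conventional
train/validation/test division.

## Architecture

The published description of this network family leaves depth, width and
several wiring details open; the choices here are:

| parameter | default | rationale |
|---|---|---|
| extraction layers | 10 (`paper`), 5 (`tiny`) | ADNet-like depth; tiny trains on one CPU in minutes |
| channels | 64 (`paper`), 16 (`tiny`) | standard denoising-CNN width |
| dilation | rate 2 at even layers ≥ 3 | interleaving widens the receptive field while limiting gridding artifacts |
| BN | absent in extraction layers 1–2, present elsewhere | early layers keep raw intensity contrast |
| spatial attention | at the end of extraction; 7×7 map conv | attend once over the richest features |
| channel attention bottleneck | reduction 8, separate per-path transforms | the two pooled descriptors are transformed independently, then summed |
| final conv | 3×3 to 1 channel, Kaiming weights, zero bias | emits the residual |

Convolutions feeding batch norm are built without bias (BN subtracts the
channel mean, making such a bias exactly inert; keeping it would leave
permanently gradient-free parameters).

**Spatial attention.** Three channel-pooled maps — mean, max, and the max
map passed through an extra 3×3 spatial maximum filter — are concatenated
and convolved to a single sigmoid map in (0,1) that rescales all channels.
The extra-max variant is the default because zero background / positive
brain favors max pooling; an `avg_extra` variant (3×3 spatial average as
the third map) is selectable. The exact wiring of the "additional pooling
layer" is not fully recoverable from the source description; this
three-map construction is one consistent reading, isolated behind
`spatial_attention_pooling`.

**Residual contract.** The model returns N; `denoise` computes
C = S − N by exact elementwise subtraction, so C + N == S bit-for-bit and
a zeroed final layer is the exact identity. Outputs are not clipped;
clipping to [0, 255] happens only on 8-bit export.

**Internal scaling.** Inputs are divided by `input_scale` (default 255)
before the network and the residual is multiplied back. This keeps
post-BN feature magnitudes and the final layer's operating point on the
same O(1) scale, which Adam handles in few steps at desk scale. It is a
pure reparameterization: all contracts above are unaffected.

## Training

Residual MSE, L(θ) = 1/(2M)·Σ‖f(Sₖ) − (Sₖ − Gₖ)‖², optimized with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 4, whole slices (no
patches). The learning-rate multipliers (1, 0.5, 0.25, 0.125) scale the
*initial* rate and apply over four equal stages of the epoch budget by
default; boundaries are configurable. The protocol's initial rate is
1e-4; the desk-scale experiments below use 2e-3 (mini-batch) and 5e-3
(single-sample overfit) because their total step counts (hundreds, not
the tens of thousands of a full training run) sit in the regime where the
larger rates converge and the protocol rate has not yet left the
initialization transient. Gradient clipping and weight
decay exist but default to off. Training is fully seeded (initialization
and shuffling) and identical arguments reproduce identical loss
histories. A non-finite loss aborts with a diagnostic rather than
continuing silently.

## Metrics

PSNR uses the fixed 255 peak and returns +inf for identical images. SSIM
is the Wang et al. index with c₁ = (0.01·255)² and c₂ = (0.03·255)² and
both constants in the denominator — necessary for SSIM(x, x) = 1 on
zero-mean images — averaged over 11×11 Gaussian windows (σ = 1.5) via
scikit-image; a `global_stats` variant evaluates the formula once from
whole-image statistics. Values are reported raw (the index can be
negative), without clamping.

## Problem sizes of the shipped experiments

Chosen so the whole suite runs on one CPU in minutes; all are package
choices, configurable at call sites:

- **Overfit oracle**: one 145×121 pair at σ = 20, `tiny` preset, 200
  epochs of full-batch Adam at a constant 5e-3 (single-sample
  memorization tolerates, and at this step count needs, a larger rate
  than mini-batch training). Converges to well under 1% of the initial
  loss; the initial loss is dominated by the
  Kaiming-initialized final layer's output transient, so the check
  verifies that optimization both removes the transient and begins
  fitting the actual noise field.
- **Scaled-down denoising experiment**: 50 training and 10 held-out
  96×80 phantom pairs at σ = 20, `tiny` preset, 40 epochs at 2e-3 with
  the staged multipliers. Yields ≈ +4.4 dB mean PSNR and ≈ +0.21 mean
  SSIM over the noisy baseline (seeds as in `scripts/acceptance.py`).
- **Monotonicity sweep**: 20 phantoms (64×56) at σ = 5, 10, 20, 30;
  baseline PSNR and SSIM decrease strictly with σ.
- Monte-Carlo noise checks use 1e5–1e6 draws; density normalization uses
  adaptive quadrature to 1e-6.

## Numerical notes and edge cases

- Everything is float64; gradient checks compare analytic backprop to
  central differences at 1e-6 step.
- Max-pooling backward routes gradients to the argmax (first index on
  exact ties, which occur only on constant regions); the 3×3 average
  filter is self-adjoint and is its own transpose in backward.
- BN uses batch statistics in training and running estimates (momentum
  0.1) in evaluation; evaluation after very short trainings therefore
  sees slightly stale statistics.
- σ = 0 corruption returns the input bit-exactly (special-cased to avoid
  sqrt-of-square rounding).
- PNG export rounds half-to-even; 8-bit storage quantizes float images to
  ±0.5 gray.
- A constant NIfTI volume min-max rescales to all zeros by convention.

## Known limitations

- Phantom realism as above; absolute PSNR/SSIM values on phantoms are not
  comparable to values on clinical data. Whether clean slices should be
  intensity-normalized before corruption is an open choice; corruption
  happens on the native [0, 255] scale here, which shifts absolute PSNR
  relative to normalized pipelines.
- The `paper` preset is not trained to convergence anywhere in the test
  suite (GPU-scale budgets); only its contracts are exercised.
- Single-channel 2D slices only; the axial axis of NIfTI volumes is
  assumed to be the third array axis (overridable).
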