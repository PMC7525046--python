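# ricianet

Removing Rician noise from brain MR slices with a feature-fusion attention
CNN, together with everything needed to exercise it end to end without
access-gated clinical data: a Rician corruption model, a synthetic brain
phantom generator, the residual training protocol, and PSNR/SSIM
evaluation.

## The problem

Magnitude MR images are reconstructed as the modulus of complex k-space
data whose real and imaginary channels carry i.i.d. Gaussian noise of
variance σ². A pixel with true amplitude R is therefore observed as

    D = sqrt((R + ℜ)² + ℑ²),    ℜ, ℑ ~ N(0, σ²)

which follows a **Rician** distribution — signal dependent, Rayleigh at
R = 0, approximately Normal(sqrt(R² + σ²), σ) at high SNR. Gaussian
denoisers mismodel it, particularly in the dark background that dominates
brain slices.

The denoiser is a residual CNN: it predicts the noise image N from the
noisy input S and reconstructs the clean estimate C = S − N by exact
subtraction. Three blocks compose the network:

1. **Feature extraction** — 3×3 conv + ReLU layers (the first two without
   batch normalization), alternating common and dilated kernels to widen
   the receptive field at zero parameter cost, closed by a spatial
   attention module whose descriptor maps include an extra max-pooled map
   (on MR slices the background is exactly zero, so max pooling steers
   attention to brain texture).
2. **Feature fusion** — the extraction features are concatenated with the
   raw input and mixed by conv + BN + ReLU layers.
3. **Attention** — channel attention with separate transforms for the
   average- and max-pooled descriptors, then a final 3×3 conv emits N.

Training minimizes the residual mean squared error

    L(θ) = 1/(2M) Σₖ ‖f(Sₖ) − (Sₖ − Gₖ)‖²

with Adam, batch size 4, initial learning rate 1e-4 reduced by factors
0.5 / 0.25 / 0.125 over the epoch budget. Quality is reported as
PSNR = 10·log₁₀(255²/MSE) in dB and mean local SSIM (11×11 Gaussian
windows, c₁ = (0.01·255)², c₂ = (0.03·255)²).

The implementation is pure NumPy — convolutions, batch norm, both
attention modules and Adam, with hand-written backpropagation verified by
finite-difference tests — so it runs anywhere scientific Python runs.

## Worked example

```python
import ricianet as rn

# 50 synthetic brain phantoms corrupted at noise level sigma = 20
phantoms = rn.PhantomConfig(height=96, width=80)
train_pairs = rn.generate_paired_dataset(50, [20.0], phantoms, seed=101)
test_pairs  = rn.generate_paired_dataset(10, [20.0], phantoms, seed=202)

model = rn.build_model(rn.NetworkConfig.tiny(), seed=1)
model, history = rn.train(
    model, train_pairs,
    rn.TrainConfig(epochs=40, initial_lr=2e-3, batch_size=4, seed=1),
)

base = rn.noisy_baseline_report(test_pairs)[20.0]
rep  = rn.evaluate_pairs(model, test_pairs)[20.0]
print(f"noisy    {base.mean_psnr:.2f} dB  SSIM {base.mean_ssim:.4f}")
print(f"denoised {rep.mean_psnr:.2f} dB  SSIM {rep.mean_ssim:.4f}")
```

Output (one CPU, a few minutes):

```
noisy    20.96 dB  SSIM 0.4783
denoised 25.34 dB  SSIM 0.6910
```

The noisy baseline scores what uncorrected σ = 20 corruption does to a
phantom; after training, the small `tiny` preset recovers about 4.4 dB of
PSNR and lifts SSIM from 0.48 to 0.69 on held-out phantoms. Full-size
training (the `paper` preset: 10 extraction layers, 64 channels) follows
the same API.

The same pipeline is scriptable from a shell:

```sh
ricianet phantom  --n 8 --seed 1 --out clean/
ricianet simulate --input clean/ --sigma 20 --seed 2 --out noisy/
ricianet train    --manifest noisy/manifest.tsv --out-dir run/ --preset tiny --epochs 40
ricianet evaluate --manifest noisy/manifest.tsv --checkpoint run/model.ckpt.npz --out report.csv
```

NIfTI volumes can be sliced into training data with
`ricianet.read_volume_slices`, which extracts axial slices (default range
37–86) rescaled per volume to [0, 255].

## Scope

2D single-coil magnitude slices only: no k-space simulation with nonzero
phase, no multi-coil noise correlation, no blind noise-level estimation,
no 3D convolutions. See `docs/methods.md` for model details, parameter
defaults, and known limitations.
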