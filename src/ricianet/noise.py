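"""Rician magnitude-noise model for MR images.

MR scanners acquire complex k-space data whose real and imaginary channels
carry i.i.d. zero-mean Gaussian noise of equal variance ``sigma**2``.  After
inverse Fourier reconstruction and the modulus operation, a pixel with true
amplitude ``R`` is observed as

    D = sqrt((R + re)**2 + im**2),   re, im ~ N(0, sigma**2)

which follows a Rician distribution with parameters ``(R, sigma)``.  The
distribution is signal dependent: at ``R = 0`` it is the Rayleigh
distribution, and at high SNR (``R >> sigma``) it approaches
``Normal(sqrt(R**2 + sigma**2), sigma)``.

Only the magnitude image is available here, so the signal phase is taken as
zero and the clean magnitude plays the role of ``R`` — the standard
convention for corrupting magnitude images.  Noise levels are expressed as
``sigma`` in gray-level units on the [0, 255] intensity scale and are never
rescaled per image.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import special

__all__ = ["NoiseSpec", "add_rician_noise", "rician_pdf"]


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one Rician corruption.

    Parameters
    ----------
    sigma
        Standard deviation of the per-channel Gaussian noise, in gray
        levels on the [0, 255] scale.  Must be nonnegative.
    seed
        Integer seed for the random generator.  The same
        ``(input, sigma, seed)`` always yields a bit-identical output.
    """

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")


def add_rician_noise(clean: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt a nonnegative magnitude image with Rician noise.

    The two Gaussian fields are drawn from ``default_rng(spec.seed)`` in
    row-major order, the real channel fully before the imaginary one, so the
    corruption is reproducible across platforms.

    Parameters
    ----------
    clean
        Array of nonnegative intensities (any shape; typically a 2D slice
        on the [0, 255] scale).
    spec
        Noise level and seed.

    Returns
    -------
    numpy.ndarray
        Float64 array of the same shape, everywhere >= 0.  With
        ``sigma == 0`` the input values are returned unchanged.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if not np.all(np.isfinite(clean)):
        raise ValueError("clean image must be finite")
    if np.any(clean < 0):
        raise ValueError("clean image must be nonnegative")
    if spec.sigma == 0:
        return clean.copy()
    rng = np.random.default_rng(spec.seed)
    re = rng.normal(0.0, spec.sigma, size=clean.shape)
    im = rng.normal(0.0, spec.sigma, size=clean.shape)
    # hypot is accurate and guarantees a nonnegative magnitude
    return np.hypot(clean + re, im)


def rician_pdf(d, r, sigma):
    """Rician probability density p(D | R, sigma).

    Evaluates ``d / sigma**2 * exp(-(d**2 + r**2) / (2 sigma**2))
    * I0(r d / sigma**2)`` where ``I0`` is the zeroth-order modified Bessel
    function.  The Bessel factor is computed through the exponentially
    scaled ``i0e`` at every argument (not just past an overflow switch
    point), folding ``r d / sigma**2`` into the exponent, so the density is
    finite for arbitrarily large ``r d / sigma**2``:

        p = d / sigma**2 * exp(-(d - r)**2 / (2 sigma**2)) * i0e(r d / sigma**2)

    At ``r = 0`` this is the Rayleigh density ``d/sigma**2 *
    exp(-d**2 / (2 sigma**2))``.

    Parameters broadcast against each other; scalars in give a scalar out.
    """
    d = np.asarray(d, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    sigma = float(sigma)
    if not math.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be finite and > 0, got {sigma!r}")
    if np.any(d < 0):
        raise ValueError("d must be nonnegative")
    if np.any(r < 0):
        raise ValueError("r must be nonnegative")
    s2 = sigma * sigma
    out = d / s2 * np.exp(-((d - r) ** 2) / (2.0 * s2)) * special.i0e(d * r / s2)
    if out.ndim == 0:
        return float(out)
    return out
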