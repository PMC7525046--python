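"""PSNR / SSIM image-quality metrics and batch evaluation reports.

PSNR uses a fixed peak of 255 (images live on the 8-bit gray scale even
when stored as floats):

    PSNR(p, q) = 10 * log10(255^2 / MSE),  MSE = mean((p - q)^2)

and returns ``+inf`` for identical images (the zero-distortion limit).

SSIM uses the standard Wang et al. index with c1 = (0.01*255)^2 and
c2 = (0.03*255)^2, both stabilizing constants present in the denominator
(without c1 the index of a zero-mean image with itself is not 1).  The
default is the mean over local 11x11 Gaussian windows (sigma = 1.5),
computed by scikit-image; ``global_stats=True`` evaluates the same formula
once from whole-image statistics.  Values are reported raw, without
clamping to [0, 1].
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .network import FFADenoiser, denoise
from .phantom import PairedSample

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "evaluate_pairs",
    "noisy_baseline_report",
]

_C1 = (0.01 * 255.0) ** 2
_C2 = (0.03 * 255.0) ** 2
_WIN = 11


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Per-image and averaged scores for one noise level."""

    per_image: tuple[tuple[float, float], ...]  # (psnr_db, ssim) pairs
    mean_psnr: float
    mean_ssim: float
    sigma: float
    n_images: int

    @classmethod
    def from_scores(cls, scores: Sequence[tuple[float, float]], sigma: float) -> "MetricReport":
        if not scores:
            raise ValueError("need at least one scored image")
        psnrs = [s[0] for s in scores]
        ssims = [s[1] for s in scores]
        return cls(
            per_image=tuple(scores),
            mean_psnr=float(np.mean(psnrs)),
            mean_ssim=float(np.mean(ssims)),
            sigma=float(sigma),
            n_images=len(scores),
        )


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if reference.size == 0:
        raise ValueError("images must have at least one pixel")
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with a 255 peak; +inf if identical."""
    reference, test = _check_pair(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, *, global_stats: bool = False) -> float:
    """Structural similarity index; see module docstring for conventions."""
    reference, test = _check_pair(reference, test)
    if global_stats:
        up, uq = reference.mean(), test.mean()
        vp, vq = reference.var(), test.var()
        cov = float(np.mean((reference - up) * (test - uq)))
        return float(
            (2 * up * uq + _C1)
            * (2 * cov + _C2)
            / ((up * up + uq * uq + _C1) * (vp + vq + _C2))
        )
    if min(reference.shape) < _WIN:
        raise ValueError(
            f"image smaller than the {_WIN}x{_WIN} analysis window; "
            "use global_stats=True for tiny images"
        )
    return float(
        structural_similarity(
            reference,
            test,
            data_range=255.0,
            win_size=_WIN,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def _score_pairs(
    items: Sequence[tuple[float, np.ndarray, np.ndarray]], global_ssim: bool
) -> dict[float, MetricReport]:
    by_sigma: dict[float, list[tuple[float, float]]] = {}
    for sigma, clean, restored in items:
        by_sigma.setdefault(float(sigma), []).append(
            (psnr(clean, restored), ssim(clean, restored, global_stats=global_ssim))
        )
    return {
        s: MetricReport.from_scores(scores, s) for s, scores in sorted(by_sigma.items())
    }


def evaluate_pairs(
    model: FFADenoiser | None,
    pairs: Sequence[PairedSample],
    *,
    global_ssim: bool = False,
) -> dict[float, MetricReport]:
    """Denoise every pair and score against the clean image, grouped by sigma.

    ``model=None`` scores the noisy images unchanged (zero residual), i.e.
    the identity-model / noisy baseline.  Deterministic given the model and
    pairs; returns ``{sigma: MetricReport}`` with sigmas in ascending order.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    items = []
    for p in pairs:
        restored = p.noisy if model is None else denoise(model, p.noisy).denoised
        items.append((p.sigma, p.clean, restored))
    return _score_pairs(items, global_ssim)


def noisy_baseline_report(
    pairs: Sequence[PairedSample], *, global_ssim: bool = False
) -> dict[float, MetricReport]:
    """Scores of the raw noisy images against clean (the no-op baseline)."""
    return evaluate_pairs(None, pairs, global_ssim=global_ssim)
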