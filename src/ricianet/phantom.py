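"""Synthetic brain-like phantom slices and paired noisy/clean datasets.

Real brain MR slices have two statistics the denoiser and its tests rely
on: the background outside the head is exactly zero, and the head region is
strictly positive on a [0, 255] gray scale.  The generator reproduces those
statistics with a nested-ellipse phantom (a bright "skull" ring, a brain
ellipse with a smooth intensity gradient, and a handful of interior tissue
ellipses) rather than sampling real anatomy — the downstream claims being
exercised are geometric and statistical, not anatomical.

Default extent is 145x121 pixels, the axial-slice resolution of the data
the tool targets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .noise import NoiseSpec, add_rician_noise

__all__ = [
    "PhantomConfig",
    "PairedSample",
    "generate_phantom",
    "generate_paired_dataset",
    "split_paired_dataset",
]

_SEED_MASK = 0x7FFFFFFF  # derived sub-seeds stay below 2**31


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of one synthetic slice.

    ``intensity_range = (lo, hi)`` bounds every tissue pixel; ``lo`` must be
    positive so tissue is distinguishable from the exactly-zero background.
    """

    height: int = 145
    width: int = 121
    n_tissue_regions: int = 4
    intensity_range: tuple[float, float] = (40.0, 250.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom extent must be at least 8x8 pixels")
        if self.n_tissue_regions < 1:
            raise ValueError("n_tissue_regions must be >= 1")
        lo, hi = self.intensity_range
        if not (0 < lo <= hi <= 255):
            raise ValueError(
                "intensity_range must satisfy 0 < lo <= hi <= 255, "
                f"got {self.intensity_range!r}"
            )


@dataclasses.dataclass(frozen=True)
class PairedSample:
    """A (clean, noisy) slice pair at a known noise level.

    The desired residual for residual learning is ``noisy - clean`` and is
    always recoverable exactly from the pair.
    """

    clean: np.ndarray
    noisy: np.ndarray
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy must share a shape")

    @property
    def residual(self) -> np.ndarray:
        """The noise image the network is trained to predict."""
        return self.noisy - self.clean


def _ellipse_mask(yy, xx, cy, cx, ry, rx, theta):
    ct, st = math.cos(theta), math.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    return (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0


def _gradient_field(yy, xx, theta):
    """Smooth unit-range ramp across the frame along direction ``theta``."""
    p = xx * math.cos(theta) + yy * math.sin(theta)
    return p / (2.0 * math.sqrt(2.0)) + 0.5  # [-sqrt2, sqrt2] -> [~0.15, ~0.85]


def generate_phantom(config: PhantomConfig = PhantomConfig()) -> np.ndarray:
    """Render one clean phantom slice.

    Returns a float64 ``(height, width)`` array whose background is exactly
    zero and whose tissue pixels all lie inside ``config.intensity_range``.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    yy = np.linspace(-1.0, 1.0, h)[:, None]
    xx = np.linspace(-1.0, 1.0, w)[None, :]
    lo, hi = config.intensity_range
    span = hi - lo

    img = np.zeros((h, w), dtype=np.float64)

    skull = _ellipse_mask(yy, xx, 0.0, 0.0, 0.95, 0.95, 0.0)
    brain = _ellipse_mask(yy, xx, 0.0, 0.0, 0.82, 0.80, 0.0)

    # bright skull ring
    img[skull & ~brain] = lo + span * 0.95

    # brain parenchyma with a smooth directional gradient
    theta = rng.uniform(0.0, 2.0 * math.pi)
    base = rng.uniform(0.35, 0.65)
    field = np.clip(base + 0.3 * (_gradient_field(yy, xx, theta) - 0.5), 0.0, 1.0)
    img[brain] = lo + span * field[brain]

    # interior tissue ellipses with their own intensity plateaus
    for _ in range(config.n_tissue_regions):
        ang = rng.uniform(0.0, math.pi)
        rad = rng.uniform(0.0, 0.40)
        cang = rng.uniform(0.0, 2.0 * math.pi)
        cy, cx = rad * math.sin(cang), rad * math.cos(cang)
        ry, rx = rng.uniform(0.08, 0.30, size=2)
        frac = rng.uniform(0.0, 1.0)
        gtheta = rng.uniform(0.0, 2.0 * math.pi)
        gfield = np.clip(
            frac + 0.2 * (_gradient_field(yy, xx, gtheta) - 0.5), 0.0, 1.0
        )
        mask = _ellipse_mask(yy, xx, cy, cx, ry, rx, ang) & brain
        img[mask] = lo + span * gfield[mask]

    return img


def _subseed(*words: int) -> int:
    return int(np.random.SeedSequence(list(words)).generate_state(1)[0]) & _SEED_MASK


def generate_paired_dataset(
    n: int,
    sigmas: Sequence[float],
    config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
) -> list[PairedSample]:
    """Generate ``n`` phantoms, each corrupted at every noise level.

    Samples are ordered phantom-major, then by position in ``sigmas``
    (phantom 0 at every sigma, then phantom 1, ...), giving
    ``n * len(sigmas)`` pairs.  Phantom ``i`` uses sub-seed
    ``SeedSequence([seed, i])`` and its corruption at ``sigmas[j]`` uses
    ``SeedSequence([seed, i, j])``, so the dataset is a pure, splittable
    function of its arguments: any (i, j) pair can be regenerated in
    isolation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    if any(s < 0 for s in sigmas):
        raise ValueError("all sigmas must be >= 0")

    samples: list[PairedSample] = []
    for i in range(n):
        pconf = dataclasses.replace(config, seed=_subseed(seed, i))
        clean = generate_phantom(pconf)
        for j, sigma in enumerate(sigmas):
            nseed = _subseed(seed, i, j)
            noisy = add_rician_noise(clean, NoiseSpec(sigma, nseed))
            samples.append(PairedSample(clean=clean, noisy=noisy, sigma=float(sigma), seed=nseed))
    return samples


def split_paired_dataset(
    samples: Sequence[PairedSample],
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[list[PairedSample], list[PairedSample], list[PairedSample]]:
    """Shuffle and split samples into train/validation/test by ratio.

    The conventional split for this task is 8:1:1; the counts are floored
    for the validation and test parts and the remainder goes to training.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to split three ways")
    total = float(sum(ratios))
    if total <= 0 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be nonnegative with a positive sum")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_val = int(len(samples) * ratios[1] / total)
    n_test = int(len(samples) * ratios[2] / total)
    n_train = len(samples) - n_val - n_test
    shuffled = [samples[k] for k in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
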