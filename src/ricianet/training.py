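"""Residual MSE objective and the mini-batch Adam training protocol.

The network predicts noise images, so the loss compares each predicted
residual with the desired residual ``S_k - G_k`` (noisy minus clean):

    L(theta) = 1/(2M) * sum_k || f(S_k) - (S_k - G_k) ||^2

with ``M`` the number of pairs in the batch and the norm summed over
pixels.  Optimization is Adam (beta1=0.9, beta2=0.999, eps=1e-8) with a
piecewise-constant learning-rate schedule: the initial rate (default 1e-4)
is multiplied by 1, 0.5, 0.25 and 0.125 over four stages, read as factors
on the *initial* rate (1e-4 -> 5e-5 -> 2.5e-5 -> 1.25e-5), not cumulative
products.  Stage boundaries default to equal quarters of the epoch budget.
Batch size defaults to 4 whole slices (no patch extraction).

Gradient clipping and weight decay are available but off by default.
"""

from __future__ import annotations

import bisect
import dataclasses
from typing import Sequence

import numpy as np

from .network import FFADenoiser
from .phantom import PairedSample

__all__ = [
    "TrainConfig",
    "Adam",
    "residual_mse_loss",
    "lr_schedule",
    "train",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule parameters.

    ``lr_multipliers`` are factors applied to ``initial_lr`` per stage;
    ``lr_stage_boundaries`` are the first epochs of stages 2..k (``None``
    divides ``epochs`` into equal stages).
    """

    epochs: int = 40
    initial_lr: float = 1e-4
    lr_multipliers: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    lr_stage_boundaries: tuple[int, ...] | None = None
    batch_size: int = 4
    seed: int = 0
    grad_clip: float | None = None
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        m = self.lr_multipliers
        if not m or any(x <= 0 for x in m):
            raise ValueError("lr_multipliers must be positive")
        if any(a < b for a, b in zip(m, m[1:])):
            raise ValueError("lr_multipliers must be non-increasing")
        if self.lr_stage_boundaries is not None:
            b = self.lr_stage_boundaries
            if len(m) != len(b) + 1:
                raise ValueError(
                    "need len(lr_multipliers) == len(lr_stage_boundaries) + 1"
                )
            if list(b) != sorted(b) or (b and b[0] < 1):
                raise ValueError("lr_stage_boundaries must be increasing and >= 1")

    def stage_boundaries(self) -> tuple[int, ...]:
        if self.lr_stage_boundaries is not None:
            return tuple(self.lr_stage_boundaries)
        k = len(self.lr_multipliers)
        return tuple(
            max(1, round(self.epochs * j / k)) for j in range(1, k)
        )


def lr_schedule(config: TrainConfig, epoch: int) -> float:
    """Learning rate of the stage containing ``epoch`` (0-based)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    stage = bisect.bisect_right(config.stage_boundaries(), epoch)
    return config.initial_lr * config.lr_multipliers[stage]


def residual_mse_loss(
    predicted_residuals: np.ndarray, noisy: np.ndarray, clean: np.ndarray
) -> float:
    """1/(2M) sum_k ||pred_k - (S_k - G_k)||^2 over a batch.

    The leading axis indexes the ``M`` samples; remaining axes are summed.
    """
    pred = np.asarray(predicted_residuals, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    clean = np.asarray(clean, dtype=np.float64)
    if not (pred.shape == noisy.shape == clean.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, noisy {noisy.shape}, clean {clean.shape}"
        )
    if pred.ndim < 1 or pred.shape[0] < 1:
        raise ValueError("need at least one sample (M >= 1)")
    m = pred.shape[0]
    diff = pred - (noisy - clean)
    return float(np.sum(diff * diff) / (2.0 * m))


class Adam:
    """Standard Adam with bias correction; learning rate passed per step."""

    def __init__(
        self,
        params,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _global_grad_norm(params) -> float:
    return float(np.sqrt(sum(float(np.sum(p.grad * p.grad)) for p in params)))


def train(
    model: FFADenoiser,
    dataset: Sequence[PairedSample],
    config: TrainConfig,
    stage_callback=None,
) -> tuple[FFADenoiser, list[tuple[int, float, float]]]:
    """Train in place; returns the model and a (epoch, lr, mean_loss) history.

    Shuffling and everything downstream is seeded by ``config.seed``;
    identical arguments give identical histories.  ``stage_callback``, if
    given, is called as ``stage_callback(stage_index, epoch, model)`` at
    the start of each new learning-rate stage (e.g. to write checkpoints).
    Raises ``FloatingPointError`` if the loss becomes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    shapes = {s.clean.shape for s in dataset}
    if len(shapes) != 1:
        raise ValueError(f"all samples must share one shape, got {shapes}")

    noisy = np.stack([s.noisy for s in dataset])[:, None].astype(np.float64)
    clean = np.stack([s.clean for s in dataset])[:, None].astype(np.float64)
    targets = noisy - clean
    n = len(dataset)

    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = Adam(params, weight_decay=config.weight_decay)
    history: list[tuple[int, float, float]] = []
    boundaries = config.stage_boundaries()
    for epoch in range(config.epochs):
        lr = lr_schedule(config, epoch)
        if stage_callback is not None and epoch in (0, *boundaries):
            stage = bisect.bisect_right(boundaries, epoch)
            stage_callback(stage, epoch, model)
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = noisy[idx], targets[idx]
            pred = model.forward(xb, training=True)
            m = len(idx)
            diff = pred - tb
            loss = float(np.sum(diff * diff) / (2.0 * m))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss!r} at epoch {epoch}; "
                    "reduce the learning rate or inspect the data"
                )
            model.zero_grad()
            model.backward(diff / m)
            if config.grad_clip is not None:
                norm = _global_grad_norm(params)
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for p in params:
                        p.grad *= scale
            opt.step(lr)
            total += loss * m
            seen += m
        history.append((epoch, lr, total / seen))
    return model, history
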