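"""Minimal NumPy neural-network primitives with manual backpropagation.

Everything operates on float64 NCHW arrays (batch, channels, height,
width).  Each layer caches what its backward pass needs during
``forward(..., training=True)``; ``backward`` consumes the cache,
accumulates parameter gradients in place and returns the gradient with
respect to its input.  Convolutions use a kernel-tap loop so the inner
work is a handful of GEMMs per layer, which keeps dilation support trivial
and parameter counts identical between common and dilated kernels.

Gradient correctness of every layer is pinned by central-difference checks
in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Dense",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Same-padding 2D convolution, stride 1, optional dilation.

    Kaiming fan-in initialization (he-normal) for weights, zeros for the
    bias.  A dilated kernel has exactly the same parameter array as a
    common one of equal size — dilation only changes tap spacing.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        use_bias: bool = True,
        name: str = "conv",
    ):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel // 2)
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel, kernel))
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            std = np.sqrt(2.0 / (in_channels * kernel * kernel))
            w = rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel))
        self.weight = Param(w, f"{name}.weight")
        # a bias feeding straight into batch norm is inert (BN subtracts the
        # channel mean), so such convolutions are built without one
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if use_bias else None
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] if self.bias is None else [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, d = self.pad, self.kernel, self.dilation
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, self.weight.data.shape[0], h, w))
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u * d : u * d + h, v * d : v * d + w]
                out += np.einsum(
                    "oc,nchw->nohw", self.weight.data[:, :, u, v], xs, optimize=True
                )
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if training:
            self._xp = xp
            self._hw = (h, w)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called before a training-mode forward")
        h, w = self._hw
        p, k, d = self.pad, self.kernel, self.dilation
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u * d : u * d + h, v * d : v * d + w]
                self.weight.grad[:, :, u, v] += np.einsum(
                    "nohw,nchw->oc", g, xs, optimize=True
                )
                gxp[:, :, u * d : u * d + h, v * d : v * d + w] += np.einsum(
                    "nohw,oc->nchw", g, self.weight.data[:, :, u, v], optimize=True
                )
        self._xp = None
        return gxp[:, :, p : p + h, p : p + w]


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes with batch statistics and updates running
    estimates (``running = (1 - momentum) * running + momentum * batch``);
    evaluation mode uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before a training-mode forward")
        xhat, invstd, n = self._cache
        self.beta.grad += g.sum(axis=(0, 2, 3))
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        gsum = g.sum(axis=(0, 2, 3), keepdims=False)[None, :, None, None]
        gxsum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        coeff = (self.gamma.data * invstd)[None, :, None, None] / n
        gx = coeff * (n * g - gsum - xhat * gxsum)
        self._cache = None
        return gx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = g * self._mask
        self._mask = None
        return gx


class Sigmoid:
    def __init__(self):
        self._out = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if training:
            self._out = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = g * self._out * (1.0 - self._out)
        self._out = None
        return gx


class Dense:
    """Fully connected layer on (N, F) arrays; used by channel attention
    where 1x1 convolutions on pooled vectors reduce to matrix products."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, name: str = "fc"):
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, (in_features, out_features)), f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ g
        self.bias.grad += g.sum(axis=0)
        gx = g @ self.weight.data.T
        self._x = None
        return gx


# ---------------------------------------------------------------------------
# pooling helpers (functional, cache returned to the caller)
# ---------------------------------------------------------------------------


def channel_max(x: np.ndarray):
    """Max over the channel axis of an NCHW array; returns (max, argmax)."""
    return x.max(axis=1), x.argmax(axis=1)


def channel_max_backward(g: np.ndarray, argmax: np.ndarray, channels: int) -> np.ndarray:
    """Route (N, H, W) gradient to the argmax channel of each pixel."""
    gx = np.zeros((g.shape[0], channels, g.shape[1], g.shape[2]))
    np.put_along_axis(gx, argmax[:, None, :, :], g[:, None, :, :], axis=1)
    return gx


def spatial_max3(x: np.ndarray):
    """3x3 same-padding maximum filter on (N, H, W); returns (out, argidx).

    Padding uses -inf so border maxima are taken over valid pixels only.
    """
    n, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    flat = win.reshape(n, h, w, 9)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg


def spatial_max3_backward(g: np.ndarray, argidx: np.ndarray) -> np.ndarray:
    n, h, w = g.shape
    du, dv = np.divmod(argidx, 3)
    gp = np.zeros((n, h + 2, w + 2))
    ii = np.arange(h)[None, :, None] + du
    jj = np.arange(w)[None, None, :] + dv
    np.add.at(gp, (np.arange(n)[:, None, None], ii, jj), g)
    return gp[:, 1 : 1 + h, 1 : 1 + w]


def spatial_avg3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding average filter (zero padding, fixed /9) on (N, H, W).

    The operator is self-adjoint, so it is its own backward pass.
    """
    return ndimage.uniform_filter(x, size=(1, 3, 3), mode="constant", cval=0.0)
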