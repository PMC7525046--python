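"""Feature-fusion attention network for residual MR denoising.

The model maps a noisy slice ``S`` to a residual (noise) image ``N`` and
reconstructs the clean estimate as ``C = S - N`` by exact elementwise
subtraction.  It is composed, in order:

* **Feature extraction** — two 3x3 conv + ReLU layers *without* batch
  normalization (BN standardizes activations and would destroy the raw
  intensity contrast the earliest features rely on), then alternating
  common and dilated 3x3 conv + BN + ReLU layers, then a spatial-attention
  module.  Dilated taps enlarge the receptive field at zero parameter cost.
* **Feature fusion** — the extraction output is concatenated with the raw
  input along the channel axis (local features fused with the global,
  un-convolved view of the slice), followed by 3x3 conv + BN + ReLU layers.
* **Attention** — a channel-attention module reweights the fused feature
  channels, and a final 3x3 convolution produces the residual.

Spatial attention builds three channel-pooled descriptor maps — the
channel-wise average, the channel-wise max, and the channel-wise max passed
through an extra 3x3 spatial maximum (or average) filter — concatenates
them and convolves to a single sigmoid map in (0, 1) that rescales every
channel.  The extra *maximum* pooling variant is the default: on MR slices
the background is exactly zero and the head strictly positive, so max
pooling steers attention toward brain texture while average pooling would
keep weighting the empty background.

Channel attention pools each channel globally by average and by max,
passes the two pooled vectors through *separate* bottleneck transforms
(1x1 convolutions on a length-C vector, i.e. dense layers), sums them and
applies a sigmoid to obtain per-channel weights in (0, 1).

Everything is NumPy with hand-written backprop; see ``layers``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dense,
    Param,
    ReLU,
    Sigmoid,
    channel_max,
    channel_max_backward,
    spatial_avg3,
    spatial_max3,
    spatial_max3_backward,
)

__all__ = [
    "NetworkConfig",
    "DenoiseResult",
    "SpatialAttention",
    "ChannelAttention",
    "FFADenoiser",
    "build_model",
    "denoise",
    "receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


def _default_dilated_positions(n_layers: int) -> frozenset[int]:
    # even 1-based extraction layers from layer 3 onward: 4, 6, 8, ...
    return frozenset(i for i in range(3, n_layers + 1) if i % 2 == 0)


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The published description of this architecture leaves depth, width,
    dilation placement and several wiring details open; the defaults below
    are this package's choices (documented in docs/methods.md) and every
    one is configurable.

    Attributes
    ----------
    in_channels : channels of the input slice (1 for grayscale MR).
    base_channels : feature width of every internal convolution.
    n_extraction_layers : convolutions in the extraction block (>= 3; the
        first two are BN-free by construction).
    dilation_rate : tap spacing of the dilated convolutions.
    dilated_layer_positions : 1-based extraction-layer indices that use the
        dilated kernel; must avoid layers 1-2.  ``None`` selects the even
        layers from 3 onward.
    spatial_attention_pooling : ``"max_extra"`` (default) or
        ``"avg_extra"`` — whether the third descriptor map of spatial
        attention applies an extra 3x3 spatial max or average filter.
    spatial_attention_kernel : odd kernel size of the attention-map conv.
    fusion_layers : convolutions in the fusion block.
    channel_attention_reduction : bottleneck ratio of channel attention.
    input_scale : intensities are divided by this before the network and
        the residual multiplied back, so internal feature scales are O(1)
        on [0, 255] data.  Purely a reparameterization.
    """

    in_channels: int = 1
    base_channels: int = 64
    n_extraction_layers: int = 10
    dilation_rate: int = 2
    dilated_layer_positions: frozenset[int] | None = None
    spatial_attention_pooling: str = "max_extra"
    spatial_attention_kernel: int = 7
    fusion_layers: int = 2
    channel_attention_reduction: int = 8
    input_scale: float = 255.0

    def __post_init__(self) -> None:
        if self.n_extraction_layers < 3:
            raise ValueError("n_extraction_layers must be >= 3")
        if self.spatial_attention_kernel % 2 != 1:
            raise ValueError("spatial_attention_kernel must be odd")
        if self.fusion_layers < 1:
            raise ValueError("fusion_layers must be >= 1")
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        if self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be > 0")
        pos = self.dilated_layer_positions
        if pos is not None:
            pos = frozenset(int(p) for p in pos)
            bad = [p for p in pos if p < 3 or p > self.n_extraction_layers]
            if bad:
                raise ValueError(
                    "dilated_layer_positions must lie in "
                    f"[3, {self.n_extraction_layers}] (layers 1-2 are the "
                    f"BN-free common convolutions); invalid: {sorted(bad)}"
                )
            object.__setattr__(self, "dilated_layer_positions", pos)

    @property
    def dilated_positions(self) -> frozenset[int]:
        if self.dilated_layer_positions is not None:
            return self.dilated_layer_positions
        return _default_dilated_positions(self.n_extraction_layers)

    def extraction_layers(self) -> list[tuple[int, int]]:
        """(kernel, dilation) of each extraction convolution, in order."""
        return [
            (3, self.dilation_rate if i in self.dilated_positions else 1)
            for i in range(1, self.n_extraction_layers + 1)
        ]

    @classmethod
    def paper(cls, **overrides) -> "NetworkConfig":
        """Full-size default configuration."""
        return cls(**overrides)

    @classmethod
    def tiny(cls, **overrides) -> "NetworkConfig":
        """A small preset that trains on one CPU in minutes."""
        kwargs = dict(base_channels=16, n_extraction_layers=5)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "NetworkConfig":
        if name == "paper":
            return cls.paper(**overrides)
        if name == "tiny":
            return cls.tiny(**overrides)
        raise ValueError(f"unknown preset {name!r}; expected 'paper' or 'tiny'")


@dataclasses.dataclass(frozen=True)
class DenoiseResult:
    """Residual image N and the clean estimate C = S - N."""

    residual: np.ndarray
    denoised: np.ndarray


def receptive_field(config_or_layers: "NetworkConfig | Iterable[tuple[int, int]]") -> int:
    """Analytic receptive-field side of a stride-1 convolution stack.

    Accepts a :class:`NetworkConfig` (uses its extraction stack) or an
    iterable of ``(kernel, dilation)`` pairs.  Uses the recurrence
    ``r <- r + (k - 1) * d`` (all strides 1): a single 3x3 conv gives 3,
    a single 3x3 dilation-2 conv gives 5.
    """
    if isinstance(config_or_layers, NetworkConfig):
        layers = config_or_layers.extraction_layers()
    else:
        layers = list(config_or_layers)
    r = 1
    for k, d in layers:
        r += (k - 1) * d
    return r


class SpatialAttention:
    """Per-pixel attention over channel-pooled descriptor maps."""

    def __init__(self, kernel: int, pooling: str, rng: np.random.Generator, name: str = "sa"):
        if pooling not in ("max_extra", "avg_extra"):
            raise ValueError(
                f"spatial_attention_pooling must be 'max_extra' or 'avg_extra', got {pooling!r}"
            )
        self.pooling = pooling
        self.conv = Conv2d(3, 1, kernel=kernel, dilation=1, rng=rng, name=f"{name}.conv")
        self._cache = None
        self.last_attention_map: np.ndarray | None = None

    def params(self) -> list[Param]:
        return self.conv.params()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        m_avg = x.mean(axis=1)
        m_max, am = channel_max(x)
        if self.pooling == "max_extra":
            third, argidx = spatial_max3(m_max)
        else:
            third, argidx = spatial_avg3(m_max), None
        maps = np.stack([m_avg, m_max, third], axis=1)
        s = self.conv.forward(maps, training)
        a = 1.0 / (1.0 + np.exp(-s))
        self.last_attention_map = a[:, 0]
        if training:
            self._cache = (x, a, am, argidx, c)
        return x * a

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, a, am, argidx, c = self._cache
        ga = (g * x).sum(axis=1, keepdims=True)
        gx = g * a
        gs = ga * a * (1.0 - a)
        gmaps = self.conv.backward(gs)
        gx += gmaps[:, 0:1] / c  # channel-mean backward, broadcast
        g3 = gmaps[:, 2]
        if self.pooling == "max_extra":
            gm_extra = spatial_max3_backward(g3, argidx)
        else:
            gm_extra = spatial_avg3(g3)  # self-adjoint
        gm = gmaps[:, 1] + gm_extra
        gx += channel_max_backward(gm, am, c)
        self._cache = None
        return gx


class ChannelAttention:
    """Per-channel attention from global average- and max-pooled vectors.

    The two pooled vectors go through separate (non-shared) bottleneck
    transforms whose outputs are summed before the sigmoid.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator, name: str = "ca"):
        hidden = max(1, channels // reduction)
        self.avg_fc1 = Dense(channels, hidden, rng, f"{name}.avg_fc1")
        self.avg_fc2 = Dense(hidden, channels, rng, f"{name}.avg_fc2")
        self.max_fc1 = Dense(channels, hidden, rng, f"{name}.max_fc1")
        self.max_fc2 = Dense(hidden, channels, rng, f"{name}.max_fc2")
        self._relu_a = ReLU()
        self._relu_m = ReLU()
        self._cache = None
        self.last_weights: np.ndarray | None = None

    def params(self) -> list[Param]:
        return (
            self.avg_fc1.params()
            + self.avg_fc2.params()
            + self.max_fc1.params()
            + self.max_fc2.params()
        )

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        pa = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, h * w)
        am = flat.argmax(axis=-1)
        pm = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
        za = self.avg_fc2.forward(self._relu_a.forward(self.avg_fc1.forward(pa, training), training), training)
        zm = self.max_fc2.forward(self._relu_m.forward(self.max_fc1.forward(pm, training), training), training)
        wgt = 1.0 / (1.0 + np.exp(-(za + zm)))
        self.last_weights = wgt
        if training:
            self._cache = (x, wgt, am)
        return x * wgt[:, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, wgt, am = self._cache
        n, c, h, w = x.shape
        gw = (g * x).sum(axis=(2, 3))
        gx = g * wgt[:, :, None, None]
        gz = gw * wgt * (1.0 - wgt)
        gpa = self.avg_fc1.backward(self._relu_a.backward(self.avg_fc2.backward(gz)))
        gpm = self.max_fc1.backward(self._relu_m.backward(self.max_fc2.backward(gz)))
        gx += gpa[:, :, None, None] / (h * w)
        gxf = gx.reshape(n, c, h * w)
        gxf[np.arange(n)[:, None], np.arange(c)[None, :], am] += gpm
        self._cache = None
        return gx


class _ConvBNReLU:
    """Conv -> optional BN -> ReLU unit used by both big blocks."""

    def __init__(self, in_ch, out_ch, dilation, use_bn, rng, name):
        self.conv = Conv2d(
            in_ch, out_ch, 3, dilation, rng, use_bias=not use_bn, name=f"{name}.conv"
        )
        self.bn = BatchNorm2d(out_ch, name=f"{name}.bn") if use_bn else None
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + (self.bn.params() if self.bn else [])

    def forward(self, x, training=True):
        x = self.conv.forward(x, training)
        if self.bn is not None:
            x = self.bn.forward(x, training)
        return self.relu.forward(x, training)

    def backward(self, g):
        g = self.relu.backward(g)
        if self.bn is not None:
            g = self.bn.backward(g)
        return self.conv.backward(g)


class FFADenoiser:
    """The residual denoising network (see module docstring)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        b = config.base_channels

        self.extraction: list[_ConvBNReLU] = []
        in_ch = config.in_channels
        for i, (k, d) in enumerate(config.extraction_layers(), start=1):
            use_bn = i > 2  # first two convolutions are BN-free
            self.extraction.append(
                _ConvBNReLU(in_ch, b, d, use_bn, rng, name=f"ext{i}")
            )
            in_ch = b

        self.spatial_attention = SpatialAttention(
            config.spatial_attention_kernel, config.spatial_attention_pooling, rng
        )

        self.fusion: list[_ConvBNReLU] = []
        in_ch = b + config.in_channels  # extraction features || raw input
        for j in range(1, config.fusion_layers + 1):
            self.fusion.append(_ConvBNReLU(in_ch, b, 1, True, rng, name=f"fus{j}"))
            in_ch = b

        self.channel_attention = ChannelAttention(
            b, config.channel_attention_reduction, rng
        )
        self.final_conv = Conv2d(b, config.in_channels, 3, 1, rng, name="out")

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for unit in self.extraction:
            out += unit.params()
        out += self.spatial_attention.params()
        for unit in self.fusion:
            out += unit.params()
        out += self.channel_attention.params()
        out += self.final_conv.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Predict the residual for an NCHW batch (gray-level scale)."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected NCHW input with {self.config.in_channels} channel(s), got shape {x.shape}"
            )
        s = self.config.input_scale
        x0 = np.asarray(x, dtype=np.float64) / s
        feat = x0
        for unit in self.extraction:
            feat = unit.forward(feat, training)
        feat = self.spatial_attention.forward(feat, training)
        fused = np.concatenate([feat, x0], axis=1)
        for unit in self.fusion:
            fused = unit.forward(fused, training)
        fused = self.channel_attention.forward(fused, training)
        residual = self.final_conv.forward(fused, training)
        return residual * s

    def backward(self, g_residual: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the (gray-scale) residual."""
        s = self.config.input_scale
        g = g_residual * s
        g = self.final_conv.backward(g)
        g = self.channel_attention.backward(g)
        for unit in reversed(self.fusion):
            g = unit.backward(g)
        b = self.config.base_channels
        g_feat = g[:, :b]  # gradient into the raw-input copy is discarded
        g_feat = self.spatial_attention.backward(g_feat)
        for unit in reversed(self.extraction):
            g_feat = unit.backward(g_feat)

    # -- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data for p in self.params()}
        for unit in self.extraction + self.fusion:
            if unit.bn is not None:
                state[unit.bn.gamma.name + ".running_mean"] = unit.bn.running_mean
                state[unit.bn.gamma.name + ".running_var"] = unit.bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.data[...] = state[p.name]
        for unit in self.extraction + self.fusion:
            if unit.bn is not None:
                unit.bn.running_mean = np.array(state[unit.bn.gamma.name + ".running_mean"])
                unit.bn.running_var = np.array(state[unit.bn.gamma.name + ".running_var"])


def build_model(config: NetworkConfig, seed: int = 0) -> FFADenoiser:
    """Construct a model with seeded Kaiming initialization."""
    return FFADenoiser(config, seed=seed)


def denoise(model: FFADenoiser, noisy: np.ndarray) -> DenoiseResult:
    """Denoise one 2D slice: residual via a forward pass, C = S - N exactly.

    No clipping is applied; export to 8-bit images may clip separately.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    if noisy.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {noisy.shape}")
    residual = model.forward(noisy[None, None], training=False)[0, 0]
    return DenoiseResult(residual=residual, denoised=noisy - residual)


# ---------------------------------------------------------------------------
# checkpoints: one .npz file with the config embedded as JSON
# ---------------------------------------------------------------------------


def _config_to_json(config: NetworkConfig) -> str:
    d = dataclasses.asdict(config)
    if d["dilated_layer_positions"] is not None:
        d["dilated_layer_positions"] = sorted(d["dilated_layer_positions"])
    return json.dumps(d)


def _config_from_json(text: str) -> NetworkConfig:
    d = json.loads(text)
    if d.get("dilated_layer_positions") is not None:
        d["dilated_layer_positions"] = frozenset(d["dilated_layer_positions"])
    return NetworkConfig(**d)


def save_checkpoint(model: FFADenoiser, path) -> None:
    """Serialize parameters, BN running stats and the config to one file."""
    arrays = dict(model.state_dict())
    arrays["__config__"] = np.frombuffer(
        _config_to_json(model.config).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> FFADenoiser:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        config = _config_from_json(bytes(data["__config__"]).decode("utf-8"))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = FFADenoiser(config, seed=0)
    model.load_state_dict(state)
    return model
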