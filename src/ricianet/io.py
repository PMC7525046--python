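"""File formats: grayscale PNG slices, NIfTI volumes, manifests, configs.

Slices travel as float64 2D arrays on the [0, 255] scale.  PNG I/O is
strict 8-bit grayscale (no silent mode conversion); NIfTI volumes are
sliced along the axial axis and min-max rescaled per volume to [0, 255]
(the fixed 255 peak of the evaluation metrics requires a fixed scale).
Paired datasets are stored as directories of PNGs plus a tab-separated
manifest with the fixed header ``clean<TAB>noisy<TAB>sigma<TAB>seed``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .metrics import MetricReport
from .network import NetworkConfig
from .phantom import PairedSample
from .training import TrainConfig

__all__ = [
    "FormatError",
    "read_png",
    "write_png",
    "read_volume_slices",
    "write_manifest",
    "read_manifest",
    "save_paired_dataset",
    "load_paired_dataset",
    "load_network_config",
    "load_train_config",
    "write_loss_csv",
    "write_metric_csv",
]

MANIFEST_HEADER = "clean\tnoisy\tsigma\tseed"
DEFAULT_SLICE_RANGE = (37, 86)  # inclusive, 0-based: 50 axial slices


class FormatError(ValueError):
    """An input file is not in the expected format."""


# ---------------------------------------------------------------------------
# PNG
# ---------------------------------------------------------------------------


def read_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float64 array in [0, 255]."""
    with Image.open(path) as img:
        if img.mode != "L":
            raise FormatError(
                f"{path}: expected 8-bit grayscale (mode 'L'), got mode {img.mode!r}"
            )
        return np.asarray(img, dtype=np.float64)


def write_png(image: np.ndarray, path, clip: bool = False) -> None:
    """Write a slice as 8-bit grayscale PNG.

    Values are rounded half-to-even; with ``clip=True`` they are clamped to
    [0, 255] first, otherwise out-of-range values are an error.  Integer
    arrays already in range round-trip losslessly.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if clip:
        image = np.clip(image, 0.0, 255.0)
    elif image.min() < 0 or image.max() > 255:
        raise ValueError(
            "values outside [0, 255]; pass clip=True to clamp before writing"
        )
    data = np.rint(image).astype(np.uint8)  # rint rounds half to even
    Image.fromarray(data, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def read_volume_slices(
    path,
    slice_range: tuple[int, int] = DEFAULT_SLICE_RANGE,
    axis: int = 2,
) -> list[np.ndarray]:
    """Extract axial slices from a 3D NIfTI volume, rescaled to [0, 255].

    ``slice_range`` is inclusive on both ends and 0-based; the default
    (37, 86) yields the 50 central axial slices.  Rescaling is per-volume
    min-max (a constant volume maps to all zeros).
    """
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {vol.ndim}D")
    lo, hi = slice_range
    n = vol.shape[axis]
    if not (0 <= lo <= hi < n):
        raise ValueError(
            f"slice_range {slice_range} out of bounds for axis {axis} of length {n}"
        )
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax > vmin:
        vol = (vol - vmin) * (255.0 / (vmax - vmin))
    else:
        vol = np.zeros_like(vol)
    vol = np.moveaxis(vol, axis, -1)
    return [np.ascontiguousarray(vol[..., k]) for k in range(lo, hi + 1)]


# ---------------------------------------------------------------------------
# manifest + paired datasets
# ---------------------------------------------------------------------------


def write_manifest(rows: Sequence[tuple[str, str, float, int]], path) -> None:
    """Write (clean, noisy, sigma, seed) rows as the fixed-schema TSV."""
    lines = [MANIFEST_HEADER]
    for clean, noisy, sigma, seed in rows:
        lines.append(f"{clean}\t{noisy}\t{float(sigma):g}\t{int(seed)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path) -> list[tuple[str, str, float, int]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln]
    if not lines or lines[0] != MANIFEST_HEADER:
        raise FormatError(f"{path}: missing manifest header {MANIFEST_HEADER!r}")
    rows = []
    for ln in lines[1:]:
        clean, noisy, sigma, seed = ln.split("\t")
        rows.append((clean, noisy, float(sigma), int(seed)))
    return rows


def save_paired_dataset(samples: Sequence[PairedSample], directory) -> Path:
    """Write pairs as 8-bit PNGs plus ``manifest.tsv``; returns the manifest path.

    Noisy images are float valued and are clipped and rounded to 8 bits on
    disk, so a saved dataset is quantized relative to the in-memory one.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, s in enumerate(samples):
        cname, nname = f"clean_{k:05d}.png", f"noisy_{k:05d}.png"
        write_png(s.clean, directory / cname, clip=True)
        write_png(s.noisy, directory / nname, clip=True)
        rows.append((cname, nname, s.sigma, s.seed))
    manifest = directory / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest


def load_paired_dataset(manifest_path) -> list[PairedSample]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    samples = []
    for cname, nname, sigma, seed in read_manifest(manifest_path):
        samples.append(
            PairedSample(
                clean=read_png(base / cname),
                noisy=read_png(base / nname),
                sigma=sigma,
                seed=seed,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# YAML configs and CSV reports
# ---------------------------------------------------------------------------


def load_network_config(path) -> NetworkConfig:
    """Network config from YAML; a ``preset`` key seeds the defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    preset = raw.pop("preset", "paper")
    if "dilated_layer_positions" in raw and raw["dilated_layer_positions"] is not None:
        raw["dilated_layer_positions"] = frozenset(raw["dilated_layer_positions"])
    return NetworkConfig.from_preset(preset, **raw)


def load_train_config(path) -> TrainConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    for key in ("lr_multipliers", "lr_stage_boundaries"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return TrainConfig(**raw)


def write_loss_csv(history: Sequence[tuple[int, float, float]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "lr", "mean_loss"])
        for epoch, lr, loss in history:
            w.writerow([epoch, repr(lr), repr(loss)])


def write_metric_csv(
    reports: dict[float, MetricReport], path, verbose: bool = False
) -> None:
    """Per-sigma summary rows; with ``verbose`` also one row per image."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sigma", "n_images", "image", "psnr_db", "ssim"])
        for sigma in sorted(reports):
            rep = reports[sigma]
            w.writerow([sigma, rep.n_images, "mean", repr(rep.mean_psnr), repr(rep.mean_ssim)])
            if verbose:
                for k, (p, s) in enumerate(rep.per_image):
                    w.writerow([sigma, rep.n_images, k, repr(p), repr(s)])
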