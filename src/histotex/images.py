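"""Tile image I/O, color normalization, grayscale conversion and gray-level quantization.

The texture matrices downstream operate on small integer gray levels, so every
pipeline ends in :func:`quantize`, which bins the observed intensity range of a
tile (optionally restricted to an ROI mask) into ``n_levels`` uniform bins.
Binning over the per-image min–max rather than a fixed 0–255 range makes the
texture features invariant to global brightness shifts, in keeping with the
normalization the pipeline applies before feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RawImage",
    "ROIMask",
    "QuantizedImage",
    "read_image",
    "read_mask",
    "write_image",
    "white_balance",
    "normalize_color",
    "to_grayscale",
    "quantize",
    "dequantize",
]

LABELS = ("GBM", "NORMAL", "UNKNOWN")

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Tiles whose ROI mask covers less than this fraction are rejected by default.
DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class RawImage:
    """An 8-bit tile image, grayscale (H, W) or RGB (H, W, 3)."""

    pixels: np.ndarray
    source_id: str = ""
    label: str = "UNKNOWN"
    patient_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"expected (H, W) or (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("zero-area or degenerate image: need H >= 2 and W >= 2")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if px.dtype != np.uint8:
            fmin, fmax = float(px.min()), float(px.max())
            if fmin < 0 or fmax > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    def with_pixels(self, pixels: np.ndarray) -> "RawImage":
        return RawImage(pixels, self.source_id, self.label, self.patient_id)


@dataclass
class ROIMask:
    """Binary region-of-interest mask; True marks pixels inside the ROI."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D grid")

    @property
    def coverage_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class QuantizedImage:
    """Integer gray-level grid; levels run 1..n_levels, 0 marks ignored pixels."""

    grid: np.ndarray
    n_levels: int
    bin_edges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.grid.min() < 0 or self.grid.max() > self.n_levels:
            raise ValueError("grid levels must lie in [0, n_levels]")
        if len(self.bin_edges) != self.n_levels + 1:
            raise ValueError("need n_levels + 1 bin edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return self.grid > 0


def read_image(path: str | Path, label: str = "UNKNOWN") -> RawImage:
    """Read a TIFF or PNG tile into a :class:`RawImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        px = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoder failures vary by backend
        raise ValueError(f"unreadable image: {path}") from exc
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth {px.dtype} (expected 8-bit): {path}")
    if px.size == 0 or px.shape[0] < 2 or px.shape[1] < 2:
        raise ValueError(f"zero-area image: {path}")
    return RawImage(px, source_id=path.stem, label=label)


def read_mask(path: str | Path) -> ROIMask:
    """Read a single-channel PNG mask; nonzero pixels mark the ROI interior."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[..., 0]
    return ROIMask(m != 0)


def write_image(img: RawImage, path: str | Path) -> None:
    iio.imwrite(Path(path), img.pixels)


def white_balance(img: RawImage) -> RawImage:
    """Gray-world white balance: rescale channels so all channel means agree.

    Each channel is multiplied by (global mean / channel mean) so the three
    channel means coincide at the global mean intensity; output clipped to
    [0, 255]. Grayscale input is returned unchanged with a warning.
    """
    if not img.is_color:
        warnings.warn("white_balance: single-channel image returned unchanged", stacklevel=2)
        return img.with_pixels(img.pixels.copy())
    px = img.pixels.astype(float)
    means = px.reshape(-1, 3).mean(axis=0)
    global_mean = means.mean()
    if global_mean == 0 or np.any(means == 0):
        return img.with_pixels(img.pixels.copy())  # all-black guard
    out = px * (global_mean / means)
    return img.with_pixels(np.clip(np.round(out), 0, 255).astype(np.uint8))


def normalize_color(img: RawImage, reference: RawImage) -> RawImage:
    """Match per-channel mean/std of ``img`` to ``reference`` (Reinhard-style).

    For each channel, ``out = (x - mu) / sigma * sigma_ref + mu_ref``; a channel
    with zero variance in either image gets its scale forced to 1 (pure mean
    shift). Output clipped to [0, 255].
    """
    if not img.is_color or not reference.is_color:
        raise ValueError("normalize_color requires 3-channel images")
    px = img.pixels.astype(float)
    ref = reference.pixels.astype(float)
    mu = px.reshape(-1, 3).mean(axis=0)
    sd = px.reshape(-1, 3).std(axis=0)
    mu_r = ref.reshape(-1, 3).mean(axis=0)
    sd_r = ref.reshape(-1, 3).std(axis=0)
    scale = np.where((sd > 0) & (sd_r > 0), np.divide(sd_r, sd, out=np.ones(3), where=sd > 0), 1.0)
    out = (px - mu) * scale + mu_r
    return img.with_pixels(np.clip(np.round(out), 0, 255).astype(np.uint8))


def to_grayscale(img: RawImage) -> RawImage:
    """Convert RGB to luminance with BT.601 weights; grayscale passes through."""
    if not img.is_color:
        return img
    w = np.asarray(LUMA_WEIGHTS)
    gray = img.pixels.astype(float) @ w
    return img.with_pixels(np.clip(np.round(gray), 0, 255).astype(np.uint8))


def quantize(img: RawImage, n_levels: int = 8, mask: ROIMask | None = None) -> QuantizedImage:
    """Uniformly bin the observed intensity range into ``n_levels`` gray levels.

    Bin edges span the min..max intensity of the in-mask pixels, so masked-out
    pixels never influence the binning; they are assigned level 0 (ignored).
    A constant image collapses to level 1 everywhere (with a warning).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if img.is_color:
        raise ValueError("quantize requires a grayscale image; call to_grayscale first")
    px = img.pixels.astype(float)
    if mask is not None:
        if mask.mask.shape != px.shape:
            raise ValueError("mask shape must match image shape")
        inside = mask.mask
        if not inside.any():
            raise ValueError("mask selects no pixels")
    else:
        inside = np.ones_like(px, dtype=bool)
    vals = px[inside]
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        warnings.warn("quantize: constant image, all pixels assigned level 1", stacklevel=2)
        grid = np.where(inside, 1, 0)
        edges = np.linspace(lo, lo + 1.0, n_levels + 1)
        return QuantizedImage(grid, n_levels, edges)
    edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.floor((px - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    levels = np.clip(levels, 1, n_levels)
    grid = np.where(inside, levels, 0)
    return QuantizedImage(grid, n_levels, edges)


def dequantize(q: QuantizedImage) -> np.ndarray:
    """Map levels back to bin-midpoint intensities; ignored pixels become NaN."""
    mids = (q.bin_edges[:-1] + q.bin_edges[1:]) / 2.0
    out = np.full(q.grid.shape, np.nan)
    v = q.valid
    out[v] = mids[q.grid[v] - 1]
    return out
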