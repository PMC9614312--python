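"""Radiograph container and preprocessing: loading, downsampling, Gaussian smoothing.

A full-length lower-limb study arrives as three grayscale exposures (hip,
knee, ankle).  Everything downstream operates on a :class:`Radiograph`: a
float64 intensity grid normalised to [0, 1] with 0-based (row, col)
coordinates, origin at the top-left, row index increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "Radiograph",
    "load_radiograph",
    "downsample",
    "gaussian_smooth",
    "gaussian_kernel_2d",
    "PART_LABELS",
]

PART_LABELS = ("hip", "knee", "ankle", "stitched", "phantom")

# ITU-R BT.709 luminance weights for RGB -> gray reduction.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

_MIN_DIM = 8


@dataclass(frozen=True)
class Radiograph:
    """A grayscale radiograph with intensities on [0, 1].

    Parameters
    ----------
    pixels
        H x W float array, every value in [0, 1].
    part_label
        Which anatomical part (or synthetic/stitched product) this grid holds.
    downsample_factor
        Cumulative integer factor by which the grid has been reduced from
        its source resolution (1 = native).
    source_path
        File the image was read from, if any.
    """

    pixels: np.ndarray
    part_label: str = "phantom"
    downsample_factor: int = 1
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < _MIN_DIM or px.shape[1] < _MIN_DIM:
            raise ValueError(
                f"image too small: {px.shape}, need at least {_MIN_DIM}x{_MIN_DIM}"
            )
        if not np.isfinite(px).all():
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{px.min():.6g}, {px.max():.6g}]"
            )
        if self.part_label not in PART_LABELS:
            raise ValueError(
                f"unknown part_label {self.part_label!r}; expected one of {PART_LABELS}"
            )
        if int(self.downsample_factor) < 1:
            raise ValueError("downsample_factor must be >= 1")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "Radiograph":
        """Copy of this radiograph with a new pixel grid, same metadata."""
        return replace(self, pixels=pixels)


def load_radiograph(path: str | Path, part_label: str) -> Radiograph:
    """Read a JPG/PNG/TIFF image into a normalised grayscale :class:`Radiograph`.

    Color images are reduced to luminance; 8- and 16-bit integer images are
    rescaled by their dtype maximum so a saturated pixel maps to 1.0.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise IOError(f"empty image file: {path}")

    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(np.float64) @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise IOError(f"unsupported channel count {arr.shape[2]} in {path}")
    elif arr.ndim != 2:
        raise IOError(f"unsupported image dimensionality {arr.ndim} in {path}")

    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(raw).dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)

    return Radiograph(
        pixels=np.clip(arr, 0.0, 1.0),
        part_label=part_label,
        downsample_factor=1,
        source_path=str(path),
    )


def downsample(r: Radiograph, factor: int) -> Radiograph:
    """Block-mean downsampling by an integer factor.

    Each output pixel is the mean of its ``factor x factor`` source block;
    trailing rows/columns that do not fill a block are dropped.  Block
    averaging acts as the anti-alias filter, and is exact on integer blocks.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return r
    h, w = r.shape
    if h < _MIN_DIM * factor or w < _MIN_DIM * factor:
        raise ValueError(
            f"image {h}x{w} too small to downsample by {factor} "
            f"(needs >= {_MIN_DIM * factor} per side)"
        )
    h2, w2 = h // factor, w // factor
    block = r.pixels[: h2 * factor, : w2 * factor]
    out = block.reshape(h2, factor, w2, factor).mean(axis=(1, 3))
    return replace(
        r, pixels=out, downsample_factor=r.downsample_factor * factor
    )


def gaussian_kernel_2d(sigma: float, size: int = 5) -> np.ndarray:
    """Normalised ``size x size`` Gaussian kernel, weights summing to 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_smooth(r: Radiograph, sigma: float = 1.0, size: int = 5) -> Radiograph:
    """Smooth with a normalised ``size x size`` Gaussian kernel (default 5x5).

    Borders are handled by reflection, which avoids the dark halo a
    zero-padded convolution would create at tile edges (and the false edges
    the detector would then find there).
    """
    k = gaussian_kernel_2d(sigma, size)
    out = ndimage.convolve(r.pixels, k, mode="reflect")
    # convex combination of in-range values; clip only to shed float dust
    return r.with_pixels(np.clip(out, 0.0, 1.0))
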