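"""Bone-edge extraction with a from-scratch Canny detector.

The stitching method rests entirely on the binary bone-edge map
``E[x, y] ∈ {0, 1}``: cortical bone gives the strongest, most reproducible
gradients in a limb radiograph, so edges alone carry enough signal to
register adjacent exposures.  The detector is the classical four-stage
composition — Gaussian smoothing, Sobel gradients, non-maximum suppression,
double-threshold hysteresis — implemented here stage by stage so each stage
is individually testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .radiograph import Radiograph, gaussian_smooth

__all__ = [
    "EdgeMap",
    "CannyConfig",
    "sobel_gradients",
    "non_maximum_suppression",
    "hysteresis_threshold",
    "canny",
]

log = logging.getLogger(__name__)

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge map with the thresholds that produced it.

    ``edges`` is an H x W uint8 grid of {0, 1}; ``n_edge_pixels`` is its sum.
    """

    edges: np.ndarray
    low_threshold: float = 0.0
    high_threshold: float = 0.0
    n_edge_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e.ndim != 2:
            raise ValueError("edge grid must be 2-D")
        vals = np.unique(e)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("edge grid must be strictly binary (0/1)")
        if not (0.0 <= self.low_threshold <= self.high_threshold):
            raise ValueError(
                "thresholds must satisfy 0 <= low <= high, got "
                f"low={self.low_threshold}, high={self.high_threshold}"
            )
        object.__setattr__(self, "edges", e.astype(np.uint8))
        object.__setattr__(self, "n_edge_pixels", int(e.sum()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.edges.shape  # type: ignore[return-value]

    def is_empty(self) -> bool:
        return self.n_edge_pixels == 0


@dataclass(frozen=True)
class CannyConfig:
    """Detector knobs.

    threshold_mode
        ``"absolute"`` (default): use ``low_abs``/``high_abs`` gradient-
        magnitude units directly.  Because every radiograph is normalised to
        [0, 1] on input, absolute thresholds are well-posed and — unlike
        percentiles — independent of how much of the frame the anatomy
        covers: on a sparse-edged image a percentile cutoff slides into the
        noise floor and admits spurious edges.
        ``"percentile"``: ``high`` = the ``high_percentile``-th percentile of
        the nonzero gradient magnitudes, ``low = low_ratio * high``; useful
        when tile exposures differ enough that one absolute scale cannot
        serve both.
    sigma, kernel_size
        The pre-smoothing Gaussian (5x5 support by default).
    bright_mask_quantile
        Optional: pixels brighter than this intensity quantile are barred
        from being edge pixels (bright saturated regions sit far from the
        cortical contour).  ``None`` disables the mask.
    """

    sigma: float = 1.0
    kernel_size: int = 5
    threshold_mode: str = "absolute"
    high_percentile: float = 90.0
    low_ratio: float = 0.4
    low_abs: float = 0.08
    high_abs: float = 0.2
    bright_mask_quantile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("percentile", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0 < self.high_percentile <= 100:
            raise ValueError("high_percentile must be in (0, 100]")
        if not 0 <= self.low_ratio <= 1:
            raise ValueError("low_ratio must be in [0, 1]")
        if self.low_abs > self.high_abs:
            raise ValueError("low_abs must not exceed high_abs")
        if self.bright_mask_quantile is not None and not (
            0 < self.bright_mask_quantile < 1
        ):
            raise ValueError("bright_mask_quantile must be in (0, 1)")


def sobel_gradients(r: Radiograph) -> tuple[np.ndarray, np.ndarray]:
    """3x3 Sobel gradient magnitude and direction (reflect borders).

    Returns ``(magnitude, direction)`` where direction = atan2(gy, gx) in
    (-pi, pi], gx the column derivative and gy the row derivative.
    """
    # correlate, not convolve: keeps the conventional dark-to-bright sign
    gx = ndimage.correlate(r.pixels, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(r.pixels, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy), np.arctan2(gy, gx)


def non_maximum_suppression(
    magnitude: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Thin the magnitude grid to ridge pixels along the gradient direction.

    The direction is quantised to the nearest of four bins (0, 45, 90,
    135 degrees); a pixel survives iff its magnitude is >= both neighbours
    along that axis.  The >= (not >) rule keeps every genuine maximum on a
    plateau; duplicate plateau pixels are tolerated downstream.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    if magnitude.shape != direction.shape:
        raise ValueError("magnitude and direction shapes differ")

    # Fold direction to [0, 180) and quantise: 0=cols, 45=main diag, 90=rows.
    deg = np.degrees(direction) % 180.0
    bins = ((deg + 22.5) // 45).astype(int) % 4

    padded = np.pad(magnitude, 1, mode="constant")
    c = padded[1:-1, 1:-1]
    # neighbour pairs along the gradient axis, per bin
    neigh = {
        0: (padded[1:-1, :-2], padded[1:-1, 2:]),     # horizontal gradient
        1: (padded[:-2, :-2], padded[2:, 2:]),        # 45 deg
        2: (padded[:-2, 1:-1], padded[2:, 1:-1]),     # vertical gradient
        3: (padded[:-2, 2:], padded[2:, :-2]),        # 135 deg
    }
    keep = np.zeros_like(magnitude, dtype=bool)
    for b, (n1, n2) in neigh.items():
        sel = bins == b
        keep |= sel & (c >= n1) & (c >= n2)
    out = np.where(keep, magnitude, 0.0)
    return out


def hysteresis_threshold(
    thinned: np.ndarray, low: float, high: float
) -> EdgeMap:
    """Double-threshold hysteresis on a thinned magnitude grid.

    Pixels >= ``high`` are strong seeds; pixels in ``[low, high)`` survive
    iff they are 8-connected (transitively) to a seed.
    """
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    thinned = np.asarray(thinned, dtype=np.float64)
    strong = thinned >= high
    candidate = thinned >= low
    if not strong.any():
        return EdgeMap(np.zeros(thinned.shape, dtype=np.uint8), low, high)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labels, _ = ndimage.label(candidate, structure=structure)
    seed_labels = np.unique(labels[strong])
    keep = np.isin(labels, seed_labels[seed_labels > 0])
    return EdgeMap(keep.astype(np.uint8), low, high)


def _resolve_thresholds(
    magnitude: np.ndarray, cfg: CannyConfig
) -> tuple[float, float]:
    if cfg.threshold_mode == "absolute":
        return float(cfg.low_abs), float(cfg.high_abs)
    nz = magnitude[magnitude > 0]
    if nz.size == 0:
        return 0.0, 0.0
    high = float(np.percentile(nz, cfg.high_percentile))
    return cfg.low_ratio * high, high


def canny(r: Radiograph, cfg: CannyConfig | None = None) -> EdgeMap:
    """Full edge detector: smooth -> gradients -> NMS -> hysteresis.

    A degenerate image (zero gradient everywhere) yields an empty edge map
    with a logged warning rather than an error.
    """
    cfg = cfg or CannyConfig()
    smoothed = gaussian_smooth(r, sigma=cfg.sigma, size=cfg.kernel_size)
    magnitude, direction = sobel_gradients(smoothed)
    if magnitude.max() < 1e-12:  # constant image up to float residue
        log.warning(
            "canny: zero gradient everywhere (constant image %s) -> empty edge map",
            r.part_label,
        )
        return EdgeMap(np.zeros(r.shape, dtype=np.uint8), 0.0, 0.0)
    thinned = non_maximum_suppression(magnitude, direction)
    low, high = _resolve_thresholds(magnitude, cfg)
    if cfg.bright_mask_quantile is not None:
        cutoff = np.quantile(smoothed.pixels, cfg.bright_mask_quantile)
        thinned = np.where(smoothed.pixels > cutoff, 0.0, thinned)
    return hysteresis_threshold(thinned, low, high)
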