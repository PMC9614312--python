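"""Wavelet-domain blending of overlap strips and canvas composition.

Once registration fixes the translation between consecutive tiles, the two
copies of each overlap region are fused in the wavelet domain: both strips
are decomposed with a multilevel 2-D wavelet transform, corresponding
coefficients at each scale are combined convexly,

    W_i = theta * W_i^1 + (1 - theta) * W_i^2,

and the inverse transform yields the blended strip.  With a uniform theta
this is numerically identical to a per-pixel convex combination (the
transform is linear); a per-scale theta lets the fusion favour one exposure
at fine scales while averaging coarse structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pywt

from .radiograph import Radiograph
from .registration import RegistrationResult

__all__ = ["BlendConfig", "StitchReport", "wavelet_blend", "compose_canvas"]

log = logging.getLogger(__name__)

Theta = Union[float, Sequence[float]]


@dataclass(frozen=True)
class BlendConfig:
    """Fusion knobs.

    wavelet_family : any PyWavelets discrete family name (default Haar).
    levels : decomposition depth; reduced automatically on strips too small
        to support it.
    theta : blend weight(s) in [0, 1].  A scalar applies uniformly; a
        sequence of length ``levels + 1`` assigns one weight to the
        approximation band followed by the detail scales, coarsest first.
    """

    wavelet_family: str = "haar"
    levels: int = 3
    theta: Theta = 0.5

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        pywt.Wavelet(self.wavelet_family)  # raises on unknown family
        th = self.theta
        if np.isscalar(th):
            vals = [float(th)]  # type: ignore[arg-type]
        else:
            vals = [float(t) for t in th]  # type: ignore[union-attr]
            if len(vals) != self.levels + 1:
                raise ValueError(
                    f"per-scale theta needs {self.levels + 1} entries "
                    f"(approximation + {self.levels} detail scales), got {len(vals)}"
                )
        if any(not 0.0 <= t <= 1.0 for t in vals):
            raise ValueError("every theta must lie in [0, 1]")


@dataclass
class StitchReport:
    """Everything a reader needs to audit one stitch."""

    dx12: int
    dy12: int
    dx23: int
    dy23: int
    matching_distance_12: float
    matching_distance_23: float
    canvas_height: int
    canvas_width: int
    tile_placements: list[tuple[int, int]] = field(default_factory=list)
    blend: Optional[dict] = None
    padded_columns: int = 0
    warnings: list[str] = field(default_factory=list)
    hka_deg: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "offsets": {
                "hip-knee": {"dx": self.dx12, "dy": self.dy12},
                "knee-ankle": {"dx": self.dx23, "dy": self.dy23},
            },
            "matching_distance": {
                "hip-knee": self.matching_distance_12,
                "knee-ankle": self.matching_distance_23,
            },
            "canvas": {"height": self.canvas_height, "width": self.canvas_width},
            "tile_placements": [list(p) for p in self.tile_placements],
            "blend": self.blend,
            "padded_columns": self.padded_columns,
            "warnings": list(self.warnings),
            "hka_deg": self.hka_deg,
        }


def _resolve_thetas(cfg: BlendConfig, levels_eff: int) -> list[float]:
    if np.isscalar(cfg.theta):
        return [float(cfg.theta)] * (levels_eff + 1)  # type: ignore[arg-type]
    th = [float(t) for t in cfg.theta]  # type: ignore[union-attr]
    # approximation weight + the coarsest levels_eff detail weights
    return [th[0]] + th[1 : levels_eff + 1]


def wavelet_blend(
    i1: np.ndarray, i2: np.ndarray, cfg: BlendConfig | None = None
) -> np.ndarray:
    """Fuse two aligned overlap strips in the wavelet domain.

    Both strips are transformed (symmetric extension handles arbitrary strip
    sizes), coefficients are combined per scale with theta, and the inverse
    transform is cropped back to the strip shape and clipped to [0, 1].
    Strips too small for the configured depth are blended at the deepest
    supported level (down to a plain pixel-domain combination).
    """
    cfg = cfg or BlendConfig()
    i1 = np.asarray(i1, dtype=np.float64)
    i2 = np.asarray(i2, dtype=np.float64)
    if i1.shape != i2.shape:
        raise ValueError(f"strip shapes differ: {i1.shape} vs {i2.shape}")

    wavelet = pywt.Wavelet(cfg.wavelet_family)
    max_lvl = pywt.dwt_max_level(min(i1.shape), wavelet.dec_len)
    levels_eff = min(cfg.levels, max_lvl)
    if levels_eff < cfg.levels:
        log.debug(
            "wavelet_blend: strip %s supports only %d levels (%d requested)",
            i1.shape,
            levels_eff,
            cfg.levels,
        )
    thetas = _resolve_thetas(cfg, max(levels_eff, 0))
    if levels_eff < 1:
        t = thetas[0]
        return np.clip(t * i1 + (1.0 - t) * i2, 0.0, 1.0)

    c1 = pywt.wavedec2(i1, wavelet, mode="symmetric", level=levels_eff)
    c2 = pywt.wavedec2(i2, wavelet, mode="symmetric", level=levels_eff)
    blended = [thetas[0] * c1[0] + (1.0 - thetas[0]) * c2[0]]
    for k in range(1, levels_eff + 1):  # k=1 is the coarsest detail scale
        t = thetas[k]
        blended.append(
            tuple(t * a + (1.0 - t) * b for a, b in zip(c1[k], c2[k]))
        )
    rec = pywt.waverec2(blended, wavelet, mode="symmetric")
    rec = rec[: i1.shape[0], : i1.shape[1]]
    return np.clip(rec, 0.0, 1.0)


def compose_canvas(
    tiles: Sequence[Radiograph],
    reg12: RegistrationResult,
    reg23: RegistrationResult,
    cfg: BlendConfig | None = None,
) -> tuple[Radiograph, StitchReport]:
    """Assemble three registered tiles (hip, knee, ankle order) into one
    full-length canvas.

    Rows outside the two overlap regions are copied verbatim from their
    source tile; overlap rows are replaced by the wavelet blend of the two
    aligned strips over their common column span.  Horizontal shifts widen
    the canvas to the union of the shifted tile extents; uncovered pixels
    stay zero and are reported as padding rather than cropped, so no
    anatomy is lost.
    """
    cfg = cfg or BlendConfig()
    if len(tiles) != 3:
        raise ValueError(f"need exactly three tiles, got {len(tiles)}")
    t1, t2, t3 = (t.pixels for t in tiles)
    (h1, w1), (h2, w2), (h3, w3) = (t.shape for t in (t1, t2, t3))
    dy12, dy23 = reg12.dy, reg23.dy
    if dy12 >= min(h1, h2) or dy23 >= min(h2, h3):
        raise ValueError("overlap height exceeds a tile height")
    if dy12 + dy23 > h2:
        raise ValueError(
            f"overlaps {dy12}+{dy23} consume more than the middle tile ({h2} rows)"
        )

    # tile placements in canvas coordinates
    rows = [0, h1 - dy12, h1 + h2 - dy12 - dy23]
    cols_raw = [0, reg12.dx, reg12.dx + reg23.dx]
    col0 = min(cols_raw)
    cols = [c - col0 for c in cols_raw]
    height = h1 + h2 + h3 - dy12 - dy23
    width = max(c + w for c, w in zip(cols, (w1, w2, w3)))

    canvas = np.zeros((height, width), dtype=np.float64)
    covered = np.zeros((height, width), dtype=bool)
    warnings: list[str] = []

    def paste(tile: np.ndarray, r0: int, c0: int, row_lo: int, row_hi: int) -> None:
        """Copy tile rows [row_lo, row_hi) (tile coords) into the canvas."""
        canvas[r0 + row_lo : r0 + row_hi, c0 : c0 + tile.shape[1]] = tile[
            row_lo:row_hi
        ]
        covered[r0 + row_lo : r0 + row_hi, c0 : c0 + tile.shape[1]] = True

    # exclusive rows first
    paste(t1, rows[0], cols[0], 0, h1 - dy12)
    paste(t2, rows[1], cols[1], dy12, h2 - dy23)
    paste(t3, rows[2], cols[2], dy23, h3)

    def blend_overlap(
        upper: np.ndarray,
        lower: np.ndarray,
        r_canvas: int,
        c_up: int,
        c_lo: int,
        dy: int,
    ) -> None:
        hu, wu = upper.shape
        strip_u_rows = upper[hu - dy :]
        strip_l_rows = lower[:dy]
        lo = max(c_up, c_lo)
        hi = min(c_up + wu, c_lo + lower.shape[1])
        if hi > lo:
            su = strip_u_rows[:, lo - c_up : hi - c_up]
            sl = strip_l_rows[:, lo - c_lo : hi - c_lo]
            canvas[r_canvas : r_canvas + dy, lo:hi] = wavelet_blend(su, sl, cfg)
            covered[r_canvas : r_canvas + dy, lo:hi] = True
        # columns covered by only one tile: copy that tile verbatim
        for strip, c0, w in ((strip_u_rows, c_up, wu), (strip_l_rows, c_lo, lower.shape[1])):
            left = slice(c0, lo) if c0 < lo else None
            right = slice(hi, c0 + w) if c0 + w > hi else None
            for span in (left, right):
                if span is None:
                    continue
                canvas[r_canvas : r_canvas + dy, span] = strip[
                    :, span.start - c0 : span.stop - c0
                ]
                covered[r_canvas : r_canvas + dy, span] = True

    blend_overlap(t1, t2, rows[1], cols[0], cols[1], dy12)
    blend_overlap(t2, t3, rows[2] , cols[1], cols[2], dy23)

    padded = int(width * height - covered.sum())
    if padded:
        warnings.append(
            f"{padded} canvas pixels outside every shifted tile were zero-filled"
        )

    report = StitchReport(
        dx12=reg12.dx,
        dy12=dy12,
        dx23=reg23.dx,
        dy23=dy23,
        matching_distance_12=reg12.matching_distance,
        matching_distance_23=reg23.matching_distance,
        canvas_height=height,
        canvas_width=width,
        tile_placements=[(r, c) for r, c in zip(rows, cols)],
        blend={
            "wavelet_family": cfg.wavelet_family,
            "levels": cfg.levels,
            "theta": cfg.theta if np.isscalar(cfg.theta) else list(cfg.theta),  # type: ignore[arg-type]
        },
        padded_columns=padded,
        warnings=warnings,
    )
    stitched = Radiograph(
        pixels=np.clip(canvas, 0.0, 1.0),
        part_label="stitched",
        downsample_factor=tiles[0].downsample_factor,
    )
    return stitched, report
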