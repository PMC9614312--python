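"""Synthetic full-length leg phantoms with known geometry.

Clinical full-length studies are rarely shareable, so the package carries a
generator of leg-like radiograph phantoms: two capsule-shaped "bones"
(femur and tibia) meeting at the knee with a programmed varus/valgus
deviation, rendered brighter than a soft-tissue background with a smoothed
cortical intensity ramp so a gradient edge detector fires cleanly on the
contour.  The phantom is then cut into three vertically overlapping tiles
(hip, knee, ankle) with known offsets, giving ground truth for every stage
of the stitching pipeline: edge maps, registration offsets, the composed
canvas and the HKA angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .hka import LandmarkTriple, hka_angle
from .radiograph import Radiograph

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "tile_phantom",
    "add_gaussian_noise",
    "bone_field",
]

Point = tuple[float, float]  # (row, col)

_MIN_TILE = 24  # rows: smallest tile the pipeline can do anything with
_RAMP = 3.0  # px: width of the smoothed cortical-edge intensity ramp
_BACKGROUND = 0.25
_BONE = 0.80
_TEXTURE_AMPLITUDE = 0.02  # soft-tissue texture, deterministic per seed
_TEXTURE_SIGMA = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one phantom.

    ``femur_axis`` runs hip centre -> knee centre and ``tibia_axis`` knee
    centre -> ankle centre; the two must share the knee point, and the angle
    they form must equal ``180 + varus_valgus_deg`` under the signed HKA
    convention.  ``PhantomSpec.standard`` builds a consistent spec from the
    deviation alone.
    """

    canvas_height: int
    canvas_width: int
    femur_axis: tuple[Point, Point]
    tibia_axis: tuple[Point, Point]
    bone_halfwidth: float
    varus_valgus_deg: float = 0.0
    noise_sd: float = 0.0
    ruler: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_height < 3 * _MIN_TILE:
            raise ValueError(
                f"canvas_height {self.canvas_height} < 3 x minimum tile "
                f"height ({3 * _MIN_TILE})"
            )
        if self.canvas_width < _MIN_TILE:
            raise ValueError(f"canvas_width {self.canvas_width} too small")
        if self.bone_halfwidth < 2:
            raise ValueError("bone_halfwidth must be >= 2 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        hip, knee_f = (tuple(map(float, p)) for p in self.femur_axis)
        knee_t, ankle = (tuple(map(float, p)) for p in self.tibia_axis)
        if knee_f != knee_t:
            raise ValueError("femur and tibia axes must share the knee point")
        for name, (r, c) in (("hip", hip), ("knee", knee_f), ("ankle", ankle)):
            if not (0 <= r < self.canvas_height and 0 <= c < self.canvas_width):
                raise ValueError(f"{name} centre {(r, c)} lies outside the canvas")
        got = hka_angle(LandmarkTriple(hip, knee_f, ankle))
        want = 180.0 + self.varus_valgus_deg
        if abs(got - want) > 1e-6:
            raise ValueError(
                f"axis geometry gives HKA {got:.8f} deg but varus_valgus_deg "
                f"promises {want:.8f}"
            )
        object.__setattr__(self, "femur_axis", (hip, knee_f))
        object.__setattr__(self, "tibia_axis", (knee_t, ankle))

    @classmethod
    def standard(
        cls,
        canvas_height: int = 852,
        canvas_width: int = 830,
        varus_valgus_deg: float = 0.0,
        bone_halfwidth: float = 40.0,
        noise_sd: float = 0.0,
        ruler: bool = False,
        seed: int = 0,
        limb_fraction: float = 0.8,
    ) -> "PhantomSpec":
        """Build a consistent spec from the programmed deviation.

        The knee sits at mid-canvas; femur and tibia are symmetric segments
        of length ``limb_fraction * canvas_height / 2`` tilted by half the
        deviation each, so the knee angle is exactly
        ``180 + varus_valgus_deg``.
        """
        knee = (canvas_height / 2.0, canvas_width / 2.0)
        seg = limb_fraction * canvas_height / 2.0
        half = math.radians(varus_valgus_deg / 2.0)
        hip = (knee[0] - seg * math.cos(half), knee[1] + seg * math.sin(half))
        ankle = (knee[0] + seg * math.cos(half), knee[1] + seg * math.sin(half))
        return cls(
            canvas_height=canvas_height,
            canvas_width=canvas_width,
            femur_axis=(hip, knee),
            tibia_axis=(knee, ankle),
            bone_halfwidth=bone_halfwidth,
            varus_valgus_deg=varus_valgus_deg,
            noise_sd=noise_sd,
            ruler=ruler,
            seed=seed,
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth carried alongside a phantom.

    Landmark centres are in full-canvas (row, col) coordinates.  Offsets are
    (dx, dy) pairs — dx the column shift of the lower tile relative to the
    upper, dy the overlap height — and stay ``None`` until the phantom is
    tiled.  ``tile_origins`` records where each tile window sat in the
    canvas, which lets landmarks be mapped into tile or stitched-canvas
    coordinates.
    """

    hip_center: Point
    knee_center: Point
    ankle_center: Point
    hka_true_deg: float
    true_offset_12: Optional[tuple[int, int]] = None
    true_offset_23: Optional[tuple[int, int]] = None
    tile_origins: Optional[tuple[tuple[int, int], ...]] = None

    def landmarks(self) -> LandmarkTriple:
        return LandmarkTriple(self.hip_center, self.knee_center, self.ankle_center)

    def to_dict(self) -> dict:
        return {
            "hip_center": list(self.hip_center),
            "knee_center": list(self.knee_center),
            "ankle_center": list(self.ankle_center),
            "hka_true_deg": self.hka_true_deg,
            "true_offset_12": list(self.true_offset_12)
            if self.true_offset_12
            else None,
            "true_offset_23": list(self.true_offset_23)
            if self.true_offset_23
            else None,
            "tile_origins": [list(o) for o in self.tile_origins]
            if self.tile_origins
            else None,
        }


# Cortical width modulation: two incommensurate ripples per bone give the
# shaft outline longitudinal structure, so a vertical shift of the tile
# misaligns the edges everywhere (a constant-width shaft would be
# self-similar under vertical translation and leave registration ambiguous).
_WAVE = {
    "femur": ((0.08, 47.0, 0.7), (0.05, 89.0, 2.1)),
    "tibia": ((0.08, 47.0, 1.9), (0.05, 89.0, 0.4)),
}


def _capsule_field(
    rr: np.ndarray, cc: np.ndarray, p0: Point, p1: Point,
    halfwidth: float, bone: str,
) -> np.ndarray:
    """Signed inside-ness field of one wavy-width bone shaft.

    Positive inside the bone, zero on the outline, ~ -distance outside.
    ``F = w(s) - d`` where d is the distance to the axis segment and w the
    rippled halfwidth at arc position s of the closest axis point.
    """
    wr, wc = p1[0] - p0[0], p1[1] - p0[1]
    length = math.hypot(wr, wc)
    t = np.clip(((rr - p0[0]) * wr + (cc - p0[1]) * wc) / (length * length), 0.0, 1.0)
    d = np.hypot(rr - (p0[0] + t * wr), cc - (p0[1] + t * wc))
    s = t * length
    w = np.full_like(d, halfwidth)
    for amp, wavelength, phase in _WAVE[bone]:
        w = w + halfwidth * amp * np.sin(2.0 * math.pi * s / wavelength + phase)
    return w - d


def _disc_field(
    rr: np.ndarray, cc: np.ndarray, center: Point, radius: float
) -> np.ndarray:
    return radius - np.hypot(rr - center[0], cc - center[1])


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def bone_field(spec: PhantomSpec, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Signed field of the whole bone silhouette (union of shafts + joints).

    Zero on the analytic outline, positive inside; the rendered intensity
    ramp is centred on the zero level set, so detected edges should hug it.
    """
    hip, knee = spec.femur_axis
    _, ankle = spec.tibia_axis
    hw = spec.bone_halfwidth
    # perpendicular unit vector at the knee, for the two condyle discs
    tr, tc = ankle[0] - knee[0], ankle[1] - knee[1]
    norm = math.hypot(tr, tc)
    pr, pc = -tc / norm, tr / norm
    fields = [
        _capsule_field(rr, cc, hip, knee, hw, "femur"),
        _capsule_field(rr, cc, knee, ankle, hw, "tibia"),
        _disc_field(rr, cc, hip, 1.5 * hw),                      # femoral head
        _disc_field(rr, cc, (knee[0] + 0.9 * hw * pr, knee[1] + 0.9 * hw * pc), 1.15 * hw),
        _disc_field(rr, cc, (knee[0] - 0.9 * hw * pr, knee[1] - 0.9 * hw * pc), 1.15 * hw),
        _disc_field(rr, cc, ankle, 1.25 * hw),                   # talar dome
    ]
    return np.maximum.reduce(fields)


def generate_phantom(spec: PhantomSpec) -> tuple[Radiograph, PhantomTruth]:
    """Render the phantom canvas and its ground truth.

    Bones are capsule-like shafts whose cortical halfwidth ripples gently
    along the axis, joined to disc-shaped joint masses (femoral head, knee
    condyles, talar dome), with a 3-pixel smoothed intensity ramp at the
    outline; the background carries low-amplitude smoothed texture.  Additive Gaussian
    noise with ``spec.noise_sd`` is applied last and the result clipped to
    [0, 1].  Deterministic for a given spec (the seed drives texture and
    noise).
    """
    h, w = spec.canvas_height, spec.canvas_width
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    field = bone_field(spec, rr, cc)
    bone_fraction = _smoothstep((field + _RAMP / 2.0) / _RAMP)
    img = _BACKGROUND + (_BONE - _BACKGROUND) * bone_fraction

    rng = np.random.default_rng(spec.seed)
    texture = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), _TEXTURE_SIGMA, mode="reflect"
    )
    img = img + _TEXTURE_AMPLITUDE * texture / max(np.abs(texture).max(), 1e-12)

    if spec.ruler:
        col0 = 10
        img[:, col0 : col0 + 5] = 0.85
        tick = (np.arange(h) % 20) < 2
        img[tick, col0 : col0 + 5] = 0.3

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))

    hip, knee = spec.femur_axis
    _, ankle = spec.tibia_axis
    truth = PhantomTruth(
        hip_center=hip,
        knee_center=knee,
        ankle_center=ankle,
        hka_true_deg=180.0 + spec.varus_valgus_deg,
    )
    radiograph = Radiograph(
        pixels=np.clip(img, 0.0, 1.0), part_label="phantom"
    )
    return radiograph, truth


def tile_phantom(
    image: Radiograph,
    truth: PhantomTruth,
    overlap_12: int,
    overlap_23: int,
    dx_12: int = 0,
    dx_23: int = 0,
) -> tuple[tuple[Radiograph, Radiograph, Radiograph], PhantomTruth]:
    """Cut the canvas into three overlapping tiles with known offsets.

    The canvas rows are split at thirds; tile 1 extends ``overlap_12`` rows
    past the first cut, tile 2 spans both cuts plus ``overlap_23`` rows, and
    tile 3 covers the final third.  Horizontal shifts are realised by
    cropping laterally shifted windows of common width from the canvas, so
    the bottom ``overlap_12`` rows of tile 1 and the top ``overlap_12`` rows
    of tile 2 show identical anatomy displaced by exactly ``(dx_12, 0)``.
    """
    h, w = image.shape
    q = h // 3
    for name, ov in (("overlap_12", overlap_12), ("overlap_23", overlap_23)):
        if not 0 < ov < q:
            raise ValueError(
                f"{name}={ov} out of range: must be in (0, {q}) for a "
                f"{h}-row canvas (nominal tile height {q})"
            )

    shift = -min(0, dx_12, dx_12 + dx_23)
    tile_w = w - shift - max(0, dx_12, dx_12 + dx_23)
    if tile_w < _MIN_TILE:
        raise ValueError(
            f"horizontal shifts ({dx_12}, {dx_23}) leave only {tile_w} "
            f"columns of common width"
        )
    origins = (
        (0, shift),
        (q, shift + dx_12),
        (2 * q, shift + dx_12 + dx_23),
    )
    row_spans = ((0, q + overlap_12), (q, 2 * q + overlap_23), (2 * q, h))
    labels = ("hip", "knee", "ankle")
    tiles = []
    for (r0, r1), (_, c0), label in zip(row_spans, origins, labels):
        tiles.append(
            Radiograph(
                pixels=image.pixels[r0:r1, c0 : c0 + tile_w],
                part_label=label,
                downsample_factor=image.downsample_factor,
            )
        )
    new_truth = replace(
        truth,
        true_offset_12=(dx_12, overlap_12),
        true_offset_23=(dx_23, overlap_23),
        tile_origins=origins,
    )
    return (tiles[0], tiles[1], tiles[2]), new_truth


def add_gaussian_noise(r: Radiograph, sd: float, seed: int) -> Radiograph:
    """Per-exposure additive Gaussian noise, clipped to [0, 1].

    Used to emulate independent detector noise on each tile of one study.
    """
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    if sd == 0:
        return r
    rng = np.random.default_rng(seed)
    noisy = r.pixels + rng.normal(0.0, sd, size=r.shape)
    return r.with_pixels(np.clip(noisy, 0.0, 1.0))
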