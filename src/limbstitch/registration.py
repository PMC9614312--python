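"""Edge-based translation registration of adjacent radiograph tiles.

Two consecutive exposures of a standing patient differ by a pure translation
(no rotation or scaling: the patient holds still while the X-ray source
travels vertically).  Registration therefore reduces to finding the integer
offset (dx, dy) — dx the column shift of the lower tile relative to the
upper, dy the overlap height in rows — that best superimposes the bone-edge
maps of the two tiles.

Alignment quality of a candidate overlap is scored by the symmetric matching
distance

    A = sum(E1 * D2) / sum(E1)  +  sum(E2 * D1) / sum(E2)

over the two equal-sized overlap strips, where ``E`` are the binary edge
maps and ``D`` the Euclidean distance maps to the nearest edge of the
*other* image.  A is the sum of the two mean edge-to-nearest-opposite-edge
distances: zero exactly when the two overlap edge maps coincide, and growing
with misalignment.  The optimum is found by exhaustively traversing the
whole (dx, dy) search grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .edges import EdgeMap

__all__ = [
    "DistanceMap",
    "SearchWindow",
    "RegistrationResult",
    "distance_map",
    "matching_distance",
    "find_offset",
    "refine_offset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel Euclidean distance to the nearest edge pixel."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=np.float64)
        if d.ndim != 2:
            raise ValueError("distance grid must be 2-D")
        if (d < 0).any() or not np.isfinite(d).all():
            raise ValueError("distances must be finite and nonnegative")
        object.__setattr__(self, "distances", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.distances.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SearchWindow:
    """Inclusive integer ranges of the exhaustive (dx, dy) traversal."""

    dy_min: int
    dy_max: int
    dx_min: int
    dx_max: int

    def __post_init__(self) -> None:
        if self.dy_min < 1 or self.dy_max < self.dy_min:
            raise ValueError("need 1 <= dy_min <= dy_max")
        if self.dx_max < self.dx_min:
            raise ValueError("need dx_min <= dx_max")

    @classmethod
    def default_for(
        cls, upper_shape: tuple[int, int], lower_shape: tuple[int, int]
    ) -> "SearchWindow":
        """Overlap between 10% and 50% of the shorter tile; lateral jitter
        up to 10% of the narrower width."""
        h = min(upper_shape[0], lower_shape[0])
        w = min(upper_shape[1], lower_shape[1])
        dy_min = max(8, int(round(0.10 * h)))
        dy_max = max(dy_min, int(round(0.50 * h)))
        dx = max(1, int(round(0.10 * w)))
        return cls(dy_min=dy_min, dy_max=dy_max, dx_min=-dx, dx_max=dx)


@dataclass(frozen=True)
class RegistrationResult:
    """Optimal translation between two tiles.

    dx: signed column shift of the lower tile relative to the upper;
    dy: overlap height in rows; matching_distance: the A value at the
    optimum; search_evaluations: number of candidates actually scored.
    """

    dx: int
    dy: int
    matching_distance: float
    search_evaluations: int
    refined: bool = False

    def __post_init__(self) -> None:
        if self.dy < 1:
            raise ValueError("dy must be a positive overlap height")
        if self.matching_distance < 0:
            raise ValueError("matching distance must be nonnegative")


class RegistrationError(RuntimeError):
    """No candidate offset could be scored."""


def distance_map(e: EdgeMap) -> DistanceMap:
    """Exact Euclidean distance from every pixel to its nearest edge pixel.

    Undefined (domain error) for an empty edge map: the minimum over an
    empty set of edge locations does not exist.
    """
    if e.is_empty():
        raise ValueError("no edges: distance undefined")
    # EDT measures distance to the zero set, so feed the complement.
    d = ndimage.distance_transform_edt(1 - e.edges)
    return DistanceMap(d)


def matching_distance(
    e1: EdgeMap, d1: DistanceMap, e2: EdgeMap, d2: DistanceMap
) -> float:
    """Symmetric matching distance A between two equal-sized overlap strips.

    Each term averages, over one image's edge pixels, the distance to the
    nearest edge of the other image; A is their sum.  Raises on a shape
    mismatch or an empty edge map (the normalising sums would vanish).
    """
    shapes = {e1.shape, d1.shape, e2.shape, d2.shape}
    if len(shapes) != 1:
        raise ValueError(f"overlap strips must share one shape, got {shapes}")
    if e1.is_empty() or e2.is_empty():
        raise ValueError("matching distance undefined for an empty edge map")
    a1 = float((e1.edges * d2.distances).sum()) / e1.n_edge_pixels
    a2 = float((e2.edges * d1.distances).sum()) / e2.n_edge_pixels
    return a1 + a2


def _strip_views(
    arr_upper: np.ndarray, arr_lower: np.ndarray, dx: int, dy: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Aligned overlap views: bottom dy rows of upper vs top dy rows of lower
    shifted by dx, restricted to their common column span."""
    h1, w1 = arr_upper.shape
    h2, w2 = arr_lower.shape
    # lower column c sits at upper column c + dx
    lo = max(0, dx)
    hi = min(w1, w2 + dx)
    if hi - lo < 1:
        return None
    up = arr_upper[h1 - dy :, lo:hi]
    lw = arr_lower[:dy, lo - dx : hi - dx]
    return up, lw


def _better(
    a: float, dx: int, dy: int, best: tuple[float, int, int] | None
) -> bool:
    """Tie rules: smaller A; then larger dy (more evidence); then smaller
    |dx|; then negative dx before positive."""
    if best is None:
        return True
    a0, dx0, dy0 = best
    if a != a0:
        return a < a0
    if dy != dy0:
        return dy > dy0
    if abs(dx) != abs(dx0):
        return abs(dx) < abs(dx0)
    return dx < dx0


def find_offset(
    e_upper: EdgeMap,
    e_lower: EdgeMap,
    search: SearchWindow | None = None,
    border_margin: int = 4,
) -> RegistrationResult:
    """Exhaustive traversal of the (dx, dy) grid minimising A.

    Distance maps are computed once per full tile and cropped per candidate,
    so each candidate costs only the strip sums; the nearest-edge distances
    therefore refer to the whole tile, not the strip alone.  Candidates whose
    overlap strip carries no edges in either image are skipped.

    ``border_margin`` rows/columns at the rim of each overlap strip are
    excluded from both edge maps when scoring: the rim of a strip coincides
    with a tile border in one image but is interior in the other, so the
    convolution boundary handling (smoothing, Sobel, NMS reach) perturbs
    edges there asymmetrically.  Masking the same rim in both maps keeps the
    cost a comparison of identically-processed pixels — in particular, two
    tiles cut from the same exposure score exactly A = 0 at the true offset.
    """
    if e_upper.is_empty() or e_lower.is_empty():
        raise ValueError("cannot register tiles with empty edge maps")
    search = search or SearchWindow.default_for(e_upper.shape, e_lower.shape)
    dy_cap = min(e_upper.shape[0], e_lower.shape[0])
    if search.dy_min >= dy_cap:
        raise ValueError(
            f"dy search range starts at {search.dy_min} but tiles only have "
            f"{dy_cap} rows"
        )

    d_upper = distance_map(e_upper).distances
    d_lower = distance_map(e_lower).distances
    eu = e_upper.edges.astype(np.float64)
    el = e_lower.edges.astype(np.float64)

    if border_margin < 0:
        raise ValueError("border_margin must be nonnegative")
    m = border_margin

    best: tuple[float, int, int] | None = None
    evaluations = 0
    skipped = 0
    for dy in range(search.dy_min, min(search.dy_max, dy_cap - 1) + 1):
        for dx in range(search.dx_min, search.dx_max + 1):
            views = _strip_views(eu, el, dx, dy)
            if views is None:
                skipped += 1
                continue
            e1s, e2s = views
            if m and (e1s.shape[0] > 2 * m and e1s.shape[1] > 2 * m):
                inner = (slice(m, e1s.shape[0] - m), slice(m, e1s.shape[1] - m))
            else:
                inner = (slice(None), slice(None))
            e1i = e1s[inner]
            e2i = e2s[inner]
            n1 = e1i.sum()
            n2 = e2i.sum()
            if n1 == 0 or n2 == 0:
                skipped += 1
                continue
            d1s, d2s = _strip_views(d_upper, d_lower, dx, dy)  # type: ignore[misc]
            a = (
                float((e1i * d2s[inner]).sum()) / n1
                + float((e2i * d1s[inner]).sum()) / n2
            )
            evaluations += 1
            if _better(a, dx, dy, best):
                best = (a, dx, dy)
    if skipped:
        log.debug("find_offset: skipped %d candidates with empty strips", skipped)
    if best is None:
        raise RegistrationError(
            "all candidate offsets had empty overlap edge maps; "
            "tiles likely share no edge features"
        )
    a, dx, dy = best
    return RegistrationResult(
        dx=dx, dy=dy, matching_distance=a, search_evaluations=evaluations
    )


def refine_offset(
    e_upper: EdgeMap,
    e_lower: EdgeMap,
    coarse: RegistrationResult,
    factor: int,
    border_margin: int = 4,
) -> RegistrationResult:
    """Re-search a +/- ``factor`` window at full resolution around a
    coarse result obtained on ``factor``-times downsampled tiles."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    dy0 = coarse.dy * factor
    dx0 = coarse.dx * factor
    dy_cap = min(e_upper.shape[0], e_lower.shape[0]) - 1
    window = SearchWindow(
        dy_min=max(1, dy0 - factor),
        dy_max=min(dy_cap, dy0 + factor),
        dx_min=dx0 - factor,
        dx_max=dx0 + factor,
    )
    fine = find_offset(e_upper, e_lower, window, border_margin=border_margin)
    return RegistrationResult(
        dx=fine.dx,
        dy=fine.dy,
        matching_distance=fine.matching_distance,
        search_evaluations=coarse.search_evaluations + fine.search_evaluations,
        refined=True,
    )
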