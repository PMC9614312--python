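"""Hip–knee–ankle (HKA) angle geometry and angle-set comparison.

The HKA angle is the clinical yardstick for lower-limb alignment: the angle
at the knee between the femoral mechanical axis (knee -> hip) and the tibial
mechanical axis (knee -> ankle).  A straight leg reads 180 degrees; varus or
valgus deformity shifts it away from 180.  Because the magnitude alone does
not say which side of straight the limb is on, the reported value is
180 plus a signed deviation: the sign of the 2-D cross product of
(knee->hip, knee->ankle) decides between 180 + delta and 180 - delta.
Mirroring the limb about a vertical axis flips the sign, i.e. maps
180 + delta to 180 - delta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["LandmarkTriple", "hka_angle", "compare_angle_sets", "AngleSetComparison"]

Point = tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class LandmarkTriple:
    """Hip, knee and ankle centres in (row, col) canvas coordinates."""

    hip_center: Point
    knee_center: Point
    ankle_center: Point

    def __post_init__(self) -> None:
        pts = [tuple(map(float, p)) for p in
               (self.hip_center, self.knee_center, self.ankle_center)]
        if len({pts[0], pts[1], pts[2]}) != 3:
            raise ValueError("hip, knee and ankle points must be pairwise distinct")
        hip_r, knee_r, ankle_r = pts[0][0], pts[1][0], pts[2][0]
        if not (min(hip_r, ankle_r) < knee_r < max(hip_r, ankle_r)):
            raise ValueError(
                "knee row must lie strictly between hip and ankle rows"
            )
        object.__setattr__(self, "hip_center", pts[0])
        object.__setattr__(self, "knee_center", pts[1])
        object.__setattr__(self, "ankle_center", pts[2])


def hka_angle(lm: LandmarkTriple) -> float:
    """Signed HKA angle in degrees: 180 for a straight leg, 180 + delta or
    180 - delta depending on the side of the deviation.

    delta is the unsigned deviation of the interior knee angle from 180;
    the sign of the cross product of knee->hip and knee->ankle (computed in
    x = col, y = row screen coordinates) picks the side.  The value is
    invariant under translation, rotation and uniform scaling of the triple.
    """
    hip = np.asarray(lm.hip_center, dtype=np.float64)
    knee = np.asarray(lm.knee_center, dtype=np.float64)
    ankle = np.asarray(lm.ankle_center, dtype=np.float64)
    u = hip - knee  # (row, col)
    v = ankle - knee
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length mechanical axis")
    # cross in (x=col, y=row): u_col * v_row - u_row * v_col
    cross = u[1] * v[0] - u[0] * v[1]
    # atan2 keeps the angle well-conditioned near 180 deg, where acos of a
    # clipped cosine loses half the significant digits
    interior = math.degrees(math.atan2(abs(cross), float(np.dot(u, v))))
    delta = 180.0 - interior
    if cross > 0:
        return 180.0 + delta
    if cross < 0:
        return 180.0 - delta
    return 180.0


@dataclass(frozen=True)
class AngleSetComparison:
    """Summary statistics of two HKA angle samples."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    paired: bool
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "paired": self.paired,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def compare_angle_sets(
    a: Sequence[float], b: Sequence[float], paired: bool = True
) -> AngleSetComparison:
    """Compare two sets of HKA angles with a t test.

    Paired mode uses the one-sample t on the differences; unpaired uses
    Welch's two-sample t.  Sample SDs use the n-1 denominator.  A paired
    comparison with zero-variance differences (e.g. identical samples)
    reports t = 0, p = 1 with a warning instead of NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each angle set needs at least two values")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length sets")

    if paired:
        diff = a - b
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                warnings.warn(
                    "identical paired samples: reporting t = 0, p = 1",
                    stacklevel=2,
                )
                t_stat, p = 0.0, 1.0
            else:
                warnings.warn(
                    "constant nonzero paired difference: reporting p = 0",
                    stacklevel=2,
                )
                t_stat, p = math.copysign(math.inf, diff.mean()), 0.0
        else:
            t_stat, p = stats.ttest_rel(a, b)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)

    return AngleSetComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        paired=paired,
        n_a=int(a.size),
        n_b=int(b.size),
    )
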