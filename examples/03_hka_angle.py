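"""Measure the hip-knee-ankle angle and compare two sets of measurements.

The HKA angle is read at the knee between the femoral and tibial mechanical
axes: 180 degrees is a straight leg, and the sign of the deviation encodes
the side (varus vs valgus).
"""

import numpy as np

import limbstitch as ls

# a single measurement from three landmark points (row, col)
lm = ls.LandmarkTriple(hip_center=(86, 415), knee_center=(426, 433),
                       ankle_center=(766, 415))
print(f"HKA angle: {ls.hka_angle(lm):.3f} deg")

# comparing two observers' angle sets, as in a method-vs-expert evaluation
rng = np.random.default_rng(0)
truth = 186.0 + rng.normal(0, 1.1, 28)        # 28 studies
observer_a = truth + rng.normal(0, 0.3, 28)   # small independent reading errors
observer_b = truth + rng.normal(0, 0.3, 28)
res = ls.compare_angle_sets(observer_a, observer_b, paired=True)
print(f"observer A: {res.mean_a:.2f} +/- {res.sd_a:.2f} deg (n={res.n_a})")
print(f"observer B: {res.mean_b:.2f} +/- {res.sd_b:.2f} deg")
print(f"paired t = {res.t_statistic:.3f}, p = {res.p_value:.3f} "
      "(p > 0.05: no significant difference between the two readings)")
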