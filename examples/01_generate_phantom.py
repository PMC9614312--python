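"""Generate a synthetic leg phantom and cut it into three overlapping tiles.

The phantom is a full-length "radiograph" with known geometry: two wavy-width
bone shafts joined at the knee with a programmed varus/valgus deviation, plus
joint masses. Tiling it with known offsets gives ground truth for testing
registration and stitching.
"""

from pathlib import Path

import limbstitch as ls
from limbstitch.pipeline import save_png

out = Path("phantom_demo")
out.mkdir(exist_ok=True)

spec = ls.PhantomSpec.standard(
    canvas_height=852, canvas_width=830, varus_valgus_deg=4.0,
    noise_sd=0.005, seed=7,
)
canvas, truth = ls.generate_phantom(spec)
tiles, truth = ls.tile_phantom(canvas, truth, overlap_12=90, overlap_23=75,
                               dx_12=6, dx_23=-10)

save_png(canvas, out / "full.png")
for tile, name in zip(tiles, ("tile_hip.png", "tile_knee.png", "tile_ankle.png")):
    save_png(tile, out / name)

print(f"canvas: {canvas.shape}, tiles: {[t.shape for t in tiles]}")
print(f"programmed HKA angle: {truth.hka_true_deg:.1f} deg "
      "(180 = straight leg, >180 = deviation toward the lateral side)")
print(f"true offsets  hip-knee: {truth.true_offset_12}  "
      f"knee-ankle: {truth.true_offset_23}  (dx = lateral shift, dy = overlap rows)")
print(f"images written to {out}/")
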