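# Methods

## The stitching problem

A standing full-length lower-limb study is acquired as three overlapping
exposures — hip, knee, ankle — because a flat-panel detector cannot cover
the whole limb. The patient holds still while the X-ray source travels
vertically, so consecutive exposures are related by a pure integer
translation: a vertical overlap of `dy` rows and a small lateral jitter of
`dx` columns. No rotation or scaling is modelled. The pipeline has four
steps: (1) read the three images in hip→knee→ankle order, normalise to
[0, 1] and optionally downsample; (2) extract binary bone-edge maps; (3)
estimate `(dx, dy)` for each adjacent pair by exhaustive search over an
edge-matching cost; (4) fuse the overlap strips in the wavelet domain and
compose the full canvas. The hip–knee–ankle (HKA) angle measured on the
result is the clinical quality metric.

## Edge detection

Edges are the only feature the method uses: cortical bone gives the
strongest, most reproducible gradients in a limb radiograph. The detector
is the classical four-stage composition, implemented stage by stage so each
is testable in isolation:

1. **Smoothing** — normalised 5×5 Gaussian, σ = 1.0 (the natural σ for 5×5
   support; configurable). All convolutions use reflect borders: zero
   padding would create a dark halo at tile edges and spawn false contours.
2. **Gradients** — 3×3 Sobel, magnitude `|g| = hypot(gx, gy)`, direction
   `atan2(gy, gx)`.
3. **Non-maximum suppression** — direction quantised to 4 bins (0°, 45°,
   90°, 135°); a pixel survives iff its magnitude is ≥ both neighbours
   along that axis. The ≥ (not >) rule never discards a genuine maximum;
   duplicated plateau pixels are tolerated downstream.
4. **Hysteresis** — pixels ≥ `high` seed; pixels in `[low, high)` survive
   iff 8-connected to a seed (implemented as connected-component labelling,
   equivalent to flood fill and verified against a BFS oracle).

**Thresholds.** Default mode is *absolute*: `low = 0.08`, `high = 0.2` in
gradient-magnitude units of a [0, 1]-normalised image. Because every input
is normalised on load, absolute thresholds are well-posed, and they are
independent of how much of the frame the anatomy covers. A percentile mode
(`high` = p-th percentile of the nonzero magnitudes, `low` = 0.4·high)
is available for studies whose tile exposures differ too much for one
absolute scale; note its cutoff is content-dependent — on a sparse-edged
frame it slides into the noise floor and admits spurious edges, which is
why it is not the default. An optional brightness mask (exclude pixels
above an intensity quantile from being edges) is off by default.

## Registration

For a candidate `(dx, dy)`, the overlap is the bottom `dy` rows of the
upper tile against the top `dy` rows of the lower tile shifted by `dx`,
restricted to the common column span. With edge maps `E¹, E²` and Euclidean
nearest-edge distance maps `D¹, D²`, the cost is the symmetric matching
distance

    A = Σ E¹·D² / Σ E¹  +  Σ E²·D¹ / Σ E²,

the sum of the two mean edge-to-nearest-opposite-edge distances (pixels).
`A ≥ 0` always, and `A = 0` exactly when the two overlap edge maps
coincide. The whole search grid is traversed exhaustively — default
`dy ∈ [10%, 50%]` of the shorter tile height, `dx ∈ ±10%` of the width,
step 1 — and the argmin returned. Ties prefer larger `dy` (more evidence),
then smaller `|dx|`, then negative `dx`; this makes the search fully
deterministic.

Numerical choices worth knowing:

- **Distance maps are exact** (Euclidean distance transform) and computed
  once per full tile, then cropped per candidate. A candidate therefore
  costs only the strip sums, but the distances refer to the whole tile, not
  the strip alone; for overlap-interior edges the two readings coincide.
- **Strip border margin.** The rim of an overlap strip coincides with a
  tile border in one image but is interior in the other, so the reflect-
  border convolutions perturb the two edge maps asymmetrically within a few
  pixels of the rim. A 4-pixel margin (smoothing reach 2 + Sobel 1 + NMS
  neighbour 1) at the strip rim is masked from *both* edge maps when
  scoring. This keeps the cost a comparison of identically-processed
  pixels; in particular two tiles cut from one exposure score exactly
  `A = 0` at the true offset, which anchors the exact-recovery tests.
- **Degenerate candidates** (no edges in either strip) are skipped; if every
  candidate is skipped, registration fails loudly.
- **Refinement.** When registration runs on downsampled tiles, an optional
  second pass (default on) re-searches a ±factor window at full resolution
  around the scaled coarse optimum.
- **Quality ceiling.** A stitch whose optimal `A` exceeds a configurable
  ceiling (default 2.0 px) is flagged low-confidence in the report — the
  only guard against tiles supplied in the wrong order, which the pipeline
  otherwise trusts.

## Fusion

Each overlap strip exists in two aligned copies. Both are decomposed with a
multilevel 2-D wavelet transform (default Haar, 3 levels; any PyWavelets
family), corresponding coefficients combined convexly per scale,
`W_i = θ·W_i¹ + (1−θ)·W_i²`, and the inverse transform cropped back to the
strip shape and clipped to [0, 1]. θ defaults to a uniform 0.5; with a
uniform θ the linear transform makes the blend identical (to float
precision) to a per-pixel convex combination, for every offered family —
a property the tests exploit. A per-scale θ (one weight for the
approximation band plus one per detail scale, coarsest first) lets the
fusion favour the sharper exposure at fine scales. Strips too small for
the configured depth are blended at the deepest supported level, down to a
plain pixel combination. Symmetric extension handles arbitrary strip sizes.

The canvas is the union of the shifted tile extents: rows outside the
overlaps are copied verbatim from their source tile, overlap rows are
replaced by the blended strip over the common column span, and pixels
outside every tile stay zero and are reported as padding (never cropped, so
no anatomy is lost). The height identity
`H = h₁ + h₂ + h₃ − dy₁₂ − dy₂₃` holds by construction and is recorded in
the stitch report, along with both offsets, both A values, the blend
settings and any warnings. Reports contain no timestamps, so identical
inputs and config reproduce byte-identical files.

## HKA angle

The angle at the knee between the femoral axis (knee→hip) and the tibial
axis (knee→ankle), reported as 180 plus a signed deviation: the sign of the
2-D cross product of the two axis vectors decides between `180 + δ` and
`180 − δ`, so a straight leg reads exactly 180° and mirroring the limb
about a vertical axis flips the side. The interior angle is computed as
`atan2(|u×v|, u·v)`, which stays well-conditioned near 180° (an
acos-of-cosine formulation loses half its digits exactly where clinical
legs live). The angle is invariant under translation, rotation and uniform
scaling of the landmark triple. Landmarks are supplied by the user or by
phantom ground truth; there is no automated landmark detector.

Angle sets are compared with a paired t test (or Welch's unpaired t), with
sample SDs on n−1. Two conventions for degenerate paired data: identical
samples report t = 0, p = 1 (not NaN); a constant nonzero difference
reports p = 0, since claiming "no difference" for a systematic offset would
be wrong.

## The phantom generator

The generator emulates what the method needs from a limb radiograph, not
radiographic physics. Two bone shafts meet at the knee with a programmed
varus/valgus deviation (the femoral and tibial segments are each tilted by
half the deviation, so the truth HKA is exactly `180 + δ`); the silhouette
is brighter (0.80) than the soft-tissue background (0.25) with a 3-pixel
smoothstep ramp at the outline so a gradient detector localises a single
clean contour. Joint masses (femoral head, two condyles, a talar dome) are
discs attached to the shaft ends.

The cortical halfwidth ripples gently along each shaft (two incommensurate
wavelengths, 47 and 89 px, amplitudes 8% and 5%, fixed phases per bone).
This matters: a constant-width shaft is self-similar under vertical
translation — its two parallel edges match at *any* overlap — so exact
offset recovery would be ill-posed. The ripple gives the contour
longitudinal structure that makes the true offset the unique zero of the
matching distance. Low-amplitude smoothed background texture (2% of range)
and optional additive Gaussian noise complete the image; everything is
deterministic given the spec and seed. An optional ruler strip with
periodic ticks can be rendered for qualitative demonstrations; the
algorithm never uses it.

Tiling cuts the canvas at thirds, extends tile 1 and tile 2 by the
requested overlaps, and realises lateral shifts by cropping laterally
shifted windows of common width — so adjacent tiles share bit-identical
anatomy at the recorded offset, the property the registration tests lean
on.

**What the phantom does not emulate:** projection geometry and
magnification, scatter, heel effect, exposure differences between tiles,
trabecular texture, implants or pathology, and soft-tissue contours.
Passing phantom tests therefore demonstrates the geometric and numerical
correctness of the pipeline under its stated assumptions (pure translation,
edge-dominated content), not clinical performance on hospital images.

## Default parameters and study sizes

| parameter | default | notes |
|---|---|---|
| downsample factor | 1 | block mean; 4 maps a 3408×3320 study to 852×830 |
| Gaussian σ / support | 1.0 / 5×5 | smoothing before gradients |
| Canny low / high | 0.08 / 0.2 | absolute, gradient units on [0, 1] images |
| search dy | 10–50% of tile height | step 1, exhaustive |
| search dx | ±10% of width | step 1 |
| strip border margin | 4 px | masked from both maps when scoring |
| quality ceiling on A | 2.0 px | above ⇒ low-confidence warning |
| wavelet / levels / θ | haar / 3 / 0.5 | uniform θ ≡ pixel-domain blend |
| phantom canvas | 852×830 | validation sweeps use 420×160 |
| validation conditions | δ ∈ ±10°, dy ∈ [40, 120], dx ∈ ±10, noise sd 0.01 | 100 trials per sweep |

Validation and acceptance sweeps run on 420×160-pixel phantoms
(proportionate to the default canvas, with bone halfwidth 16 px and search
window dy ∈ [30, 126], dx ∈ ±12) so that a 100-trial sweep of the full
pipeline completes in about a minute.

## Known limitations

- Pure translation only; a patient who rotates between exposures violates
  the model and will register poorly (flagged via the quality ceiling at
  best).
- The matching distance reads nearest-edge distances from the whole tile
  rather than the strip alone (a deliberate efficiency choice); for edge
  sets dense near the strip this is indistinguishable, but sparse exotic
  inputs can score slightly differently than a strictly strip-local cost.
- Percentile thresholds are content-dependent (see above); the absolute
  defaults assume [0, 1]-normalised radiographs with ordinary contrast.
- No intensity harmonisation between tiles; exposure steps across a seam
  are blended, not corrected.
- No automated landmark detection; HKA accuracy through the pipeline is
  measured by mapping ground-truth landmarks through the recovered
  placements.
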