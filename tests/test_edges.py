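import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import limbstitch as ls
from limbstitch import Radiograph
from limbstitch.edges import (
    CannyConfig,
    EdgeMap,
    canny,
    hysteresis_threshold,
    non_maximum_suppression,
    sobel_gradients,
)
from limbstitch.phantom import bone_field


def _manual_sobel(px):
    """Independent Sobel oracle: explicit loops with reflect padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    ky = kx.T
    padded = np.pad(px, 1, mode="symmetric")  # scipy 'reflect' == np 'symmetric'
    h, w = px.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            gx[i, j] = (win * kx).sum()
            gy[i, j] = (win * ky).sum()
    return np.hypot(gx, gy)


class TestSobel:
    def test_constant_image_has_zero_gradient(self):
        mag, _ = sobel_gradients(Radiograph(np.full((10, 10), 0.3)))
        assert np.all(mag < 1e-15)

    def test_vertical_step_gives_horizontal_gradient(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 1.0
        mag, direction = sobel_gradients(Radiograph(px))
        step_cols = mag[:, 4:6]
        assert np.all(step_cols == mag.max())
        # gradient points along +x: direction ~ 0 on the step columns
        assert np.allclose(np.abs(direction[:, 4:6]), 0.0, atol=1e-12)

    def test_matches_manual_convolution_oracle(self, rng):
        px = rng.random((8, 9))
        mag, _ = sobel_gradients(Radiograph(px))
        np.testing.assert_allclose(mag, _manual_sobel(px), atol=1e-12)


class TestNonMaximumSuppression:
    def test_single_pixel_ridge_survives(self):
        mag = np.zeros((9, 9))
        mag[:, 4] = 1.0  # vertical ridge, horizontal gradient
        direction = np.zeros((9, 9))  # 0 rad -> compare left/right
        out = non_maximum_suppression(mag, direction)
        np.testing.assert_array_equal(out, mag)

    def test_plateau_kept_by_ge_rule(self):
        # 3-wide plateau perpendicular to the gradient: the >= rule keeps
        # every plateau column (none is strictly below a neighbour).
        mag = np.zeros((5, 9))
        mag[:, 3:6] = 1.0
        out = non_maximum_suppression(mag, np.zeros((5, 9)))
        np.testing.assert_array_equal(out, mag)

    def test_monotone_slope_is_thinned(self):
        mag = np.tile(np.array([0.1, 0.5, 1.0, 0.5, 0.1]), (5, 1))
        out = non_maximum_suppression(mag, np.zeros((5, 5)))
        assert np.all(out[:, 2] == 1.0)
        assert np.all(out[:, [0, 1, 3]] == 0)  # col 4 borders zero padding

    def test_output_supported_on_input(self, rng):
        mag = rng.random((12, 12))
        direction = rng.uniform(-np.pi, np.pi, (12, 12))
        out = non_maximum_suppression(mag, direction)
        assert np.all((out == 0) | (out == mag))

    def test_zero_input_zero_output(self):
        out = non_maximum_suppression(np.zeros((6, 6)), np.zeros((6, 6)))
        assert np.all(out == 0)


def _bfs_hysteresis(grid, low, high):
    """Flood-fill oracle: BFS from every strong pixel over 8-neighbours."""
    h, w = grid.shape
    keep = np.zeros((h, w), dtype=bool)
    stack = [(i, j) for i in range(h) for j in range(w) if grid[i, j] >= high]
    for i, j in stack:
        keep[i, j] = True
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < h and 0 <= nj < w
                    and not keep[ni, nj] and grid[ni, nj] >= low
                ):
                    keep[ni, nj] = True
                    stack.append((ni, nj))
    return keep.astype(np.uint8)


class TestHysteresis:
    def test_all_strong_keeps_everything(self):
        out = hysteresis_threshold(np.ones((5, 5)), 0.2, 0.5)
        assert np.all(out.edges == 1)

    def test_weak_kept_only_when_linked_to_strong(self):
        grid = np.zeros((7, 7))
        grid[3, 3] = 1.0   # strong
        grid[2, 2] = 0.3   # weak, 8-adjacent to strong
        grid[6, 6] = 0.3   # weak, isolated
        out = hysteresis_threshold(grid, 0.2, 0.5)
        assert out.edges[2, 2] == 1
        assert out.edges[3, 3] == 1
        assert out.edges[6, 6] == 0
        assert out.n_edge_pixels == 2

    def test_low_above_high_rejected(self):
        with pytest.raises(ValueError):
            hysteresis_threshold(np.zeros((5, 5)), 0.9, 0.1)

    @given(st.integers(0, 10_000))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((12, 12))
        out = hysteresis_threshold(grid, 0.5, 0.8)
        np.testing.assert_array_equal(out.edges, _bfs_hysteresis(grid, 0.5, 0.8))


class TestEdgeMapInvariants:
    def test_nonbinary_grid_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            EdgeMap(np.full((4, 4), 0.5))

    def test_bad_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            EdgeMap(np.zeros((4, 4)), low_threshold=2.0, high_threshold=1.0)


class TestCanny:
    def test_constant_image_yields_empty_map(self, caplog):
        with caplog.at_level(logging.WARNING, logger="limbstitch.edges"):
            e = canny(Radiograph(np.full((16, 16), 0.7)))
        assert e.is_empty()
        assert any("zero gradient" in r.message for r in caplog.records)

    def test_phantom_contour_hugs_analytic_outline(self):
        spec = ls.PhantomSpec.standard(
            canvas_height=200, canvas_width=120, bone_halfwidth=14.0,
            varus_valgus_deg=0.0, limb_fraction=0.6,
        )
        canvas, _ = ls.generate_phantom(spec)
        e = canny(canvas)
        assert e.n_edge_pixels > 100
        rr, cc = np.nonzero(e.edges)
        # the field is ~signed distance to the outline (|grad| ~ 1)
        f = bone_field(spec, rr.astype(float), cc.astype(float))
        assert np.abs(f).max() <= 2.0

    def test_raising_high_threshold_never_adds_edges(self, noiseless_study):
        _, tiles, _ = noiseless_study
        counts = []
        for high in (0.15, 0.3, 0.6, 1.0):
            cfg = CannyConfig(low_abs=0.08, high_abs=high)
            counts.append(canny(tiles[0], cfg).n_edge_pixels)
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 0

    def test_percentile_mode_resolves_thresholds(self, noiseless_study):
        _, tiles, _ = noiseless_study
        cfg = CannyConfig(threshold_mode="percentile", high_percentile=99.0)
        e = canny(tiles[0], cfg)
        assert e.high_threshold > e.low_threshold > 0
        assert e.n_edge_pixels > 0

    def test_bright_mask_removes_bright_edges(self, noiseless_study):
        _, tiles, _ = noiseless_study
        plain = canny(tiles[0])
        masked = canny(tiles[0], CannyConfig(bright_mask_quantile=0.5))
        assert masked.n_edge_pixels < plain.n_edge_pixels

    def test_step_edge_is_one_pixel_wide(self):
        px = np.zeros((20, 20))
        px[:, 10:] = 1.0
        e = canny(Radiograph(px))
        widths = e.edges.sum(axis=1)
        assert np.all(widths == 1)
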