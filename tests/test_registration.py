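import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import limbstitch as ls
from limbstitch.edges import EdgeMap
from limbstitch.registration import (
    DistanceMap,
    RegistrationError,
    SearchWindow,
    _strip_views,
    distance_map,
    find_offset,
    matching_distance,
)

from conftest import SEARCH, make_tiled_phantom


def _random_edge_map(rng, shape=(32, 32), p=0.05):
    e = (rng.random(shape) < p).astype(np.uint8)
    if e.sum() == 0:
        e[shape[0] // 2, shape[1] // 2] = 1
    return EdgeMap(e)


def _brute_force_distance(edges):
    """All-pairs nearest-edge oracle."""
    h, w = edges.shape
    pts = np.argwhere(edges == 1)
    grid = np.argwhere(np.ones((h, w), dtype=bool))
    return cdist(grid, pts).min(axis=1).reshape(h, w)


class TestDistanceMap:
    def test_zero_at_edges_and_345_triangle(self):
        e = np.zeros((8, 8), dtype=np.uint8)
        e[0, 0] = 1
        d = distance_map(EdgeMap(e)).distances
        assert d[0, 0] == 0.0
        assert d[3, 4] == pytest.approx(5.0, abs=1e-12)

    def test_empty_edge_map_is_domain_error(self):
        with pytest.raises(ValueError, match="no edges"):
            distance_map(EdgeMap(np.zeros((8, 8), dtype=np.uint8)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            e = _random_edge_map(rng)
            d = distance_map(e).distances
            np.testing.assert_allclose(
                d, _brute_force_distance(e.edges), atol=1e-9
            )

    def test_lipschitz_under_euclidean_metric(self, rng):
        e = _random_edge_map(rng, p=0.02)
        d = distance_map(e).distances
        h, w = d.shape
        p = rng.integers(0, [h, w], size=(10_000, 2))
        q = rng.integers(0, [h, w], size=(10_000, 2))
        gaps = np.abs(d[p[:, 0], p[:, 1]] - d[q[:, 0], q[:, 1]])
        dist = np.hypot(*(p - q).T)
        assert np.all(gaps <= dist + 1e-9)


class TestMatchingDistance:
    def test_identical_nonempty_maps_score_zero(self, rng):
        e = _random_edge_map(rng, (16, 16), p=0.1)
        d = distance_map(e)
        assert matching_distance(e, d, e, d) == 0.0

    def test_worked_three_by_three_corner_case(self):
        e1 = np.zeros((3, 3), dtype=np.uint8)
        e2 = np.zeros((3, 3), dtype=np.uint8)
        e1[0, 0] = 1
        e2[2, 2] = 1
        a = matching_distance(
            EdgeMap(e1), distance_map(EdgeMap(e1)),
            EdgeMap(e2), distance_map(EdgeMap(e2)),
        )
        assert a == pytest.approx(2 * math.sqrt(8), abs=1e-9)

    def test_matches_literal_formula_oracle(self, rng):
        for _ in range(200):
            e1 = _random_edge_map(rng, (10, 12), p=0.1)
            e2 = _random_edge_map(rng, (10, 12), p=0.1)
            d1, d2 = distance_map(e1), distance_map(e2)
            got = matching_distance(e1, d1, e2, d2)
            # literal per-pixel evaluation of the formula
            num1 = sum(
                d2.distances[i, j]
                for i in range(10) for j in range(12) if e1.edges[i, j]
            )
            num2 = sum(
                d1.distances[i, j]
                for i in range(10) for j in range(12) if e2.edges[i, j]
            )
            want = num1 / e1.n_edge_pixels + num2 / e2.n_edge_pixels
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_its_arguments(self, rng):
        e1 = _random_edge_map(rng, (9, 9), p=0.15)
        e2 = _random_edge_map(rng, (9, 9), p=0.15)
        d1, d2 = distance_map(e1), distance_map(e2)
        assert matching_distance(e1, d1, e2, d2) == pytest.approx(
            matching_distance(e2, d2, e1, d1), abs=1e-12
        )

    def test_empty_map_and_shape_mismatch_rejected(self, rng):
        e = _random_edge_map(rng, (6, 6))
        d = distance_map(e)
        empty = EdgeMap(np.zeros((6, 6), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            matching_distance(e, d, empty, d)
        other = _random_edge_map(rng, (7, 6))
        with pytest.raises(ValueError, match="shape"):
            matching_distance(e, d, other, distance_map(other))


class TestSearchWindow:
    def test_default_fractions(self):
        w = SearchWindow.default_for((300, 200), (260, 200))
        assert w.dy_min == 26 and w.dy_max == 130
        assert w.dx_min == -20 and w.dx_max == 20

    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            SearchWindow(dy_min=0, dy_max=5, dx_min=0, dx_max=0)
        with pytest.raises(ValueError):
            SearchWindow(dy_min=5, dy_max=4, dx_min=0, dx_max=0)


class TestFindOffset:
    def test_recovers_truth_exactly_on_noiseless_phantom(self, noiseless_study):
        _, tiles, truth = noiseless_study
        e = [ls.canny(t) for t in tiles]
        r12 = find_offset(e[0], e[1], SEARCH)
        assert (r12.dx, r12.dy) == truth.true_offset_12
        assert r12.matching_distance == 0.0
        r23 = find_offset(e[1], e[2], SEARCH)
        assert (r23.dx, r23.dy) == truth.true_offset_23
        assert r23.matching_distance == 0.0
        assert r12.search_evaluations > 1000

    def test_exhaustive_optimality_against_direct_scoring(self):
        # oracle: score every candidate via matching_distance on cropped maps
        _, tiles, _ = make_tiled_phantom(seed=11, vv=3.0, ov12=50, ov23=50)
        e_up, e_lo = ls.canny(tiles[0]), ls.canny(tiles[1])
        window = SearchWindow(dy_min=40, dy_max=60, dx_min=-3, dx_max=3)
        res = find_offset(e_up, e_lo, window, border_margin=0)
        du = distance_map(e_up).distances
        dl = distance_map(e_lo).distances
        for dy in range(window.dy_min, window.dy_max + 1):
            for dx in range(window.dx_min, window.dx_max + 1):
                e1s, e2s = _strip_views(
                    e_up.edges.astype(float), e_lo.edges.astype(float), dx, dy
                )
                if e1s.sum() == 0 or e2s.sum() == 0:
                    continue
                d1s, d2s = _strip_views(du, dl, dx, dy)
                a = matching_distance(
                    EdgeMap(e1s.astype(np.uint8)), DistanceMap(d1s),
                    EdgeMap(e2s.astype(np.uint8)), DistanceMap(d2s),
                )
                assert res.matching_distance <= a + 1e-12

    def test_restricted_range_returns_inrange_minimiser(self):
        _, tiles, truth = make_tiled_phantom(seed=5, vv=2.0, ov12=90, ov23=60)
        e_up, e_lo = ls.canny(tiles[0]), ls.canny(tiles[1])
        window = SearchWindow(dy_min=30, dy_max=60, dx_min=-3, dx_max=3)  # truth dy=90
        res = find_offset(e_up, e_lo, window)
        assert 30 <= res.dy <= 60
        assert res.matching_distance > 0.0

    def test_empty_edge_maps_rejected(self):
        empty = EdgeMap(np.zeros((40, 40), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            find_offset(empty, empty)

    def test_all_candidates_skipped_raises(self):
        # edges confined to the top rows: every candidate strip of the
        # upper tile is empty
        e1 = np.zeros((60, 40), dtype=np.uint8)
        e1[0, :] = 1
        e2 = np.zeros((60, 40), dtype=np.uint8)
        e2[0, :] = 1
        window = SearchWindow(dy_min=8, dy_max=20, dx_min=0, dx_max=0)
        with pytest.raises(RegistrationError):
            find_offset(EdgeMap(e1), EdgeMap(e2), window)

    @given(st.integers(0, 200))
    def test_self_registration_recovers_constructed_offset(self, seed):
        # cut two overlapping windows from one edge pattern
        rng = np.random.default_rng(seed)
        canvas = (rng.random((120, 50)) < 0.03).astype(np.uint8)
        canvas[0, 0] = 1  # ensure non-empty
        upper = EdgeMap(canvas[:70])
        lower = EdgeMap(canvas[50:])
        window = SearchWindow(dy_min=8, dy_max=35, dx_min=-4, dx_max=4)
        res = find_offset(upper, lower, window, border_margin=0)
        assert (res.dx, res.dy) == (0, 20)
        assert res.matching_distance == 0.0
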