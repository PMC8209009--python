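"""Unit and property tests for the SMLM spatial statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanodomain as nd
from nanodomain.errors import StructuralError
from nanodomain.spatial import _isotropic_weight, expected_pair_counts

from oracles import (
    brute_cross_pair_counts,
    brute_neighbor_counts,
    brute_ripley_k,
)


def table(x, y, **kw):
    return nd.LocalizationTable.from_arrays(x, y, **kw)


class TestNeighborDensity:
    def test_single_point_has_no_neighbors(self, square_window):
        res = nd.neighbor_density(table([100.0], [100.0]), square_window, 100.0)
        assert res.per_point_counts.tolist() == [0]

    def test_threshold_crossing_at_pair_distance(self, square_window):
        pts = table([1000.0, 1050.0], [1000.0, 1000.0])  # 50 nm apart
        assert nd.neighbor_density(pts, square_window, 100.0).per_point_counts.tolist() == [1, 1]
        assert nd.neighbor_density(pts, square_window, 40.0).per_point_counts.tolist() == [0, 0]

    def test_histogram_frequencies_sum_to_n(self, square_window, rng):
        pts = table(rng.uniform(0, 3000, 500), rng.uniform(0, 3000, 500))
        res = nd.neighbor_density(pts, square_window, 100.0)
        assert res.histogram["frequency"].sum() == 500

    def test_matches_brute_force_exactly(self, square_window, rng):
        n = 1000
        pts = table(rng.uniform(0, 3000, n), rng.uniform(0, 3000, n))
        res = nd.neighbor_density(pts, square_window, 100.0)
        expected = brute_neighbor_counts(pts.coords(), 100.0)
        np.testing.assert_array_equal(res.per_point_counts, expected)

    def test_csr_mean_near_lambda_pi_r2(self, square_window, rng):
        lam = 1000 / (3000.0 * 3000.0)
        pts = table(rng.uniform(0, 3000, 1000), rng.uniform(0, 3000, 1000))
        res = nd.neighbor_density(pts, square_window, 100.0)
        # interior points only, to avoid edge deficit
        xy = pts.coords()
        interior = ((xy > 100) & (xy < 2900)).all(axis=1)
        mean = res.per_point_counts[interior].mean()
        assert mean == pytest.approx(lam * np.pi * 100 ** 2, rel=0.25)

    def test_empty_table_warns_and_returns_empty(self, square_window):
        res = nd.neighbor_density(table([], []), square_window, 100.0)
        assert len(res.per_point_counts) == 0


class TestRipleyK:
    def test_central_pair_k_equals_area(self, square_window):
        # two central points at 100 nm: w = 1, K jumps to A at r >= d
        pts = table([1450.0, 1550.0], [1500.0, 1500.0])
        res = nd.ripley_k(pts, square_window, [50.0, 100.0, 150.0])
        assert res.k_values[0] == 0.0
        assert res.k_values[1] == pytest.approx(square_window.area)
        assert res.k_values[2] == pytest.approx(square_window.area)

    @pytest.mark.parametrize("correction", ["isotropic", "translation", "none"])
    def test_matches_brute_force(self, square_window, rng, correction):
        n = 300
        pts = table(rng.uniform(0, 3000, n), rng.uniform(0, 3000, n))
        r = np.arange(25.0, 525.0, 25.0)
        res = nd.ripley_k(pts, square_window, r, correction)
        expected = brute_ripley_k(pts.coords(), 3000.0, 3000.0, r, correction)
        np.testing.assert_allclose(res.k_values, expected, rtol=1e-10)

    def test_r_grid_validation(self, square_window):
        pts = table([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(StructuralError):
            nd.ripley_k(pts, square_window, [100.0, 50.0])
        with pytest.raises(StructuralError):
            nd.ripley_k(pts, square_window, [100.0, 2000.0])  # > min(W,H)/2
        with pytest.raises(StructuralError):
            nd.ripley_k(pts, square_window, [100.0], edge_correction="bogus")

    def test_k_nonnegative_nondecreasing(self, square_window, rng):
        pts = table(rng.uniform(0, 3000, 400), rng.uniform(0, 3000, 400))
        res = nd.ripley_k(pts, square_window, np.arange(10.0, 510.0, 10.0))
        assert np.all(res.k_values >= 0)
        assert np.all(np.diff(res.k_values) >= 0)
        np.testing.assert_allclose(res.l_values, np.sqrt(res.k_values / np.pi))
        np.testing.assert_allclose(res.h_values, res.l_values - res.r_grid)

    def test_isotropic_weight_is_one_deep_inside(self, square_window):
        w = _isotropic_weight(np.array([[1500.0, 1500.0]]), np.array([100.0]),
                              square_window)
        assert w[0] == pytest.approx(1.0)

    def test_isotropic_weight_corner_quarter_circle(self):
        # circle centred exactly on a corner: 3/4 outside -> weight 4
        win = nd.AnalysisWindow(1000.0, 1000.0)
        w = _isotropic_weight(np.array([[0.0, 0.0]]), np.array([50.0]), win)
        assert w[0] == pytest.approx(4.0)


class TestRmax:
    def test_symmetric_peak(self):
        res = nd.RipleyResult(np.array([50.0, 100.0, 150.0, 200.0, 250.0]),
                              np.zeros(5), np.zeros(5),
                              np.array([0.0, 1.0, 0.0, -1.0, -2.0]),
                              "isotropic", 10)
        assert nd.estimate_rmax(res) == pytest.approx(100.0)
        assert not res.r_max_at_boundary

    def test_tie_breaks_toward_smaller_r(self):
        # H = (0, 1, 1, 0, -1): first tied max at r=100; parabola through
        # (50,0),(100,1),(150,1) has vertex at r = 125 (hand computation)
        res = nd.RipleyResult(np.array([50.0, 100.0, 150.0, 200.0, 250.0]),
                              np.zeros(5), np.zeros(5),
                              np.array([0.0, 1.0, 1.0, 0.0, -1.0]),
                              "isotropic", 10)
        assert nd.estimate_rmax(res) == pytest.approx(125.0)

    def test_monotone_h_flags_boundary(self):
        res = nd.RipleyResult(np.arange(5, 55, 10.0), np.zeros(5), np.zeros(5),
                              np.arange(5.0), "isotropic", 10)
        assert nd.estimate_rmax(res) == pytest.approx(45.0)
        assert res.r_max_at_boundary


class TestCrossCorrelation:
    def test_identical_channels_first_bin_dominates(self, square_window, rng):
        truth = nd.PatternTruth(process="thomas", kappa_per_um2=30, mu=10, sigma_nm=20)
        a, _ = nd.simulate_point_pattern(truth, square_window, rng=rng)
        res = nd.cross_correlation(a, a, square_window, np.arange(0, 510, 10.0))
        assert res.c_values[0] > 10
        assert res.c_values[0] > res.c_values[5] > res.c_values[-1] * 0.5

    def test_pair_counts_match_brute_force_exactly(self, square_window, rng):
        a = table(rng.uniform(0, 3000, 400), rng.uniform(0, 3000, 400))
        b = table(rng.uniform(0, 3000, 300), rng.uniform(0, 3000, 300))
        edges = np.arange(0, 510, 10.0)
        res = nd.cross_correlation(a, b, square_window, edges)
        expected = brute_cross_pair_counts(a.coords(), b.coords(), edges)
        np.testing.assert_array_equal(res.n_pairs_per_bin, expected)

    def test_symmetric_under_channel_swap(self, square_window, rng):
        a = table(rng.uniform(0, 3000, 200), rng.uniform(0, 3000, 200))
        b = table(rng.uniform(0, 3000, 250), rng.uniform(0, 3000, 250))
        edges = np.arange(0, 310, 10.0)
        c_ab = nd.cross_correlation(a, b, square_window, edges).c_values
        c_ba = nd.cross_correlation(b, a, square_window, edges).c_values
        np.testing.assert_allclose(c_ab, c_ba, rtol=1e-12)

    def test_expected_counts_integrate_window_geometry(self, square_window):
        # over the whole feasible range the expectation must not exceed n_a*n_b
        edges = np.array([0.0, 3000.0])
        exp = expected_pair_counts(100, 100, square_window, edges)
        assert 0 < exp[0] < 100 * 100

    def test_empty_channel_rejected(self, square_window):
        a = table([1.0], [1.0])
        with pytest.raises(StructuralError):
            nd.cross_correlation(a, table([], []), square_window, [0.0, 10.0])


class TestTiling:
    def test_exact_tiling(self):
        win = nd.AnalysisWindow(9000.0, 9000.0)
        tiles = nd.tile_windows(table([], []), win, 3000.0, min_points=0)
        assert len(tiles) == 9

    def test_floor_rule_discards_margins(self):
        win = nd.AnalysisWindow(10000.0, 10000.0)
        tiles = nd.tile_windows(table([], []), win, 3000.0, min_points=0)
        assert len(tiles) == 9

    def test_half_open_boundary_assignment(self):
        win = nd.AnalysisWindow(9000.0, 9000.0)
        pts = table([3000.0], [0.0])
        tiles = nd.tile_windows(pts, win, 3000.0, min_points=1)
        assert len(tiles) == 1
        tile_win, sub = tiles[0]
        assert tile_win.origin_x == 3000.0 and tile_win.origin_y == 0.0
        assert len(sub) == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 8999.99), st.floats(0, 8999.99)),
                    min_size=1, max_size=30))
    def test_every_interior_point_lands_in_exactly_one_tile(self, pts):
        win = nd.AnalysisWindow(9000.0, 9000.0)
        t = table([p[0] for p in pts], [p[1] for p in pts])
        tiles = nd.tile_windows(t, win, 3000.0, min_points=0)
        total = sum(len(sub) for _, sub in tiles)
        assert total == len(pts)


class TestBlinkingMerge:
    def test_merges_repeated_localizations(self, square_window, rng):
        truth = nd.PatternTruth(process="csr", intensity_per_um2=30,
                                blinking_mean=4.0, precision_nm=10.0)
        tab, rec = nd.simulate_point_pattern(truth, square_window, rng=rng)
        merged = nd.merge_blinking(tab, radius=50.0, max_frame_gap=3)
        # merged molecule count near the underlying molecule count
        underlying = rec["n_points"] / 4.0
        assert len(merged) < len(tab)
        assert len(merged) == pytest.approx(underlying, rel=0.35)

    def test_blinking_inflates_k_and_merge_restores(self, square_window, rng):
        blink = nd.PatternTruth(process="csr", intensity_per_um2=100,
                                blinking_mean=3.0, precision_nm=10.0)
        r = np.arange(10.0, 210.0, 10.0)
        ratios_raw, ratios_merged = [], []
        for s in range(5):
            tab, _ = nd.simulate_point_pattern(blink, square_window, seed=900 + s)
            k_raw = nd.ripley_k(tab, square_window, r).k_values
            merged = nd.merge_blinking(tab, radius=40.0, max_frame_gap=3)
            k_merged = nd.ripley_k(merged, square_window, r).k_values
            csr = np.pi * r ** 2
            ratios_raw.append(k_raw[2] / csr[2])
            ratios_merged.append(k_merged[2] / csr[2])
        assert np.mean(ratios_raw) > 1.5  # duplicates inflate K at small r
        assert np.mean(ratios_merged) == pytest.approx(1.0, abs=0.1)
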