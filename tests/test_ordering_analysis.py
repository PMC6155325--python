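"""Detection, pairing, angle histogram and the order parameter with its null."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from spraydep.ordering_analysis import (
    BIN_CENTERS,
    AngleHistogram,
    MaximaSet,
    PairSet,
    angle_histogram,
    combine_order,
    detect_maxima,
    nearest_neighbor_pairs,
    order_p_value,
    order_parameter,
    pairs_from_points,
)
from spraydep.synthetic_afm import AFMMap, ParticleField, render_height_map


def _hist(counts):
    return AngleHistogram(counts=np.asarray(counts), bin_centers=BIN_CENTERS)


class TestDetectMaxima:
    def test_all_zero_map_gives_empty_set(self):
        afm = AFMMap(np.zeros((50, 50)), pixel_size=4.0)
        assert detect_maxima(afm, threshold=0.1, noise_tolerance=0.05).n == 0

    def test_single_bump_gives_one_maximum_at_apex(self):
        field = ParticleField(np.array([[100.0, 100.0]]), [1.0], [8.0], (200.0, 200.0))
        afm = render_height_map(field, 2.0)
        maxima = detect_maxima(afm, threshold=0.2, noise_tolerance=0.1)
        assert maxima.n == 1
        np.testing.assert_allclose(maxima.positions[0] * 2.0, [100.0, 100.0], atol=2.0)
        assert maxima.heights[0] == pytest.approx(1.0, abs=0.05)

    def test_subthreshold_bump_is_rejected(self):
        """Amplitudes 1.0 and 0.15 with threshold 0.2: only one survives."""
        field = ParticleField(
            np.array([[60.0, 100.0], [140.0, 100.0]]), [1.0, 0.15], [8.0, 8.0], (200.0, 200.0)
        )
        afm = render_height_map(field, 2.0)
        maxima = detect_maxima(afm, threshold=0.2, noise_tolerance=0.1)
        assert maxima.n == 1
        assert maxima.positions[0][0] * 2.0 == pytest.approx(60.0, abs=2.0)

    def test_map_smaller_than_filter_rejected(self):
        afm = AFMMap(np.zeros((2, 2)), pixel_size=1.0)
        with pytest.raises(ValueError, match="filter"):
            detect_maxima(afm, median_filter_size=3)

    def test_default_tolerance_suppresses_noise_peaks(self):
        rng = np.random.default_rng(0)
        afm = AFMMap(rng.normal(0, 0.05, (100, 100)), pixel_size=4.0)
        maxima = detect_maxima(afm)  # 3x robust-noise defaults
        assert maxima.n <= 5


class TestNearestNeighborPairs:
    def test_two_interior_points_one_pair(self):
        maxima = MaximaSet(np.array([[40.0, 50.0], [60.0, 50.0]]), [1, 1], (100, 100))
        pairs = nearest_neighbor_pairs(maxima, pixel_size=1.0)
        assert pairs.n == 1
        np.testing.assert_allclose(np.abs(pairs.vectors[0]), [20.0, 0.0])

    def test_collinear_points_tie_broken_by_lowest_index(self):
        """x = 10, 20, 30: pairs (0,1) and (1,2); the middle point ties to 0."""
        pts = np.array([[10.0, 50.0], [20.0, 50.0], [30.0, 50.0]])
        pairs = pairs_from_points(pts, (100.0, 100.0))
        keys = {tuple(k) for k in pairs.indices}
        assert keys == {(0, 1), (1, 2)}

    def test_border_pair_discarded(self):
        """A point 5 nm from the border with its NN 10 nm away is dropped."""
        pts = np.array([[5.0, 50.0], [15.0, 50.0]])
        pairs = pairs_from_points(pts, (100.0, 100.0))
        assert pairs.n == 0
        assert pairs.n_discarded_border == 1

    def test_pair_judged_once_at_first_encounter(self):
        # pair (0,1) is first found from centre 0 (5 nm from the border, NN
        # 10 nm away: discarded) and is not re-examined from centre 1
        pts = np.array([[5.0, 50.0], [15.0, 50.0], [50.0, 50.0]])
        pairs = pairs_from_points(pts, (100.0, 100.0))
        keys = {tuple(k) for k in pairs.indices}
        assert (0, 1) not in keys
        assert keys == {(1, 2)}
        assert pairs.n_discarded_border == 1

    def test_fewer_than_two_maxima_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            pairs = pairs_from_points(np.array([[10.0, 10.0]]), (100.0, 100.0))
        assert pairs.n == 0

    def test_coincident_maxima_excluded_and_counted(self):
        pts = np.array([[50.0, 50.0], [50.0, 50.0], [60.0, 50.0]])
        pairs = pairs_from_points(pts, (100.0, 100.0))
        assert pairs.n_coincident >= 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_for_small_point_sets(self, seed):
        """All-pairs oracle: identical retained pairs for <= 12 points."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        extent = (200.0, 200.0)
        pts = rng.uniform([0, 0], extent, (n, 2))

        # oracle: exhaustive distances, lowest-index ties, pair judged once at
        # its first (lowest-index) centre against the border rule
        expected = set()
        examined = set()
        for i in range(n):
            d = np.linalg.norm(pts - pts[i], axis=1)
            d[i] = np.inf
            j = int(np.flatnonzero(d == d.min()).min())
            key = (min(i, j), max(i, j))
            if key in examined:
                continue
            examined.add(key)
            border = min(pts[i, 0], extent[0] - pts[i, 0], pts[i, 1], extent[1] - pts[i, 1])
            if d[j] <= border:
                expected.add(key)

        pairs = pairs_from_points(pts, extent)
        assert {tuple(k) for k in pairs.indices} == expected


class TestAngleHistogram:
    def test_pair_along_x_falls_in_zero_bin(self):
        pairs = PairSet(vectors=np.array([[10.0, 0.0]]), indices=[(0, 1)])
        hist = angle_histogram(pairs)
        assert hist.counts[3] == 1  # centre 0
        assert hist.n == 1

    def test_vertical_pairs_both_directions_share_merged_end_bin(self):
        pairs = PairSet(vectors=np.array([[0.0, 10.0], [0.0, -10.0]]), indices=[(0, 1), (2, 3)])
        hist = angle_histogram(pairs)
        assert hist.counts[7] == 2  # merged +-pi/2 bin
        assert hist.counts[:7].sum() == 0

    def test_edge_angle_goes_to_higher_bin(self):
        theta = math.pi / 16  # edge between bins centred 0 and pi/8
        vec = np.array([[math.cos(theta), math.sin(theta)]])
        hist = angle_histogram(PairSet(vectors=vec, indices=[(0, 1)]))
        assert hist.counts[4] == 1

    def test_uniform_angles_fill_bins_evenly(self, rng):
        """8000 isotropic angles: each bin within 4 binomial sd of 1000."""
        theta = rng.uniform(-math.pi / 2, math.pi / 2, 8000)
        vecs = np.column_stack([np.cos(theta), np.sin(theta)])
        hist = angle_histogram(PairSet(vectors=vecs, indices=np.arange(16000).reshape(-1, 2)))
        sd = math.sqrt(8000 * (1 / 8) * (7 / 8))
        assert np.all(np.abs(hist.counts - 1000) < 4 * sd)

    def test_empty_pairs_rejected(self):
        empty = PairSet(vectors=np.empty((0, 2)), indices=np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            angle_histogram(empty)


class TestOrderParameter:
    @pytest.mark.parametrize("n", [16, 100, 10_000])
    def test_single_bin_attains_upper_bound(self, n):
        counts = np.zeros(8, dtype=int)
        counts[0] = n
        res = order_parameter(_hist(counts))
        assert res.O == pytest.approx(7.0 * (1.0 - 1.0 / n), rel=1e-12)

    @pytest.mark.parametrize("n", [16, 10_000])
    def test_flat_histogram_attains_lower_bound(self, n):
        res = order_parameter(_hist(np.full(8, n // 8)))
        assert res.sample_variance == 0.0
        assert res.O == pytest.approx(-7.0 / n, rel=1e-12)

    def test_sigma_formula(self):
        res = order_parameter(_hist([13, 12, 13, 12, 13, 12, 13, 12]))
        assert res.n_pairs == 100
        assert res.sigma_O == pytest.approx((7.0 / 100.0) * math.sqrt(2.0 / 8.0), rel=1e-12)
        assert res.sigma_O == pytest.approx(0.035, abs=1e-6)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            order_parameter(_hist(np.zeros(8, dtype=int)))

    def test_fewer_pairs_than_bins_warns(self):
        with pytest.warns(UserWarning, match="uncertainty"):
            order_parameter(_hist([1, 0, 1, 0, 1, 0, 1, 0]))

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=500), min_size=8, max_size=8).filter(
            lambda c: sum(c) >= 8
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_analytic_bounds_hold_for_any_histogram(self, counts):
        """-sigma_bin^2/mu^2 <= O <= (N_bin - 1)(1 - 1/N) for all count vectors."""
        res = order_parameter(_hist(counts))
        n = sum(counts)
        assert res.O >= -7.0 / n - 1e-12
        assert res.O <= 7.0 * (1.0 - 1.0 / n) + 1e-12
        assert 0.0 <= res.p_value <= 1.0


class TestPValue:
    def test_flat_counts_give_half(self):
        assert order_p_value(_hist(np.full(8, 10))) == pytest.approx(0.5)

    def test_matches_normal_tail_of_sigma_x(self):
        counts = np.array([40, 0, 8, 8, 8, 0, 0, 0])
        n = counts.sum()
        mu, sb = n / 8, math.sqrt(n * (1 / 8) * (7 / 8))
        sigma_x = math.sqrt(np.mean(((counts - mu) / sb) ** 2))
        assert order_p_value(_hist(counts)) == pytest.approx(norm.sf(sigma_x), rel=1e-12)

    def test_p_decreases_with_concentration(self):
        flatish = order_p_value(_hist([11, 9, 10, 10, 10, 10, 10, 10]))
        peaked = order_p_value(_hist([45, 5, 5, 5, 5, 5, 5, 5]))
        assert peaked < flatish

    def test_upper_tail_value(self):
        # sigma_x = 2.326 corresponds to p ~ 0.010
        assert norm.sf(2.326) == pytest.approx(0.010, abs=5e-4)


class TestCombineOrder:
    def test_single_result_unchanged(self):
        res = order_parameter(_hist([20, 10, 10, 10, 10, 10, 10, 10]))
        comb = combine_order([res])
        assert comb.O == pytest.approx(res.O)
        assert comb.sigma_O == pytest.approx(res.sigma_O)
        assert comb.p_value == pytest.approx(res.p_value)

    def test_two_equal_results_halve_the_variance(self):
        res = order_parameter(_hist([20, 10, 10, 10, 10, 10, 10, 10]))
        comb = combine_order([res, res])
        assert comb.O == pytest.approx(res.O)
        assert comb.sigma_O == pytest.approx(res.sigma_O / math.sqrt(2.0))

    def test_hand_computed_weighting(self):
        """O = (0.1, sigma 0.1) and (0.3, sigma 0.3) -> 0.12 +- 0.0949."""
        a = order_parameter(_hist([20, 10, 10, 10, 10, 10, 10, 10]))
        r1 = type(a)(O=0.1, sigma_O=0.1, sample_variance=0, null_variance=0,
                     mu_bin=0, p_value=0.5, n_pairs=10)
        r2 = type(a)(O=0.3, sigma_O=0.3, sample_variance=0, null_variance=0,
                     mu_bin=0, p_value=0.5, n_pairs=10)
        comb = combine_order([r1, r2])
        assert comb.O == pytest.approx(0.12, rel=1e-12)
        assert comb.sigma_O == pytest.approx(0.09486832980505137, rel=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            combine_order([])
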