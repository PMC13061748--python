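"""Ripley K/L estimation, edge correction, envelopes, classification."""

import math

import numpy as np
import pytest

from diebackmap import (
    DistanceGrid,
    classify_per_distance,
    k_hat_bivariate,
    k_hat_univariate,
    monte_carlo_envelope,
    simulate_pattern,
    ProcessSpec,
    Window,
)
from diebackmap.ripley import envelope_rank, isotropic_weight

from conftest import make_pattern


def brute_force_weight(cx, cy, d, window):
    """Edge-correction weight written independently from the definition:
    reciprocal of the inside fraction of the circle through the neighbour."""
    bx = min(cx, window.width - cx)
    by = min(cy, window.height - cy)
    if d <= bx and d <= by:
        return 1.0
    a1 = 2 * math.acos(min(bx / d, 1.0))
    a2 = 2 * math.acos(min(by / d, 1.0))
    if d * d > bx * bx + by * by:
        outside = 0.5 * a1 + 0.5 * a2 + math.pi / 2
    else:
        outside = a1 + a2
    return min(2 * math.pi / (2 * math.pi - outside), 4.0)


def brute_force_k(xs, ys, r_values, window, pairs=None):
    """Plain-loop evaluation of the edge-corrected K estimator."""
    n = len(xs)
    area = window.width * window.height
    out = []
    for r in r_values:
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
                if d <= r:
                    total += brute_force_weight(xs[i], ys[i], d, window)
        out.append(area * total / (n * n))
    return np.asarray(out)


class TestEdgeCorrection:
    def test_interior_pair_weight_is_one(self, window):
        assert isotropic_weight(500, 500, 100, window) == 1.0

    def test_weight_matches_numeric_circle_fraction(self, window):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * np.pi, 400_000, endpoint=False)
        for _ in range(10):
            x, y = rng.uniform(0, 1000, 2)
            d = rng.uniform(5, 500)
            px, py = x + d * np.cos(t), y + d * np.sin(t)
            frac = (
                (px >= 0) & (px <= 1000) & (py >= 0) & (py <= 1000)
            ).mean()
            expected = min(1.0 / frac, 4.0)
            got = float(isotropic_weight(x, y, d, window))
            assert got == pytest.approx(expected, rel=1e-4)

    def test_weight_bounded_and_cap_binds(self, window):
        # the corner quarter-circle is the worst case: weight approaches 4
        w = float(isotropic_weight(1.0, 1.0, 499.0, window, cap=100.0))
        assert 3.9 < w <= 4.0
        assert float(isotropic_weight(1.0, 1.0, 499.0, window, cap=2.0)) == 2.0


class TestKUnivariate:
    def test_two_interior_points_hand_value(self, window):
        # Both >= 200 cm from every edge, 50 cm apart: w = 1 both ways,
        # K(100) = A * 2 / n^2 = 1e6 * 2 / 4.
        p = make_pattern([(400, 500), (450, 500)])
        est = k_hat_univariate(p, DistanceGrid(np.array([100.0])))
        assert est.k_hat[0] == pytest.approx(5.0e5)
        assert est.l_hat[0] == pytest.approx(math.sqrt(5e5 / math.pi) - 100)

    def test_k_zero_below_minimum_pair_distance(self, window):
        p = make_pattern([(300, 300), (700, 700)])
        grid = DistanceGrid(np.array([50.0, 100.0]))
        est = k_hat_univariate(p, grid)
        assert np.all(est.k_hat == 0)
        assert np.allclose(est.l_hat, -grid.r)

    def test_k_monotone_and_l_plus_r_nonnegative(self):
        p = simulate_pattern(ProcessSpec("csr", n=80), seed=5)
        est = k_hat_univariate(p)
        assert np.all(np.diff(est.k_hat) >= 0)
        assert np.all(est.l_hat + est.grid.r >= 0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        grid = DistanceGrid(np.array([50.0, 150.0, 400.0]))
        w = Window(1000, 1000)
        for _ in range(5):
            xs = rng.uniform(0, 1000, 30)
            ys = rng.uniform(0, 1000, 30)
            p = make_pattern(np.column_stack([xs, ys]))
            est = k_hat_univariate(p, grid)
            oracle = brute_force_k(xs, ys, grid.r, w)
            assert np.allclose(est.k_hat, oracle, atol=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        xs, ys = rng.uniform(0, 1000, (2, 40))
        p1 = make_pattern(np.column_stack([xs, ys]))
        p2 = make_pattern(
            np.column_stack([2 * xs, 2 * ys]), window=Window(2000, 2000)
        )
        grid1 = DistanceGrid.regular(400, 50)
        grid2 = DistanceGrid(2 * grid1.r)
        l1 = k_hat_univariate(p1, grid1).l_hat
        l2 = k_hat_univariate(p2, grid2).l_hat
        assert np.allclose(l2 / grid2.r, l1 / grid1.r, atol=1e-9)

    def test_needs_two_points(self, window):
        with pytest.raises(ValueError, match="2 points"):
            k_hat_univariate(make_pattern([(5, 5)]))

    def test_rmax_beyond_half_window_rejected(self):
        p = make_pattern([(100, 100), (200, 200)])
        with pytest.raises(ValueError, match="r_max"):
            k_hat_univariate(p, DistanceGrid(np.array([600.0])))


class TestKBivariate:
    def test_live_dead_pair_hand_value(self):
        p = make_pattern(
            [(500, 500), (500, 560)], status=["live", "dead"]
        )
        grid = DistanceGrid(np.array([100.0]))
        est = k_hat_bivariate(p, "live", "dead", grid)
        assert est.k_hat[0] == pytest.approx(1.0e6)

    def test_swap_symmetry(self, marked_pattern):
        grid = DistanceGrid.regular(300, 50)
        a = k_hat_bivariate(marked_pattern, "live", "dead", grid)
        b = k_hat_bivariate(marked_pattern, "dead", "live", grid)
        assert np.allclose(a.k_hat, b.k_hat, atol=1e-12)

    def test_empty_class_named_in_error(self, marked_pattern):
        with pytest.raises(ValueError, match="'gone'"):
            k_hat_bivariate(marked_pattern, "live", "gone")

    def test_matches_brute_force_on_split_pattern(self):
        rng = np.random.default_rng(8)
        w = Window(1000, 1000)
        xs, ys = rng.uniform(0, 1000, (2, 30))
        status = ["live"] * 15 + ["dead"] * 15
        p = make_pattern(np.column_stack([xs, ys]), status=status)
        grid = DistanceGrid(np.array([100.0, 300.0]))
        est = k_hat_bivariate(p, "live", "dead", grid)
        area = 1e6
        k12 = np.zeros(2)
        k21 = np.zeros(2)
        for gi, r in enumerate(grid.r):
            for i in range(15):
                for j in range(15, 30):
                    d = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
                    if d <= r:
                        k12[gi] += brute_force_weight(xs[i], ys[i], d, w)
                        k21[gi] += brute_force_weight(xs[j], ys[j], d, w)
        k12 = area * k12 / (15 * 15)
        k21 = area * k21 / (15 * 15)
        oracle = (15 * k12 + 15 * k21) / 30
        assert np.allclose(est.k_hat, oracle, atol=1e-9)


class TestEnvelope:
    def test_rank_rule(self):
        assert envelope_rank(500, 95) == 13
        assert envelope_rank(99, 95) == 3
        assert envelope_rank(20, 95) == 1

    def test_rejects_too_few_sims(self, marked_pattern):
        with pytest.raises(ValueError, match="n_sims"):
            monte_carlo_envelope(marked_pattern, n_sims=10, seed=0)

    def test_null_statistic_pairing_enforced(self, marked_pattern):
        with pytest.raises(ValueError):
            monte_carlo_envelope(
                marked_pattern, kind="univariate", null="independence", seed=0
            )

    def test_csr_pattern_stays_mostly_inside(self):
        p = simulate_pattern(ProcessSpec("csr", n=100), seed=21)
        env = monte_carlo_envelope(
            p, grid=DistanceGrid.regular(300, 20), n_sims=199, seed=22
        )
        assert env.exit_fraction <= 0.2
        assert np.all(env.lower <= env.upper)

    def test_independence_null_calibration_random_labels(self):
        # Random labelling makes live and dead independent by construction;
        # the toroidal-shift envelope should rarely flag departure.
        exits = []
        for seed in range(10):
            p = simulate_pattern(ProcessSpec("csr", n=120), seed=100 + seed)
            rng = np.random.default_rng(200 + seed)
            status = np.where(rng.random(p.n) < 0.4, "dead", "live")
            p = p.with_marks(status=status)
            env = monte_carlo_envelope(
                p,
                kind="bivariate",
                mark_a="live",
                mark_b="dead",
                grid=DistanceGrid.regular(300, 30),
                n_sims=199,
                seed=300 + seed,
            )
            exits.append(env.exit_fraction)
        assert np.mean(exits) <= 0.10

    def test_random_labeling_null_option(self, marked_pattern):
        env = monte_carlo_envelope(
            marked_pattern,
            kind="bivariate",
            null="random_labeling",
            mark_a="live",
            mark_b="dead",
            grid=DistanceGrid.regular(200, 50),
            n_sims=39,
            seed=1,
        )
        assert env.null == "random_labeling"
        assert len(env.classification) == 4


class TestClassification:
    def test_univariate_labels(self):
        labels = classify_per_distance(
            [5.0, 0.0, -5.0], [-2.0, -2.0, -2.0], [2.0, 2.0, 2.0], "univariate"
        )
        assert labels == ["clumped", "random", "uniform"]

    def test_bivariate_labels(self):
        labels = classify_per_distance(
            [5.0, -5.0], [-2.0, -2.0], [2.0, 2.0], "bivariate"
        )
        assert labels == ["attraction", "repulsion"]

    def test_value_on_bound_counts_as_inside(self):
        labels = classify_per_distance([2.0, -2.0], [-2.0, -2.0], [2.0, 2.0],
                                       "univariate")
        assert labels == ["random", "random"]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            classify_per_distance([1.0, 2.0], [0.0], [3.0], "univariate")
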