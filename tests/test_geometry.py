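"""Circle solvers, activation weighting, and the consensus loop."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitsize.errors import (
    DegenerateConfigurationError,
    DegenerateSampleError,
    InsufficientPointsError,
)
from fruitsize.geometry import (
    Circle,
    RansacConfig,
    activation_weight,
    point_circle_distance,
    ransac_circle,
    refit_circle,
    solve_circle_3pt,
)

from conftest import circle_points


class TestSolveCircle3pt:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(1, 0), (0, 1), (-1, 0)], (0.0, 0.0, 1.0)),
            ([(0, 0), (2, 0), (1, 1)], (1.0, 0.0, 1.0)),
            ([(0, 0), (6, 0), (3, 9)], (3.0, 4.0, 5.0)),
        ],
    )
    def test_known_circles(self, pts, expected):
        c = solve_circle_3pt(*pts)
        assert (c.a, c.b, c.r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            [(0, 0), (1, 1), (2, 2)],      # collinear
            [(0, 0), (0, 0), (1, 1)],      # duplicate
            [(0, 0), (1e-13, 0), (2e-13, 0)],
        ],
    )
    def test_degenerate_samples_rejected(self, pts):
        with pytest.raises(DegenerateSampleError):
            solve_circle_3pt(*pts)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(-500, 500),
        b=st.floats(-500, 500),
        r=st.floats(0.5, 300),
        angles=st.tuples(
            st.floats(0, 2 * math.pi),
            st.floats(0, 2 * math.pi),
            st.floats(0, 2 * math.pi),
        ),
    )
    def test_reconstructs_generating_circle(self, a, b, r, angles):
        """Any circle is recovered exactly from three well-separated points."""
        t = np.sort(np.array(angles))
        if np.min(np.diff(np.concatenate([t, [t[0] + 2 * math.pi]]))) < 0.1:
            return  # nearly coincident sample points: not a valid triple
        pts = np.column_stack([a + r * np.cos(t), b + r * np.sin(t)])
        c = solve_circle_3pt(*pts)
        scale = max(abs(a), abs(b), r, 1.0)
        assert math.hypot(c.a - a, c.b - b) < 1e-7 * scale
        assert abs(c.r - r) < 1e-7 * scale


class TestPointCircleDistance:
    @pytest.mark.parametrize(
        "p, circle, expected",
        [
            ((0, 0), Circle(0, 0, 5), 0.0),
            ((3, 4), Circle(0, 0, 5), 5.0),
            ((6, 8), Circle(1, 1, 1), math.sqrt(74)),
        ],
    )
    def test_distance_to_centre(self, p, circle, expected):
        assert point_circle_distance(p, circle) == pytest.approx(expected)


class TestActivationWeight:
    def test_half_at_circle_in_both_modes(self):
        for mode in ("signed", "absolute"):
            assert activation_weight(7.0, 7.0, 2.5, mode) == 0.5

    def test_signed_limits(self):
        assert activation_weight(1e6, 5.0, 1.0, "signed") == pytest.approx(0.0)
        assert activation_weight(5 - math.log(3), 5.0, 1.0, "signed") == pytest.approx(0.75)

    def test_overflow_saturates_finite(self):
        lo = activation_weight(1e8, 1.0, 50.0, "signed")
        hi = activation_weight(-1e8, 1.0, 50.0, "signed")
        assert np.isfinite([lo, hi]).all()
        assert lo == 0.0 and hi == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(
        r=st.floats(0.1, 100),
        alpha=st.floats(0.01, 20),
        delta=st.floats(0.0, 50),
    )
    def test_absolute_mode_symmetric_and_bounded(self, r, alpha, delta):
        inner = activation_weight(r - delta, r, alpha, "absolute")
        outer = activation_weight(r + delta, r, alpha, "absolute")
        assert inner == pytest.approx(outer, rel=1e-12)
        assert 0.0 <= inner <= 0.5
        assert activation_weight(r, r, alpha, "absolute") == 0.5

    def test_absolute_mode_nonincreasing_in_residual(self):
        deltas = np.linspace(0, 10, 50)
        weights = activation_weight(5.0 + deltas, 5.0, 1.3, "absolute")
        assert np.all(np.diff(weights) <= 0)


class TestRefitCircle:
    def test_three_points_match_exact_solver(self):
        exact = solve_circle_3pt((1, 0), (0, 1), (-1, 0))
        ls = refit_circle([(1, 0), (0, 1), (-1, 0)])
        assert (ls.a, ls.b, ls.r) == pytest.approx((exact.a, exact.b, exact.r), abs=1e-6)

    def test_exact_points_zero_noise(self):
        pts = circle_points(10, 20, 7, n=100)
        c = refit_circle(pts)
        assert (c.a, c.b, c.r) == pytest.approx((10, 20, 7), abs=1e-6)

    def test_radial_noise_monte_carlo(self):
        pts = circle_points(10, 20, 7, n=100, jitter=0.5, seed=123)
        c = refit_circle(pts)
        assert abs(c.r - 7) < 0.2

    def test_weights_pull_fit_toward_heavy_points(self):
        pts = np.vstack([circle_points(0, 0, 10, 30), circle_points(0, 0, 12, 30)])
        w_inner = np.concatenate([np.full(30, 1.0), np.full(30, 1e-6)])
        c = refit_circle(pts, w_inner)
        assert c.r == pytest.approx(10, abs=0.01)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateConfigurationError):
            refit_circle(pts)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            refit_circle([(0, 0), (1, 1)])


def brute_force_best_model(points: np.ndarray, epsilon: float):
    """Independent oracle: enumerate every triple via perpendicular
    bisectors, count inliers, apply the same tie-breaking."""
    best = None
    for i, j, k in itertools.combinations(range(len(points)), 3):
        (x1, y1), (x2, y2), (x3, y3) = points[i], points[j], points[k]
        d = 2 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
        if abs(d) < 1e-9:
            continue
        ux = ((x1**2 + y1**2) * (y2 - y3) + (x2**2 + y2**2) * (y3 - y1)
              + (x3**2 + y3**2) * (y1 - y2)) / d
        uy = ((x1**2 + y1**2) * (x3 - x2) + (x2**2 + y2**2) * (x1 - x3)
              + (x3**2 + y3**2) * (x2 - x1)) / d
        r = math.hypot(x1 - ux, y1 - uy)
        res = np.abs(np.hypot(points[:, 0] - ux, points[:, 1] - uy) - r)
        inl = res < epsilon
        key = (-int(inl.sum()), float(res[inl].mean()) if inl.any() else np.inf)
        if best is None or key < best[0]:
            best = (key, (ux, uy, r), int(inl.sum()))
    return best


class TestRansacCircle:
    def test_noiseless_consensus(self):
        pts = circle_points(5, 5, 3, n=20)
        res = ransac_circle(pts, RansacConfig(seed=0))
        assert (res.circle.a, res.circle.b, res.circle.r) == pytest.approx((5, 5, 3), abs=1e-6)
        assert res.retained_mask.all()
        assert res.n_inliers == 20

    def test_gross_outliers_match_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([
            circle_points(12, 9, 6, n=20, jitter=0.3, seed=3),
            rng.uniform(25, 45, size=(5, 2)),  # all >= 10 px from the circle
        ])
        cfg = RansacConfig(sampling="exhaustive", epsilon=2.0, seed=0)
        res = ransac_circle(pts, cfg)
        _, _, oracle_count = brute_force_best_model(pts, epsilon=2.0)
        assert res.n_inliers == oracle_count
        assert abs(res.circle.r - 6) < 0.5

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            ransac_circle([(0, 0), (1, 1)], RansacConfig())

    def test_signed_mode_retains_interior_points(self):
        """Literal one-sided rule: interior clutter survives the filter."""
        pts = np.vstack([circle_points(20, 20, 10, n=40), [(20.0, 20.0), (21.0, 20.0)]])
        res = ransac_circle(pts, RansacConfig(residual_mode="signed", seed=1))
        assert res.retained_mask[-2:].all()
        res_abs = ransac_circle(pts, RansacConfig(residual_mode="absolute", seed=1))
        assert not res_abs.retained_mask[-2:].any()

    def test_determinism_bit_identical(self):
        pts = circle_points(8, -3, 5, n=30, jitter=0.4, seed=9)
        cfg = RansacConfig(seed=42)
        r1 = ransac_circle(pts, cfg)
        r2 = ransac_circle(pts, cfg)
        assert r1.circle == r2.circle
        assert r1.best_model == r2.best_model
        assert np.array_equal(r1.inlier_mask, r2.inlier_mask)
        assert np.array_equal(r1.retained_mask, r2.retained_mask)
        assert r1.mean_abs_residual == r2.mean_abs_residual

    def test_robust_recovery_over_seeds(self):
        """>= 70% of points near a circle, rest uniform clutter: the refit
        radius lands within 1 px of truth in >= 95% of seeded runs."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            pts = np.vstack([
                circle_points(30, 30, 15, n=35, jitter=0.5, seed=seed),
                rng.uniform(10, 50, size=(15, 2)),
            ])
            res = ransac_circle(pts, RansacConfig(seed=seed))
            hits += abs(res.circle.r - 15) <= 1.0
        assert hits / n_runs >= 0.95

    def test_activation_weighted_refit_runs(self):
        pts = circle_points(5, 5, 4, n=25, jitter=0.2, seed=2)
        res = ransac_circle(pts, RansacConfig(refit_mode="activation_weighted", seed=3))
        assert abs(res.circle.r - 4) < 0.3
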