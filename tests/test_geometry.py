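"""Bézier fitting and curvature analysis: exactness, oracles and invariances."""

import numpy as np
import pytest

from tuberkit.geometry import (
    BezierCurve,
    BezierProfileModel,
    CurvatureProfile,
    bernstein_matrix,
    curvature_profile,
    curvature_ratio,
    fit_bezier,
    fit_bezier_regular,
    max_abs_curvature,
    mean_abs_curvature,
)
from tuberkit.synthetic import BumpSpec, make_profile

from conftest import arc_points

QUAD = BezierCurve([[0.0, 0.0], [50.0, 40.0], [100.0, 0.0]])


def finite_difference_curvature(curve, t, h=1e-5):
    """Independent curvature oracle: central differences on curve points."""
    p_m, p_0, p_p = (curve.evaluate(np.clip(t + d, 0, 1)) for d in (-h, 0.0, h))
    d1 = (p_p - p_m) / (2 * h)
    d2 = (p_p - 2 * p_0 + p_m) / h**2
    return (d1[0] * d2[1] - d1[1] * d2[0]) / (d1[0] ** 2 + d1[1] ** 2) ** 1.5


class TestEvaluation:
    def test_endpoint_interpolation(self):
        assert np.allclose(QUAD.evaluate(0.0), [0, 0])
        assert np.allclose(QUAD.evaluate(1.0), [100, 0])

    def test_midpoint_by_hand_de_casteljau(self):
        # hand de Casteljau: (25,20),(75,20) -> (50,20)
        assert np.allclose(QUAD.evaluate(0.5), [50.0, 20.0])

    def test_bernstein_and_de_casteljau_agree(self, rng):
        cp = rng.normal(size=(7, 2)) * 50
        curve = BezierCurve(cp)
        for t in rng.uniform(0, 1, 25):
            assert np.allclose(curve.evaluate(t), curve.evaluate_de_casteljau(t), atol=1e-9)

    def test_parameter_range_enforced(self):
        with pytest.raises(ValueError):
            QUAD.evaluate(1.2)
        with pytest.raises(ValueError):
            QUAD.evaluate(-0.1)

    def test_degree_below_two_rejected(self):
        with pytest.raises(ValueError):
            BezierCurve([[0, 0], [1, 1]])


class TestFitting:
    def test_exact_recovery_of_quadratic(self):
        pts = bernstein_matrix(np.linspace(0, 1, 11), 2) @ QUAD.control_points
        res = fit_bezier(pts, degree=2)
        assert np.abs(res.curve.control_points - QUAD.control_points).max() < 1e-6
        assert res.residual_rms < 1e-8

    def test_straight_line_any_degree_has_zero_curvature(self):
        pts = np.column_stack([np.linspace(0, 100, 40), np.zeros(40)])
        for degree in (2, 3, 5):
            prof = fit_bezier(pts, degree=degree).curvature_profile()
            assert np.nanmax(prof.kappa_scaled) <= 1e-6

    def test_arc_curvature_within_two_percent_everywhere(self):
        # radius 50 micron <-> scaled curvature 20
        res = fit_bezier(arc_points(50.0), degree=5)
        t = np.linspace(0.05, 0.95, 100)
        kappa = np.abs(res.curve.signed_curvature(t)) * 1000
        assert np.all(np.abs(kappa - 20.0) / 20.0 < 0.02)

    def test_too_few_points_error_names_minimum(self):
        with pytest.raises(ValueError, match="at least 6 points"):
            fit_bezier(np.column_stack([np.arange(4), np.arange(4)]), degree=5)

    def test_duplicate_points_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            fit_bezier(pts, degree=2)

    def test_auto_degree_meets_rms_target(self):
        spec = BumpSpec(shape="compound", W=80, H=20, noise_sd=0.0, seed=1)
        pts = make_profile(spec).points
        res = BezierProfileModel(pts, degree="auto").fit()
        assert res.residual_rms < 0.5 or res.curve.degree == 10

    def test_regular_fit_escalates_degree_past_near_cusp(self):
        # a very sharp tall bump collapses a degree-5 fit into a near-cusp
        pts = make_profile(BumpSpec("acute", W=48.5, H=110.4, noise_sd=0.5, seed=7)).points
        plain = fit_bezier(pts, degree=5)
        robust = fit_bezier_regular(pts, degree=5)
        assert plain.min_speed_ratio < 0.15  # the failure mode exists
        assert robust.min_speed_ratio >= 0.15
        # apex radius W/20 = 2.425 micron -> scaled curvature ~412
        kmax = robust.curvature_profile().max_abs()
        assert 250 < kmax < 600


class TestCurvature:
    def test_circle_recovery_at_reference_radii(self):
        for r in (10.0, 25.0, 50.0, 100.0):
            prof = fit_bezier(arc_points(r), degree=5).curvature_profile()
            assert 0.98 * 1000 / r <= prof.mean_abs() <= 1.02 * 1000 / r

    def test_matches_finite_difference_oracle(self, rng):
        for _ in range(10):
            degree = int(rng.integers(2, 7))
            curve = BezierCurve(np.cumsum(rng.normal(size=(degree + 1, 2)), axis=0) * 30)
            for t in rng.uniform(0.05, 0.95, 8):
                analytic = curve.signed_curvature(t)
                oracle = finite_difference_curvature(curve, t)
                assert abs(analytic - oracle) <= 1e-5 * max(1.0, abs(oracle))

    def test_parabola_curvature_against_oracle(self):
        t = 0.5
        assert abs(QUAD.signed_curvature(t) - finite_difference_curvature(QUAD, t)) < 1e-6

    def test_euclidean_invariance(self, rng):
        pts = arc_points(40.0)
        base = fit_bezier(pts, degree=5).curvature_profile().kappa_scaled
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ R.T + np.array([13.0, -7.0])
        rotated = fit_bezier(moved, degree=5).curvature_profile().kappa_scaled
        assert np.nanmax(np.abs(base - rotated)) < 1e-9 * 1000

    def test_scaling_divides_curvature(self):
        pts = arc_points(40.0)
        base = fit_bezier(pts, degree=5).curvature_profile().kappa_scaled
        scaled = fit_bezier(pts * 3.0, degree=5).curvature_profile().kappa_scaled
        assert np.allclose(scaled, base / 3.0, rtol=1e-9, atol=1e-9)

    def test_cusp_is_flagged_not_silent(self):
        # cubic whose first derivative vanishes exactly at t = 0.5
        cusp = BezierCurve([[0.0, 0.0], [4.0, 4.0], [0.0, 0.0], [4.0, 4.0]])
        with pytest.warns(RuntimeWarning, match="cusp"):
            k = cusp.signed_curvature(0.5)
        assert np.isnan(k)


class TestCurvatureProfile:
    def test_constant_on_circular_arc(self):
        prof = fit_bezier(arc_points(50.0), degree=5).curvature_profile()
        k = prof.kappa_scaled
        assert np.nanmax(k) / np.nanmin(k) < 1.02 / 0.98

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError):
            curvature_profile(QUAD, n_samples=10)

    def test_acute_bump_has_unique_interior_maximum(self):
        pts = make_profile(BumpSpec("acute", W=72, H=43.6, noise_sd=0.0)).points
        prof = fit_bezier(pts, degree=5).curvature_profile()
        k = prof.kappa_scaled
        # dense-sampling oracle: a single dominant curvature peak at the apex
        dominant = (k[1:-1] > k[:-2]) & (k[1:-1] > k[2:]) & (k[1:-1] > 0.5 * np.nanmax(k))
        assert dominant.sum() == 1
        tmax = prof.t_values[1:-1][dominant][0]
        assert 0.4 < tmax < 0.6

    def test_compound_bump_has_multiple_curvature_maxima(self):
        pts = make_profile(BumpSpec("compound", W=80, H=20, noise_sd=0.0)).points
        prof = BezierProfileModel(pts, degree="auto").fit().curvature_profile(400)
        k = prof.kappa_scaled
        local_max = (k[1:-1] > k[:-2]) & (k[1:-1] > k[2:]) & (k[1:-1] > 0.2 * np.nanmax(k))
        assert local_max.sum() >= 2

    def test_max_at_least_mean_and_ratio_at_least_one(self, rng):
        for _ in range(5):
            curve = BezierCurve(np.cumsum(rng.normal(size=(6, 2)), axis=0) * 40)
            prof = curvature_profile(curve)
            kmax, kmean = max_abs_curvature(prof), mean_abs_curvature(prof)
            assert kmax >= kmean
            assert curvature_ratio(kmax, kmean) >= 1.0

    def test_constant_profile_ratio_is_one(self):
        prof = fit_bezier(arc_points(50.0), degree=5).curvature_profile()
        assert curvature_ratio(prof.max_abs(), prof.mean_abs()) == pytest.approx(1.0, abs=0.02)

    def test_zero_mean_curvature_ratio_flagged(self):
        with pytest.raises(ValueError, match="ratio undefined"):
            curvature_ratio(0.0, 0.0)

    def test_arc_weighted_mean_available(self):
        prof = fit_bezier(arc_points(50.0), degree=5).curvature_profile()
        assert prof.mean_abs(arc_weighted=True) == pytest.approx(prof.mean_abs(), rel=0.02)


class TestSerialization:
    def test_curve_json_round_trip(self):
        again = BezierCurve.from_json(QUAD.to_json())
        assert np.array_equal(again.control_points, QUAD.control_points)

    def test_profile_frame_has_expected_columns(self):
        res = fit_bezier(arc_points(50.0), degree=5)
        df = res.curvature_profile().to_frame(res.curve)
        assert list(df.columns)[:4] == ["t", "x", "y", "kappa_scaled"]

    def test_summary_and_plot_run(self):
        res = fit_bezier(arc_points(50.0), degree=5)
        assert "residual RMS" in res.summary()
        fig = res.plot()
        assert fig is not None
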