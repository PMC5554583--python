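"""Penalized polynomial fit: cost/gradient correctness, equivalence with
closed-form least squares when unpenalized, penalty behaviour, and curve
inversion."""

import numpy as np
import pytest
from numpy.polynomial import polynomial as P

from pallor.kalman import FeatureSeries
from pallor.regression import (
    MatchingIssueWarning,
    PenaltyConfig,
    PolynomialModel,
    cost,
    cost_gradient,
    fit_linear_regression,
    fit_penalty_regression,
    invert_model,
    predict_feature,
)


def toy_cfg(**kw):
    """Configuration for standardized toy problems (fast convergence)."""
    base = dict(alpha=1e-3, lam=0.0, tol=1e-14, max_iter=300_000, standardize=True)
    base.update(kw)
    return PenaltyConfig(**base)


class TestPredict:
    @pytest.mark.parametrize(
        "coeffs,h,expected",
        [((1, 2), 3, 7), ((0, 0), 5, 0), ((1, 0, 0, 0, 1), 2, 17)],
    )
    def test_polynomial_evaluation(self, coeffs, h, expected):
        model = PolynomialModel(coeffs=np.array(coeffs, dtype=float))
        assert predict_feature(model, h) == pytest.approx(expected)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError):
            PolynomialModel(coeffs=[1.0, np.inf])


class TestCost:
    def test_perfect_fit_without_penalty_is_zero(self, linear_series):
        model = PolynomialModel(coeffs=[60.0, 8.0])
        cfg = PenaltyConfig(order=1, c=(1.0,), lam=0.0, alpha=1.0)
        assert cost(model, linear_series, cfg) == 0.0

    def test_single_point_squared_error(self):
        s = FeatureSeries(hb=[1.0], z=[2.0])
        cfg = PenaltyConfig(order=1, c=(0.0,), lam=0.0, alpha=1.0)
        assert cost(PolynomialModel(coeffs=[0.0, 0.0]), s, cfg) == pytest.approx(4.0)

    def test_penalty_term_alone_when_no_data(self):
        cfg = PenaltyConfig(order=1, c=(2.0,), lam=1.0, alpha=1.0)
        assert cost(PolynomialModel(coeffs=[0.0, 3.0]), None, cfg) == pytest.approx(18.0)

    def test_intercept_is_never_penalized(self):
        cfg = PenaltyConfig(order=1, c=(1.0,), lam=5.0, alpha=1.0)
        assert cost(PolynomialModel(coeffs=[100.0, 0.0]), None, cfg) == 0.0


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, rng):
        cfg = PenaltyConfig(order=3, c=(1.0, 10.0, 20.0), lam=0.3, alpha=0.7)
        for _ in range(5):
            hb = np.sort(rng.uniform(1, 3, 12)) + np.arange(12) * 1e-9
            s = FeatureSeries(hb=hb, z=rng.normal(0, 1, 12))
            a = rng.normal(0, 1, 4)
            g = cost_gradient(PolynomialModel(coeffs=a), s, cfg)
            eps = 1e-6
            for i in range(4):
                ap, am = a.copy(), a.copy()
                ap[i] += eps
                am[i] -= eps
                fd = (
                    cost(PolynomialModel(coeffs=ap), s, cfg)
                    - cost(PolynomialModel(coeffs=am), s, cfg)
                ) / (2 * eps)
                assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestFitPenalty:
    @pytest.mark.parametrize("order", [1, 2])
    def test_unpenalized_fit_matches_normal_equations(self, order):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            hb = np.sort(rng.uniform(6, 16, 30)) + np.arange(30) * 1e-9
            true = rng.normal(0, 1, order + 1) * [100, 10, 1][: order + 1]
            z = P.polyval(hb, true) + rng.normal(0, 0.5, 30)
            s = FeatureSeries(hb=hb, z=z)
            cfg = toy_cfg(order=order, c=tuple([1.0] * order), init_seed=seed)
            model = fit_penalty_regression(s, cfg)
            oracle = P.polyfit(hb, z, order)
            np.testing.assert_allclose(model.coeffs, oracle, rtol=1e-3, atol=1e-6)

    def test_cost_is_nonincreasing_and_reported(self, linear_series):
        cfg = toy_cfg(order=2, c=(1.0, 10.0))
        model = fit_penalty_regression(linear_series, cfg)
        assert model.fit_report["converged"]
        assert model.fit_report["final_cost"] >= 0

    def test_dominant_penalty_shrinks_slope_toward_constant_fit(self, linear_series):
        cfg = toy_cfg(order=2, c=(1.0, 1.0), lam=10.0, alpha=1e-2, tol=1e-16,
                      max_iter=500_000)
        model = fit_penalty_regression(linear_series, cfg)
        # penalty dominates the data term: the fit collapses to ~the best constant
        span = np.ptp(linear_series.z)
        pred = P.polyval(linear_series.hb, model.coeffs)
        assert np.ptp(pred) < 0.05 * span
        assert np.mean(pred) == pytest.approx(np.mean(linear_series.z), rel=0.05)

    def test_penalty_term_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        hb = np.linspace(0.1, 2.0, 30)
        z = 1.5 - 0.8 * hb + 0.3 * hb**2 + rng.normal(0, 0.05, 30)
        s = FeatureSeries(hb=hb, z=z)
        pens = []
        for lam in (0.0, 1e-3, 1.0, 1e3):
            cfg = PenaltyConfig(
                order=4, c=(1.0, 10.0, 20.0, 30.0), lam=lam, alpha=1e-3,
                tol=1e-14, max_iter=400_000, init_seed=1,
            )
            m = fit_penalty_regression(s, cfg)
            pens.append(float(np.sum(np.array(cfg.c) * m.coeffs[1:] ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(pens, pens[1:]))

    def test_backtracking_recovers_from_oversized_steps(self, linear_series):
        cfg = toy_cfg(order=1, c=(1.0,), alpha=50.0)  # far beyond the stable step
        model = fit_penalty_regression(linear_series, cfg)
        assert model.fit_report["step_halvings"] > 0
        assert model.fit_report["converged"]

    def test_underdetermined_fit_warns(self):
        s = FeatureSeries(hb=[10.0, 11.0], z=[1.0, 2.0])
        with pytest.warns(UserWarning, match="underdetermined"):
            fit_penalty_regression(s, toy_cfg(order=4, c=(1, 10, 20, 30), max_iter=1000))

    def test_decreasing_penalty_coefficients_warn(self):
        with pytest.warns(UserWarning, match="nondecreasing"):
            PenaltyConfig(order=2, c=(10.0, 1.0)).validate()

    def test_raw_scale_defaults_converge_on_study_scale_data(self, noisy_table):
        s = FeatureSeries(
            hb=np.sort(noisy_table["hb_g_dl"].to_numpy()),
            z=noisy_table.sort_values("hb_g_dl")["feature"].to_numpy(),
        )
        model = fit_penalty_regression(s)  # protocol defaults, raw scale
        assert model.fit_report["converged"]
        assert np.all(np.isfinite(model.coeffs))


class TestLinear:
    def test_two_points(self):
        s = FeatureSeries(hb=[1.0, 2.0], z=[1.0, 2.0])
        np.testing.assert_allclose(fit_linear_regression(s).coeffs, [0.0, 1.0], atol=1e-12)

    def test_constant_feature_gives_flat_line(self):
        s = FeatureSeries(hb=[1.0, 2.0, 3.0], z=[5.0, 5.0, 5.0])
        np.testing.assert_allclose(fit_linear_regression(s).coeffs, [5.0, 0.0], atol=1e-12)

    def test_collinear_points_fit_exactly(self):
        s = FeatureSeries(hb=[1.0, 2.0, 4.0], z=[3.0, 5.0, 9.0])
        model = fit_linear_regression(s)
        np.testing.assert_allclose(model.coeffs, [1.0, 2.0], atol=1e-12)

    def test_degenerate_hb_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_regression(FeatureSeries(hb=[2.0], z=[1.0]))


class TestInvert:
    def test_monotone_line_inverts_exactly(self):
        model = PolynomialModel(coeffs=[200.0, -10.0])
        assert invert_model(model, 90.0, (5.0, 16.0)) == pytest.approx(11.0, abs=1e-6)

    def test_out_of_range_feature_clamps_to_boundary(self):
        model = PolynomialModel(coeffs=[200.0, -10.0])  # decreasing curve
        assert invert_model(model, 500.0, (5.0, 16.0)) == pytest.approx(5.0, abs=1e-9)

    def test_tied_roots_resolve_to_smallest_hb_with_warning(self):
        model = PolynomialModel(coeffs=[0.0, 0.0, 1.0])  # f(h) = h^2
        with pytest.warns(MatchingIssueWarning):
            est = invert_model(model, 1.0, (-2.0, 2.0))
        assert est == pytest.approx(-1.0, abs=1e-6)

    def test_round_trip_for_strictly_monotone_model(self, rng):
        model = PolynomialModel(coeffs=[60.0, 8.0, 0.1])
        for h_true in rng.uniform(6, 16, 10):
            feat = predict_feature(model, h_true)
            assert invert_model(model, feat, (6.0, 16.0)) == pytest.approx(
                h_true, abs=2e-3
            )

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            invert_model(PolynomialModel(coeffs=[0.0, 1.0]), 1.0, (5.0, 5.0))
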