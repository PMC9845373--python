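"""Heat-day bins, RR curves, and the percent-change statistic."""

import numpy as np
import pytest

import heatdlnm as h
from heatdlnm.glm import DLNMResults
from heatdlnm.risk import (
    HeatDayBins,
    RRCurve,
    bin_grid,
    heat_day_bins,
    percent_change,
    percent_change_ci,
    predict_rr,
)
from heatdlnm.splines import CrossBasisSpec, SplineSpec, ns_basis


def _toy_fit(beta, cov, spec):
    p = len(beta)
    return DLNMResults(
        params=np.asarray(beta, float),
        cov=np.asarray(cov, float),
        column_labels=[f"cb{i}" for i in range(p)],
        loglik=0.0,
        aic=0.0,
        deviance=0.0,
        n_obs=10,
        converged=True,
        iterations=1,
        cb_spec=spec,
        cb_index=np.arange(p),
    )


def _toy_spec():
    var = SplineSpec((27.0,), (20.0, 36.0))  # 2 columns
    lag = SplineSpec((), (0.0, 2.0), include_intercept=True)  # 2 columns
    return CrossBasisSpec(2, var, lag)


class TestHeatDayBins:
    def test_percentile_labels_map_to_bins(self):
        bins = HeatDayBins(30.0, 33.0, 36.0)
        assert bins.bin_range("Mild", 40.0) == (30.0, 33.0)
        assert bins.bin_range("Moderate", 40.0) == (33.0, 36.0)
        assert bins.bin_range("Severe", 40.0) == (36.0, 40.0)

    def test_uniform_draws_match_order_statistics_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(20.0, 40.0, 10_000)
        bins = heat_day_bins(x)
        xs = np.sort(x)

        def oracle(p):
            # sort-and-index percentile with linear interpolation
            rank = p / 100 * (x.size - 1)
            lo = int(np.floor(rank))
            frac = rank - lo
            return xs[lo] * (1 - frac) + xs[min(lo + 1, x.size - 1)] * frac

        np.testing.assert_allclose(
            [bins.p60, bins.p90, bins.p99], [oracle(60), oracle(90), oracle(99)], atol=1e-9
        )
        # Monte-Carlo proximity to the uniform population quantiles
        np.testing.assert_allclose([bins.p60, bins.p90, bins.p99], [32.0, 38.0, 39.8], atol=0.3)

    def test_constant_series_rejected_as_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            heat_day_bins(np.full(500, 30.0))

    def test_short_series_warns(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="summer days"):
            heat_day_bins(rng.uniform(20, 40, 50))


class TestPredictRR:
    def test_zero_coefficients_give_flat_curve_with_zero_width(self):
        spec = _toy_spec()
        fit = _toy_fit(np.zeros(4), np.zeros((4, 4)), spec)
        curve = predict_rr(fit, spec, [25.0, 30.0, 35.0], 28.0)
        np.testing.assert_allclose(curve.rr, 1.0)
        np.testing.assert_allclose(curve.lower95, 1.0)
        np.testing.assert_allclose(curve.upper95, 1.0)

    def test_reference_centering_identity(self):
        rng = np.random.default_rng(23)
        spec = _toy_spec()
        fit = _toy_fit(rng.normal(size=4), np.eye(4) * 0.01, spec)
        curve = predict_rr(fit, spec, [28.0], 28.0)
        assert curve.rr[0] == pytest.approx(1.0, abs=0)
        assert curve.lower95[0] == pytest.approx(1.0)
        assert curve.upper95[0] == pytest.approx(1.0)

    def test_log_rr_matches_hand_coded_basis_difference(self):
        spec = _toy_spec()
        beta = np.array([0.03, -0.01, 0.02, 0.005])
        fit = _toy_fit(beta, np.zeros((4, 4)), spec)
        ref = 26.0
        grid = np.array([24.0, 30.0, 34.0])
        curve = predict_rr(fit, spec, grid, ref)
        # hand-coded loops: logRR(T) = sum_ij beta_ij (b_i(T)-b_i(ref)) sum_l c_j(l)
        var_cols = ns_basis(np.append(grid, ref), spec.var_spec).values
        lag_vals = spec.lag_basis()
        for g, T in enumerate(grid):
            expected = 0.0
            for i in range(2):
                for j in range(2):
                    csum = sum(lag_vals[l, j] for l in range(3))
                    expected += beta[i * 2 + j] * (var_cols[g, i] - var_cols[-1, i]) * csum
            assert np.log(curve.rr[g]) == pytest.approx(expected, abs=1e-10)

    def test_grid_outside_boundary_warns(self):
        spec = _toy_spec()
        fit = _toy_fit(np.zeros(4), np.zeros((4, 4)), spec)
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_rr(fit, spec, [40.0], 28.0)

    def test_fitted_curve_is_centred_at_reference(self, fitted_stratum):
        res = fitted_stratum["result"]
        ref = fitted_stratum["reference"]
        curve = res.predict_rr([ref - 2.0, ref, ref + 2.0], ref)
        assert curve.rr[1] == pytest.approx(1.0, abs=1e-12)
        assert (curve.lower95 <= curve.rr + 1e-12).all()
        assert (curve.rr <= curve.upper95 + 1e-12).all()
        assert (curve.rr > 0).all()


class TestPercentChange:
    def test_flat_curve_gives_zero(self):
        grid = np.arange(30.0, 36.0)
        curve = RRCurve(grid, np.ones(6), np.ones(6), np.ones(6), 30.0)
        pc = percent_change(curve, (30.0, 35.0), "Mild")
        assert pc.value == 0.0

    def test_hand_arithmetic_eleven_points(self):
        grid = np.arange(25.0, 36.0)
        rr = np.linspace(1.0, 1.10, 11)
        curve = RRCurve(grid, rr, rr, rr, 25.0)
        pc = percent_change(curve, (25.0, 35.0), "Mild")
        assert pc.n_points == 11
        assert pc.value == pytest.approx(1.0)

    def test_hand_arithmetic_five_points(self):
        grid = np.arange(30.0, 35.0)
        rr = np.linspace(1.02, 1.06, 5)
        curve = RRCurve(grid, rr, rr, rr, 30.0)
        pc = percent_change(curve, (30.0, 34.0), "Severe")
        assert pc.n_points == 5
        assert pc.value == pytest.approx(1.0)

    def test_exact_value_identity(self):
        grid = np.arange(30.0, 34.0)
        rr = np.array([1.0, 1.03, 1.05, 1.09])
        curve = RRCurve(grid, rr, rr, rr, 30.0)
        pc = percent_change(curve, (30.0, 33.4), "Moderate")
        assert pc.value == (pc.rr_last - pc.rr_first) / (pc.n_points - 1) * 100

    def test_narrow_bin_rejected(self):
        grid = np.arange(30.0, 36.0)
        curve = RRCurve(grid, np.ones(6), np.ones(6), np.ones(6), 30.0)
        with pytest.raises(ValueError, match="narrower than 1"):
            percent_change(curve, (30.0, 30.5), "Severe")

    def test_grid_rule_floor_plus_one(self):
        assert bin_grid(30.0, 33.0).tolist() == [30.0, 31.0, 32.0, 33.0]
        assert bin_grid(30.0, 33.9).tolist() == [30.0, 31.0, 32.0, 33.0]


class TestPercentChangeCI:
    def test_zero_covariance_collapses_to_point(self):
        spec = _toy_spec()
        beta = np.array([0.02, 0.01, 0.0, 0.005])
        fit = _toy_fit(beta, np.zeros((4, 4)), spec)
        lo, hi = percent_change_ci(fit, spec, (28.0, 33.0), 28.0, n_draws=1000, seed=1)
        pc = fit.percent_change(28.0, 33.0, 28.0)
        assert lo == pytest.approx(pc.value, abs=1e-10)
        assert hi == pytest.approx(pc.value, abs=1e-10)

    def test_reproducible_under_fixed_seed(self, fitted_stratum):
        res = fitted_stratum["result"]
        bins = fitted_stratum["bins"]
        ref = fitted_stratum["reference"]
        a = res.percent_change_ci(bins.p60, bins.p90, ref, n_draws=1000, seed=99)
        b = res.percent_change_ci(bins.p60, bins.p90, ref, n_draws=1000, seed=99)
        assert a == b

    def test_matches_closed_form_normal_quantiles_in_one_parameter_model(self):
        # single cross-basis column: lag intercept-only, linear var basis.
        var = SplineSpec((), (0.0, 10.0))
        spec = CrossBasisSpec(0, var, None)
        sigma = 0.002
        fit = _toy_fit([0.01], [[sigma**2]], spec)
        lo, hi = percent_change_ci(fit, spec, (1.0, 3.0), 0.0, n_draws=100_000, seed=3)
        # percent change = (e^{3b} - e^{b})/2*100, monotone in b, so the CI
        # maps the normal quantiles of b through the same function.
        for bound, q in ((lo, -1.959963984540054), (hi, 1.959963984540054)):
            b = 0.01 + q * sigma
            expected = (np.exp(3 * b) - np.exp(b)) / 2 * 100
            assert bound == pytest.approx(expected, rel=1e-2)

    def test_requires_enough_draws(self, fitted_stratum):
        res = fitted_stratum["result"]
        bins = fitted_stratum["bins"]
        with pytest.raises(ValueError, match="n_draws"):
            res.percent_change_ci(bins.p60, bins.p90, fitted_stratum["reference"], n_draws=10)
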