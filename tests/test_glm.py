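"""Poisson IRLS fit, AIC, and lag-window selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import heatdlnm as h
from heatdlnm.glm import aic_of, build_confounders, fit_poisson, select_lag
from oracles import newton_poisson_mle, poisson_loglik


def _random_instance(rng, n, p):
    X = np.column_stack([np.ones(n), rng.normal(0, 0.5, (n, p - 1))])
    beta = rng.normal(0, 0.3, p)
    beta[0] = rng.uniform(0.5, 2.0)
    y = rng.poisson(np.exp(X @ beta))
    return X, y


class TestFitPoisson:
    def test_intercept_only_recovers_log_mean(self):
        res = fit_poisson(np.ones((3, 1)), [2, 4, 6])
        assert res.converged
        np.testing.assert_allclose(res.params[0], np.log(4.0), atol=1e-8)

    def test_recovers_known_coefficients_within_three_se(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(20.0, 5.0, n)
        X = np.column_stack([np.ones(n), x])
        y = rng.poisson(np.exp(2.0 + 0.05 * x))
        res = fit_poisson(X, y)
        for est, se, true in zip(res.params, res.bse, (2.0, 0.05)):
            assert abs(est - true) < 3 * se

    def test_matches_newton_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(50, 200))
            p = int(rng.integers(2, 10))
            X, y = _random_instance(rng, n, p)
            res = fit_poisson(X, y)
            beta_oracle, _ = newton_poisson_mle(X, y)
            np.testing.assert_allclose(res.params, beta_oracle, atol=1e-6)

    def test_score_vanishes_at_optimum(self):
        rng = np.random.default_rng(9)
        X, y = _random_instance(rng, 150, 5)
        res = fit_poisson(X, y)
        score = X.T @ (y - np.exp(X @ res.params))
        assert np.max(np.abs(score)) < 1e-6

    def test_covariance_matches_numerical_hessian(self):
        rng = np.random.default_rng(13)
        X, y = _random_instance(rng, 150, 4)
        res = fit_poisson(X, y)
        p = res.params.size
        eps = 1e-5
        hess = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                b = res.params.copy()
                pp = np.zeros(p)
                pp[i] += eps
                qq = np.zeros(p)
                qq[j] += eps
                hess[i, j] = (
                    poisson_loglik(b + pp + qq, X, y)
                    - poisson_loglik(b + pp - qq, X, y)
                    - poisson_loglik(b - pp + qq, X, y)
                    + poisson_loglik(b - pp - qq, X, y)
                ) / (4 * eps**2)
        se_numeric = np.sqrt(np.diag(np.linalg.inv(-hess)))
        np.testing.assert_allclose(res.bse, se_numeric, rtol=0.01)

    def test_loglik_matches_written_out_likelihood(self):
        res = fit_poisson(np.ones((3, 1)), [2, 4, 6])
        y = np.array([2.0, 4.0, 6.0])
        by_hand = np.sum(y * np.log(4.0) - 4.0 - gammaln(y + 1))
        np.testing.assert_allclose(res.loglik, by_hand, atol=1e-8)

    def test_rejects_negative_or_fractional_counts(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson(np.ones((2, 1)), [1.0, -2.0])
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson(np.ones((2, 1)), [1.5, 2.0])

    def test_quasi_poisson_inflates_covariance_only(self):
        rng = np.random.default_rng(61)
        X, _ = _random_instance(rng, 200, 3)
        # negative-binomial-ish counts: overdispersed relative to Poisson
        mu = np.exp(X @ np.array([1.5, 0.2, -0.1]))
        y = rng.poisson(mu * rng.gamma(2.0, 0.5, 200))
        plain = fit_poisson(X, y)
        qp = fit_poisson(X, y, quasi_poisson=True)
        np.testing.assert_allclose(plain.params, qp.params, atol=1e-10)
        assert (qp.bse > plain.bse).all()

    def test_rank_deficiency_names_collinear_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson(X, np.ones(10, dtype=int), column_labels=["const", "a", "a_double"])


class TestAic:
    def test_formula(self):
        res = fit_poisson(np.ones((3, 1)), [2, 4, 6])
        res.loglik = -10.0
        res.params = np.zeros(3)
        assert aic_of(res) == pytest.approx(26.0)

    def test_intercept_only_hand_evaluated(self):
        res = fit_poisson(np.ones((3, 1)), [2, 4, 6])
        y = np.array([2.0, 4.0, 6.0])
        expected = -2 * np.sum(y * np.log(4.0) - 4.0 - gammaln(y + 1)) + 2
        np.testing.assert_allclose(aic_of(res), expected, atol=1e-8)
        np.testing.assert_allclose(res.aic, expected, atol=1e-8)

    def test_pure_noise_column_never_decreases_loglik(self):
        rng = np.random.default_rng(21)
        X, y = _random_instance(rng, 120, 3)
        base = fit_poisson(X, y)
        wider = fit_poisson(np.column_stack([X, rng.normal(size=120)]), y)
        assert wider.loglik >= base.loglik - 1e-9
        assert wider.n_params == base.n_params + 1

    def test_rejects_unconverged_fit(self):
        res = fit_poisson(np.ones((3, 1)), [2, 4, 6])
        res.converged = False
        with pytest.raises(ValueError, match="unconverged"):
            aic_of(res)


class TestSelectLag:
    def test_single_candidate_returned(self, decade_weather, jja_mask, truth):
        w = decade_weather
        counts = h.simulate_death_counts(w, truth, truth.strata[0], seed=31)
        sel = select_lag([7], w["tmax"].to_numpy(), counts, fit_mask=jja_mask)
        assert sel.chosen == 7
        assert list(sel.table["max_lag"]) == [7]

    def test_tie_breaks_toward_smaller_lag(self, monkeypatch):
        # force every candidate to yield the same AIC; the smaller lag wins
        import heatdlnm.glm as glm_mod

        def fake_fit(self, tol=1e-9, maxiter=100):
            return fit_poisson(np.ones((10, 1)), np.full(10, 3))

        monkeypatch.setattr(glm_mod.PoissonDLNM, "fit", fake_fit)
        rng = np.random.default_rng(3)
        tmax = rng.uniform(20, 35, 300)
        y = rng.poisson(5.0, 300)
        sel = select_lag([7, 2], tmax, y)
        assert sel.table["aic"].nunique() == 1
        assert sel.chosen == 2

    def test_aic_table_covers_all_candidates(self, decade_weather, jja_mask, truth):
        w = decade_weather
        counts = h.simulate_death_counts(w, truth, truth.strata[0], seed=37)
        conf = build_confounders(w["date"], w["rhavg"].to_numpy(), w["prcp"].to_numpy())
        sel = select_lag([0, 3, 7], w["tmax"].to_numpy(), counts, confounders=conf, fit_mask=jja_mask)
        assert list(sel.table["max_lag"]) == [0, 3, 7]
        assert sel.table["aic"].notna().all()
        assert sel.chosen in (0, 3, 7)

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            select_lag([], np.ones(10), np.ones(10, dtype=int))


class TestCoverage:
    def test_wald_interval_coverage_in_simulation(self):
        """95% Wald intervals cover the true coefficient at a nominal-ish
        rate across replicated Poisson regressions."""
        rng = np.random.default_rng(55)
        n, true = 400, 0.08
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1.0, n)
            y = rng.poisson(np.exp(1.0 + true * x))
            res = fit_poisson(np.column_stack([np.ones(n), x]), y)
            lo = res.params[1] - 1.96 * res.bse[1]
            hi = res.params[1] + 1.96 * res.bse[1]
            hits += lo <= true <= hi
        assert 0.90 <= hits / reps <= 0.98


class TestSummary:
    def test_summary_table_shape_and_labels(self, fitted_stratum):
        res = fitted_stratum["result"]
        tab = res.summary()
        assert isinstance(tab, pd.DataFrame)
        assert list(tab.columns) == ["coef", "std_err", "z", "p_value", "ci_low", "ci_high"]
        assert len(tab) == res.n_params
        assert (tab["std_err"] >= 0).all()
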