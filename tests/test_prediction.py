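"""Wall-model regression fits, bootstrap ensembles and prediction metrics."""

import numpy as np
import pytest

from wallmap.atlas import CohortMapSet
from wallmap.prediction import (
    evaluate_prediction,
    fit_bootstrap_regressions,
    fit_wt_regression,
    max_wall_thickness,
    predict_wt_map,
)


def _simulate(beta, n=500, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    wss = rng.uniform(0.5, 3.0, n)
    d = rng.uniform(3.0, 8.0, n)
    wt = beta[0] + beta[1] * wss + beta[2] * d + beta[3] * wss * d
    wt = wt + noise * rng.normal(size=n)
    return wt, wss, d


class TestFitRegression:
    def test_noiseless_recovery_exact(self):
        beta = (0.8, -0.3, 0.05, 0.02)
        wt, wss, d = _simulate(beta)
        fit = fit_wt_regression(wt, wss, d)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.nanmax(np.abs(fit.residual_map)) < 1e-9

    def test_reduced_model_on_exact_line(self):
        rng = np.random.default_rng(0)
        wss = rng.uniform(0, 2, 100)
        wt = 2.0 - wss
        fit = fit_wt_regression(wt, wss, np.ones_like(wss) * 5.0, terms=("WSS",))
        assert fit.beta[0] == pytest.approx(2.0)
        assert fit.beta[1] == pytest.approx(-1.0)
        assert fit.beta[2] == fit.beta[3] == 0.0
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        # brute-force (X'X)^-1 X'y on random 200-vertex problems
        for _ in range(5):
            wt, wss, d = _simulate((1.0, -0.2, 0.04, 0.01), n=200,
                                   noise=0.1, seed=int(rng.integers(2**31)))
            fit = fit_wt_regression(wt, wss, d)
            x = np.column_stack([np.ones_like(wss), wss, d, wss * d])
            oracle = np.linalg.solve(x.T @ x, x.T @ wt)
            np.testing.assert_allclose(fit.beta, oracle, rtol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        wt, wss, d = _simulate((1.0, -0.2, 0.04, 0.01), n=300, noise=0.15, seed=3)
        fit = fit_wt_regression(wt, wss, d)
        x = sm.add_constant(np.column_stack([wss, d, wss * d]))
        ols = sm.OLS(wt, x).fit()
        np.testing.assert_allclose(fit.beta, ols.params, rtol=1e-8)
        assert fit.r_squared == pytest.approx(ols.rsquared, rel=1e-8)

    def test_estimates_within_three_se_mostly(self):
        # OLS sampling-distribution check: |beta_hat - beta| <= 3 SE nearly always
        beta = np.array([1.0, -0.2, 0.04, 0.01])
        hits = 0
        trials = 40
        for seed in range(trials):
            wt, wss, d = _simulate(beta, n=5000, noise=0.2, seed=seed)
            fit = fit_wt_regression(wt, wss, d)
            x = np.column_stack([np.ones_like(wss), wss, d, wss * d])
            resid = wt - x @ fit.beta
            sigma2 = resid @ resid / (len(wt) - 4)
            se = np.sqrt(np.diag(sigma2 * np.linalg.inv(x.T @ x)))
            hits += int(np.all(np.abs(fit.beta - beta) <= 3 * se))
        assert hits >= int(0.95 * trials)

    def test_collinear_design_rejected_naming_term(self):
        rng = np.random.default_rng(0)
        wss = np.full(100, 1.5)  # constant WSS: collinear with intercept
        d = rng.uniform(3, 8, 100)
        wt = 1.0 + 0.05 * d
        with pytest.raises(ValueError, match="WSS"):
            fit_wt_regression(wt, wss, d, terms=("WSS", "D"))

    def test_missing_rows_excluded(self):
        wt, wss, d = _simulate((0.8, -0.3, 0.05, 0.02), n=50)
        wt[3] = np.nan
        fit = fit_wt_regression(wt, wss, d)
        assert fit.n_used == 49
        assert np.isnan(fit.residual_map[3])

    def test_nesting_r_squared(self):
        wt, wss, d = _simulate((1.0, -0.2, 0.04, 0.01), n=400, noise=0.3, seed=9)
        full = fit_wt_regression(wt, wss, d).r_squared
        for terms in (("WSS",), ("D",), ("WSS*D",)):
            assert full >= fit_wt_regression(wt, wss, d, terms=terms).r_squared - 1e-12


class TestBootstrapRegression:
    def _mapset(self, n_subj=6, n_vert=300, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        wss0 = rng.uniform(0.5, 3.0, n_vert)
        d0 = rng.uniform(3.0, 8.0, n_vert)
        beta = (1.0, -0.2, 0.04, 0.01)
        wss = np.tile(wss0, (n_subj, 1))
        d = np.tile(d0, (n_subj, 1))
        wt = beta[0] + beta[1] * wss + beta[2] * d + beta[3] * wss * d
        wt = wt + noise * rng.normal(size=wt.shape)
        return CohortMapSet(shared=None, matrices={"WT": wt, "WSS": wss, "D": d}), beta

    def test_identical_subjects_give_zero_width_ci(self):
        ms, beta = self._mapset(noise=0.0)
        ens = fit_bootstrap_regressions(ms, B=30, seed=1)
        np.testing.assert_allclose(ens.betas - ens.betas[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(ens.ci95[:, 0], ens.ci95[:, 1], atol=1e-12)
        np.testing.assert_allclose(ens.mean_beta, beta, atol=1e-9)

    def test_noisy_cohort_recovers_beta(self):
        # parameter-recovery simulation: mean estimates close to truth and
        # the 95% CIs cover it in the vast majority of instances
        covered = 0
        trials = 8
        for seed in range(trials):
            ms, beta = self._mapset(n_subj=15, n_vert=800, noise=0.2, seed=seed)
            ens = fit_bootstrap_regressions(ms, B=200, seed=seed + 100)
            assert abs(ens.mean_beta[0] - beta[0]) / abs(beta[0]) < 0.10
            assert abs(ens.mean_beta[1] - beta[1]) / abs(beta[1]) < 0.10
            covered += int(
                all(ens.ci95[k, 0] <= beta[k] <= ens.ci95[k, 1] for k in (0, 1))
            )
        assert covered >= trials - 2

    def test_bit_identical_across_runs(self):
        ms, _ = self._mapset(noise=0.1, seed=8)
        e1 = fit_bootstrap_regressions(ms, B=50, seed=11)
        e2 = fit_bootstrap_regressions(ms, B=50, seed=11)
        np.testing.assert_array_equal(e1.betas, e2.betas)

    def test_shares_multisets_with_correlation_bootstrap(self):
        from wallmap.stats import bootstrap_multisets

        ms, _ = self._mapset(noise=0.1, seed=8)
        # same seed -> same multisets drive both bootstrap analyses
        m1 = bootstrap_multisets(ms.n_subjects, 25, 13)
        m2 = bootstrap_multisets(ms.n_subjects, 25, 13)
        np.testing.assert_array_equal(m1, m2)


class TestPrediction:
    def test_constant_beta_constant_map(self):
        pred, n_neg = predict_wt_map(np.ones(10), np.ones(10), np.array([1.0, 0, 0, 0]))
        np.testing.assert_allclose(pred, 1.0)
        assert n_neg == 0

    def test_own_beta_residual_identity(self):
        wt, wss, d = _simulate((0.8, -0.3, 0.05, 0.02), n=200, noise=0.2, seed=5)
        fit = fit_wt_regression(wt, wss, d)
        pred, _ = predict_wt_map(wss, d, fit.beta)
        np.testing.assert_allclose(wt - pred, fit.residual_map, atol=1e-10)

    def test_negative_predictions_retained_and_counted(self):
        pred, n_neg = predict_wt_map(
            np.array([10.0, 0.1]), np.array([1.0, 1.0]), np.array([1.0, -1.1, 0.0, 0.0])
        )
        assert pred[0] == pytest.approx(-10.0)
        assert pred[1] > 0
        assert n_neg == 1

    def test_non_finite_beta_rejected(self):
        with pytest.raises(ValueError):
            predict_wt_map(np.ones(5), np.ones(5), np.array([np.nan, 0, 0, 0]))

    def test_cohort_beta_predicts_held_out_subject(self):
        beta = (1.0, -0.2, 0.04, 0.01)
        wt, wss, d = _simulate(beta, n=2000, noise=0.05, seed=77)
        pred, _ = predict_wt_map(wss, d, np.asarray(beta))
        ev = evaluate_prediction(wt, pred)
        assert ev.spearman_rho > 0.9


class TestEvaluation:
    def test_identity_maps(self):
        v = np.linspace(0.5, 2.0, 50)
        ev = evaluate_prediction(v, v.copy())
        assert ev.spearman_rho == pytest.approx(1.0)
        assert ev.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert ev.loa == pytest.approx(0.0, abs=1e-12)
        assert ev.max_wt_original == ev.max_wt_predicted

    def test_constant_shift(self):
        v = np.linspace(0.5, 2.0, 50)
        ev = evaluate_prediction(v, v + 0.5)
        assert ev.mean_difference == pytest.approx(0.5)
        assert ev.loa == pytest.approx(0.0, abs=1e-9)
        assert ev.spearman_rho == pytest.approx(1.0)

    def test_top_five_percent_max_wt(self):
        values = np.arange(1.0, 101.0)
        assert max_wall_thickness(values) == pytest.approx(98.0)

    def test_constant_maps_give_undefined_rho(self):
        with pytest.warns(UserWarning, match="constant"):
            ev = evaluate_prediction(np.full(10, 1.0), np.full(10, 2.0))
        assert np.isnan(ev.spearman_rho)
        assert ev.mean_difference == pytest.approx(1.0)

    def test_loa_is_1_96_sd_of_differences(self, rng):
        orig = rng.uniform(0.5, 2.0, 300)
        pred = orig + rng.normal(0.1, 0.3, 300)
        ev = evaluate_prediction(orig, pred)
        diff = pred - orig
        assert ev.loa == pytest.approx(1.96 * diff.std(ddof=1))
        assert ev.mean_difference == pytest.approx(diff.mean())
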