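"""Likelihood, fitting and inference checks for the two-cause regression."""

import math

import numpy as np
import pandas as pd
import pytest

import gomprisk as gk
from gomprisk import CauseModel, GompertzParams
from gomprisk.cohort import generate_cohort
from gomprisk import model as mdl

from conftest import RECOVERY_TRUTH_VECTOR, recovery_config, recovery_truth
from oracles import competing_loglik, gompertz_plateau

# fixed 5-record toy set: 3 deaths, 1 transplant, 1 censored
TOY = pd.DataFrame({
    "time": [0.7, 1.4, 2.9, 1.1, 3.6],
    "event": [1, 1, 1, 2, 0],
    "age": [61.0, 72.5, 55.0, 48.0, 67.0],
    "male": [1.0, 0.0, 1.0, 1.0, 0.0],
})
TOY_CM1 = CauseModel(GompertzParams(1.3, -0.5, 0.22), ("age", "male"),
                     np.array([0.02, 0.4]))
TOY_CM2 = CauseModel(GompertzParams(0.9, -0.7, 0.12), ("age", "male"),
                     np.array([-0.03, 0.25]))


def _toy_oracle_value():
    records = [(r.time, r.event, {"age": r.age, "male": r.male})
               for r in TOY.itertuples()]
    c1 = {"theta": 1.3, "gamma": -0.5, "lam": 0.22,
          "beta": {"age": 0.02, "male": 0.4}}
    c2 = {"theta": 0.9, "gamma": -0.7, "lam": 0.12,
          "beta": {"age": -0.03, "male": 0.25}}
    return competing_loglik(records, c1, c2)


class TestLogLikelihood:
    def test_matches_term_by_term_oracle(self):
        assert gk.log_likelihood(TOY, TOY_CM1, TOY_CM2) == pytest.approx(
            _toy_oracle_value(), abs=1e-10)

    def test_record_order_invariance(self):
        shuffled = TOY.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert gk.log_likelihood(shuffled, TOY_CM1, TOY_CM2) == pytest.approx(
            gk.log_likelihood(TOY, TOY_CM1, TOY_CM2), abs=1e-12)

    def test_censored_near_zero_contributes_nothing(self):
        df = pd.DataFrame({"time": [1e-12], "event": [0],
                           "age": [60.0], "male": [1.0]})
        assert gk.log_likelihood(df, TOY_CM1, TOY_CM2) == pytest.approx(0.0, abs=1e-9)

    def test_input_validation(self):
        bad_time = TOY.assign(time=[0.7, -1.0, 2.9, 1.1, 3.6])
        with pytest.raises(ValueError):
            gk.log_likelihood(bad_time, TOY_CM1, TOY_CM2)
        bad_cov = TOY.assign(age=[61.0, np.nan, 55.0, 48.0, 67.0])
        with pytest.raises(ValueError):
            gk.log_likelihood(bad_cov, TOY_CM1, TOY_CM2)


class TestCauseCdf:
    def test_zero_covariates_equal_baseline(self):
        t = np.linspace(0, 5, 20)
        np.testing.assert_allclose(
            gk.cause_cdf(t, np.zeros(2), TOY_CM1),
            gk.cdf(t, TOY_CM1.baseline), atol=1e-14)

    def test_null_effects_equal_baseline(self):
        cm = CauseModel(TOY_CM1.baseline, ("age", "male"), np.zeros(2))
        t = np.linspace(0, 5, 20)
        np.testing.assert_allclose(gk.cause_cdf(t, np.array([70.0, 1.0]), cm),
                                   gk.cdf(t, TOY_CM1.baseline), atol=1e-14)

    def test_log2_effect_doubles_exponential_rate(self):
        cm = CauseModel(GompertzParams(1.0, 0.0, 0.3), ("x",),
                        np.array([math.log(2.0)]))
        t = np.linspace(0, 6, 30)
        expected = 1.0 - np.exp(-0.6 * t)
        np.testing.assert_allclose(gk.cause_cdf(t, np.array([1.0]), cm),
                                   expected, atol=1e-12)


class TestOverallSurvival:
    def test_one_at_origin(self):
        assert gk.overall_survival(0.0, np.zeros(2), TOY_CM1, TOY_CM2) == 1.0

    def test_symmetric_causes(self):
        t = np.linspace(0, 5, 10)
        S = gk.overall_survival(t, np.zeros(2), TOY_CM1, TOY_CM1)
        np.testing.assert_allclose(S, 1 - 2 * gk.cdf(t, TOY_CM1.baseline), atol=1e-12)

    def test_limit_is_one_minus_total_plateau(self):
        S_inf = gk.overall_survival(500.0, np.zeros(2), TOY_CM1, TOY_CM2)
        expect = 1.0 - gompertz_plateau(1.3, -0.5, 0.22) - gompertz_plateau(0.9, -0.7, 0.12)
        assert S_inf == pytest.approx(expect, abs=1e-9)

    def test_identity_cif_plus_survival(self):
        t = np.linspace(0, 10, 50)
        x = np.array([62.0, 1.0])
        F1 = gk.cause_cdf(t, x, TOY_CM1)
        F2 = gk.cause_cdf(t, x, TOY_CM2)
        S = gk.overall_survival(t, x, TOY_CM1, TOY_CM2)
        np.testing.assert_allclose(F1 + F2 + S, 1.0, atol=1e-12)


class TestValidityCheck:
    def test_two_proper_causes_fail(self):
        a = CauseModel(GompertzParams(1.0, 0.1, 0.2))
        worst, ok = gk.validity_check(a, a)
        assert worst == pytest.approx(2.0) and not ok

    def test_known_plateaus_pass(self):
        # theta=1, gamma=-1: plateau = 1 - exp(-lam), so lam = -ln(1 - p)
        def with_plateau(p):
            return CauseModel(GompertzParams(1.0, -1.0, -math.log(1.0 - p)))
        worst, ok = gk.validity_check(with_plateau(0.5), with_plateau(0.4))
        assert worst == pytest.approx(0.9, abs=1e-12) and ok

    def test_empty_design_checks_baseline_only(self):
        worst, ok = gk.validity_check(TOY_CM1, TOY_CM2, pd.DataFrame())
        base = (gompertz_plateau(1.3, -0.5, 0.22) + gompertz_plateau(0.9, -0.7, 0.12))
        assert worst == pytest.approx(base, abs=1e-12) and ok


@pytest.fixture(scope="module")
def recovery_fit():
    df = generate_cohort(recovery_config(3000, seed=11))
    return df, gk.fit_mle(df, ("x",), ("x",), multistart=2, seed=0)


@pytest.fixture(scope="module")
def mid_fit():
    df = generate_cohort(recovery_config(1500, seed=5))
    return gk.fit_mle(df, ("x",), ("x",), multistart=1, seed=0)


class TestFitMle:
    def test_estimates_within_3_se_of_truth(self, recovery_fit):
        _, fit = recovery_fit
        assert fit.converged and fit.covariance is not None
        se = np.sqrt(np.diag(fit.covariance))
        for i, name in enumerate(fit.param_names):
            z = (fit.estimates[i] - RECOVERY_TRUTH_VECTOR[name]) / se[i]
            assert abs(z) < 3.0, f"{name}: z = {z:.2f}"

    def test_optimum_at_least_truth_loglik(self, recovery_fit):
        df, fit = recovery_fit
        cm1, cm2 = recovery_truth()
        assert fit.loglik >= gk.log_likelihood(df, cm1, cm2) - 1e-6

    def test_duplicated_data_scaling(self, recovery_fit):
        df, fit = recovery_fit
        doubled = pd.concat([df, df], ignore_index=True)
        fit2 = gk.fit_mle(doubled, ("x",), ("x",), multistart=1, seed=0)
        np.testing.assert_allclose(fit2.estimates, fit.estimates, atol=5e-4)
        assert fit2.loglik == pytest.approx(2.0 * fit.loglik, rel=1e-6)
        ratio = np.sqrt(np.diag(fit2.covariance) / np.diag(fit.covariance))
        np.testing.assert_allclose(ratio, 1.0 / math.sqrt(2.0), atol=0.02)

    def test_needs_events_of_both_causes(self):
        df = TOY[TOY["event"] != 2]
        with pytest.raises(ValueError):
            gk.fit_mle(df, ("age",), ("age",))

    def test_complete_case_dropping_counted(self, recovery_fit):
        df, _ = recovery_fit
        df2 = df.copy()
        df2.loc[df2.index[:5], "x"] = np.nan
        fit = gk.fit_mle(df2, ("x",), ("x",), multistart=1, seed=0)
        assert fit.n_dropped == 5 and fit.n_used == len(df) - 5

    def test_covariate_rescaling_equivariance(self, recovery_fit):
        df, fit = recovery_fit
        b = 2.5
        df2 = df.assign(x=(df["x"] - 1.0) / b)
        fit2 = gk.fit_mle(df2, ("x",), ("x",), multistart=1, seed=0)
        i = fit.index_of("cause1:x")
        assert fit2.estimates[i] == pytest.approx(b * fit.estimates[i], rel=5e-3)
        # fitted incidence at matching profiles is unchanged
        F_orig = gk.cause_cdf(2.0, np.array([1.5]), fit.cause_model(1))
        F_resc = gk.cause_cdf(2.0, np.array([(1.5 - 1.0) / b]), fit2.cause_model(1))
        assert F_resc == pytest.approx(F_orig, abs=2e-3)

    def test_gradient_norm_small_at_optimum(self, recovery_fit):
        df, fit = recovery_fit
        from gomprisk.model import _loglik_vector, _unpack
        t = df["time"].to_numpy()
        ev = df["event"].to_numpy().astype(int)
        X = df[["x"]].to_numpy()

        def negll(x):
            return -np.sum(_loglik_vector(t, ev, X, X, *_unpack(x, 1, 1)))

        g = np.zeros(fit.estimates.size)
        h = 1e-6
        for i in range(g.size):
            e = np.zeros_like(g)
            e[i] = h
            g[i] = (negll(fit.estimates + e) - negll(fit.estimates - e)) / (2 * h)
        assert np.linalg.norm(g) < 1e-4


class TestWaldInference:
    def test_wider_level_contains_narrower(self, mid_fit):
        lo = gk.wald_ci(mid_fit, "cause1:x", 0.75)
        hi = gk.wald_ci(mid_fit, "cause1:x", 0.90)
        assert hi.beta_lo < lo.beta_lo and hi.beta_hi > lo.beta_hi

    def test_shr_endpoints_are_exp_of_beta_endpoints(self, mid_fit):
        ci = gk.wald_ci(mid_fit, "cause2:x", 0.90)
        assert ci.shr_lo == pytest.approx(math.exp(ci.beta_lo), rel=1e-12)
        assert ci.shr_hi == pytest.approx(math.exp(ci.beta_hi), rel=1e-12)

    def test_unknown_name_rejected(self, mid_fit):
        with pytest.raises(KeyError):
            gk.wald_ci(mid_fit, "cause1:nonexistent", 0.9)

    def test_table_consistent_with_wald_ci(self, mid_fit):
        tab = gk.shr_table(mid_fit, levels=(0.75, 0.90))
        assert {"ci75_lo", "ci75_hi", "ci90_lo", "ci90_hi"} <= set(tab.columns)
        row = tab[(tab.cause == 1) & (tab.variable == "x")].iloc[0]
        ci = gk.wald_ci(mid_fit, "cause1:x", 0.90)
        assert row["shr"] == pytest.approx(ci.shr, rel=1e-12)
        assert row["ci90_lo"] == pytest.approx(ci.shr_lo, rel=1e-12)
        assert row["p"] == pytest.approx(ci.p, rel=1e-12)

    def test_null_effect_interval_covers_one(self):
        cfg = recovery_config(1200, seed=21)
        import dataclasses
        cm1 = CauseModel(cfg.cause1.baseline, ("x",), np.zeros(1))
        cfg = dataclasses.replace(cfg, cause1=cm1)
        df = generate_cohort(cfg)
        fit = gk.fit_mle(df, ("x",), ("x",), multistart=1, seed=0)
        ci = gk.wald_ci(fit, "cause1:x", 0.90)
        assert ci.shr_lo < 1.0 < ci.shr_hi
        assert ci.shr == pytest.approx(1.0, abs=0.15)


class TestCifCurve:
    def test_zero_at_origin(self, mid_fit):
        F1, F2 = gk.cif_curve(mid_fit, {"x": 0.0}, np.array([0.0]))
        assert F1[0] == 0.0 and F2[0] == 0.0

    def test_monotone_and_subadditive_on_dense_grid(self, mid_fit):
        times = np.linspace(0.0, 40.0, 1000)
        F1, F2 = gk.cif_curve(mid_fit, {"x": 0.5}, times)
        assert np.all(np.diff(F1) >= -1e-12)
        assert np.all(np.diff(F2) >= -1e-12)
        assert np.all(F1 + F2 <= 1.0 + 1e-9)
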