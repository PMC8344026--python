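"""Closed-form, quadrature and sampling checks of the generalized Gompertz."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import gomprisk as gk
from gomprisk.gompertz import GompertzParams

from oracles import gompertz_cdf, gompertz_pdf, gompertz_plateau

P_IMPROPER = GompertzParams(theta=2.0, gamma=-0.5, lam=1.0)
P_EXP = GompertzParams(theta=1.0, gamma=0.0, lam=math.log(2))


params_strategy = st.builds(
    GompertzParams,
    theta=st.floats(0.2, 5.0),
    gamma=st.floats(-2.0, 1.0),
    lam=st.floats(0.05, 3.0),
)


class TestConstructor:
    @pytest.mark.parametrize("kwargs", [
        dict(theta=0.0, gamma=0.1, lam=1.0),
        dict(theta=-1.0, gamma=0.1, lam=1.0),
        dict(theta=1.0, gamma=0.1, lam=0.0),
        dict(theta=1.0, gamma=math.nan, lam=1.0),
        dict(theta=1.0, gamma=0.1, lam=math.inf),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GompertzParams(**kwargs)


class TestCdf:
    def test_zero_at_origin(self):
        assert gk.cdf(0.0, P_IMPROPER) == 0.0
        assert gk.cdf(0.0, P_EXP) == 0.0

    def test_exponential_median(self):
        assert gk.cdf(1.0, P_EXP) == pytest.approx(0.5, abs=1e-12)

    def test_matches_independent_closed_form(self):
        # independent scalar evaluation, cross-checked by quadrature of pdf
        expected = gompertz_cdf(2.0, 2.0, -0.5, 1.0)
        by_quad, err = integrate.quad(lambda t: gk.pdf(t, P_IMPROPER), 0.0, 2.0)
        assert gk.cdf(2.0, P_IMPROPER) == pytest.approx(expected, abs=1e-12)
        assert gk.cdf(2.0, P_IMPROPER) == pytest.approx(by_quad, abs=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gk.cdf(-0.1, P_EXP)

    @pytest.mark.parametrize("T", [1.0, 5.0, 50.0])
    def test_quadrature_of_pdf_reproduces_cdf(self, T):
        val, _ = integrate.quad(lambda t: gk.pdf(t, P_IMPROPER), 0.0, T, limit=200)
        assert val == pytest.approx(gk.cdf(T, P_IMPROPER), abs=1e-8)

    def test_branch_continuity_at_small_gamma(self):
        t = np.linspace(0.0, 10.0, 101)
        lo = GompertzParams(1.7, 1e-8, 0.4)
        exact = GompertzParams(1.7, 0.0, 0.4)
        assert np.max(np.abs(gk.cdf(t, lo) - gk.cdf(t, exact))) < 1e-6

    def test_two_parameter_gompertz_reduction(self):
        # theta=1, gamma>0 is the classical Gompertz; scipy parameterizes it
        # as cdf(x) = 1 - exp(-c (e^x - 1)) with x = gamma*t, c = lam/gamma
        p = GompertzParams(1.0, 0.7, 0.3)
        t = np.linspace(0.0, 8.0, 50)
        ref = stats.gompertz.cdf(t, c=p.lam / p.gamma, scale=1.0 / p.gamma)
        np.testing.assert_allclose(gk.cdf(t, p), ref, atol=1e-12)


class TestPdf:
    def test_exponential_density_at_origin(self):
        p = GompertzParams(1.0, 0.0, 2.0)
        assert gk.pdf(0.0, p) == pytest.approx(2.0, abs=1e-12)

    def test_integrates_to_plateau(self):
        val, _ = integrate.quad(lambda t: gk.pdf(t, P_IMPROPER), 0.0, np.inf, limit=200)
        assert val == pytest.approx(gk.plateau(P_IMPROPER), abs=1e-6)

    def test_matches_cdf_derivative(self):
        h = 1e-5
        fd = (gk.cdf(1.3 + h, P_IMPROPER) - gk.cdf(1.3 - h, P_IMPROPER)) / (2 * h)
        assert gk.pdf(1.3, P_IMPROPER) == pytest.approx(fd, abs=1e-6)

    def test_matches_independent_scalar_form(self):
        for t in (0.2, 1.0, 3.5):
            assert gk.pdf(t, P_IMPROPER) == pytest.approx(
                gompertz_pdf(t, 2.0, -0.5, 1.0), rel=1e-12)


class TestPlateau:
    def test_proper_when_gamma_nonnegative(self):
        assert gk.plateau(GompertzParams(3.0, 0.1, 0.5)) == 1.0
        assert gk.plateau(GompertzParams(0.5, 0.0, 2.0)) == 1.0

    def test_improper_values(self):
        assert gk.plateau(GompertzParams(1.0, -0.5, 1.0)) == pytest.approx(
            gompertz_plateau(1.0, -0.5, 1.0), abs=1e-14)
        assert gk.plateau(GompertzParams(2.0, -1.0, 1.0)) == pytest.approx(
            (1.0 - math.exp(-1.0)) ** 2, abs=1e-14)

    def test_cdf_bounded_by_plateau_on_grid(self):
        t = np.linspace(0.0, 200.0, 2001)
        F = gk.cdf(t, P_IMPROPER)
        assert np.all(np.diff(F) >= -1e-15)
        assert F[-1] <= gk.plateau(P_IMPROPER) + 1e-12
        assert F[-1] == pytest.approx(gk.plateau(P_IMPROPER), abs=1e-9)


class TestQuantile:
    def test_zero(self):
        assert gk.quantile(0.0, P_IMPROPER) == 0.0

    def test_exponential_median(self):
        assert gk.quantile(0.5, P_EXP) == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip(self):
        p = GompertzParams(1.5, 0.4, 0.3)
        for t in (0.1, 1.0, 5.0):
            assert gk.quantile(gk.cdf(t, p), p) == pytest.approx(t, abs=1e-8)

    def test_cdf_of_quantile_identity(self):
        u = np.linspace(0.0, 0.999, 200) * gk.plateau(P_IMPROPER)
        t = gk.quantile(u, P_IMPROPER)
        np.testing.assert_allclose(gk.cdf(t, P_IMPROPER), u, atol=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gk.quantile(-0.1, P_EXP)
        with pytest.raises(ValueError):
            gk.quantile(gk.plateau(P_IMPROPER), P_IMPROPER)  # no finite quantile


class TestSample:
    def test_empty(self):
        assert gk.sample(P_IMPROPER, 0, np.random.default_rng(0)).size == 0

    def test_proper_regime_has_no_never(self):
        s = gk.sample(GompertzParams(1.0, 0.2, 0.5), 5000, np.random.default_rng(1))
        assert np.all(np.isfinite(s))

    def test_reproducible_under_seed(self):
        a = gk.sample(P_IMPROPER, 100, np.random.default_rng(42))
        b = gk.sample(P_IMPROPER, 100, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_ks_against_conditional_cdf(self):
        rng = np.random.default_rng(2024)
        s = gk.sample(P_IMPROPER, 10_000, rng)
        finite = s[np.isfinite(s)]
        pl = gk.plateau(P_IMPROPER)
        res = stats.kstest(finite, lambda t: gk.cdf(t, P_IMPROPER) / pl)
        crit_1pct = 1.628 / math.sqrt(finite.size)
        assert res.statistic < crit_1pct

    def test_never_fraction_within_3_binomial_se(self):
        rng = np.random.default_rng(7)
        n = 20_000
        s = gk.sample(P_IMPROPER, n, rng)
        p_never = 1.0 - gk.plateau(P_IMPROPER)
        frac = np.mean(~np.isfinite(s))
        se = math.sqrt(p_never * (1 - p_never) / n)
        assert abs(frac - p_never) < 3 * se


class TestSubdistributionHazard:
    def test_exponential_constant_hazard(self):
        p = GompertzParams(1.0, 0.0, 0.7)
        for t in (0.0, 1.0, 10.0):
            assert gk.subdistribution_hazard(t, p) == pytest.approx(0.7, abs=1e-12)

    def test_matches_direct_ratio(self):
        expect = gompertz_pdf(1.0, 2.0, -0.5, 1.0) / (1 - gompertz_cdf(1.0, 2.0, -0.5, 1.0))
        assert gk.subdistribution_hazard(1.0, P_IMPROPER) == pytest.approx(expect, rel=1e-12)

    def test_nonnegative_on_grid(self):
        t = np.linspace(0.0, 10.0, 500)
        assert np.all(gk.subdistribution_hazard(t, P_IMPROPER) >= 0.0)


class TestProperties:
    @given(p=params_strategy, t=st.floats(0.0, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_cdf_in_valid_range(self, p, t):
        F = gk.cdf(t, p)
        assert 0.0 <= F <= gk.plateau(p) + 1e-12

    @given(p=params_strategy, t=st.floats(0.001, 30.0))
    @settings(max_examples=200, deadline=None)
    def test_quantile_inverts_cdf(self, p, t):
        u = gk.cdf(t, p)
        if u < gk.plateau(p) * (1 - 1e-9) and u > 0:
            assert gk.quantile(u, p) == pytest.approx(t, rel=1e-6, abs=1e-8)

    @given(p=params_strategy)
    @settings(max_examples=100, deadline=None)
    def test_exponential_reduction_at_theta_one_gamma_zero(self, p):
        q = GompertzParams(1.0, 0.0, p.lam)
        t = np.linspace(0.0, 10.0, 11)
        np.testing.assert_allclose(gk.cdf(t, q), stats.expon.cdf(t, scale=1 / p.lam),
                                   atol=1e-10)
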