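import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from psmforge import fixtures as fx
from psmforge.errors import InvalidParameterError
from psmforge.km_reconstruct import IPDSet
from psmforge.surv_models import (FAMILIES, ParametricCurve, censored_loglik,
                                  evaluate, fit_menu, fit_parametric)

# admissible parameter strategies per family (kept well inside the domain
# so numerics stay clean)
PARAM_STRATEGIES = {
    "exponential": st.tuples(st.floats(0.01, 2.0)),
    "weibull": st.tuples(st.floats(0.3, 4.0), st.floats(0.5, 50.0)),
    "gamma": st.tuples(st.floats(0.3, 6.0), st.floats(0.01, 2.0)),
    "log-logistic": st.tuples(st.floats(0.5, 5.0), st.floats(0.5, 50.0)),
    "log-normal": st.tuples(st.floats(-1.0, 4.0), st.floats(0.2, 2.0)),
    "gompertz": st.tuples(st.floats(-0.1, 0.2), st.floats(0.005, 0.5)),
    "generalized-gamma": st.tuples(st.floats(-1.0, 4.0), st.floats(0.3, 2.0),
                                   st.floats(-2.0, 2.0)),
    "generalized-F": st.tuples(st.floats(-1.0, 4.0), st.floats(0.3, 2.0),
                               st.floats(-1.5, 1.5), st.floats(0.05, 3.0)),
}


class TestCensoredLoglik:
    def test_exponential_closed_form(self, toy_exp_ipd):
        # sum ln f = 4 ln(lambda) - lambda * 10
        lam = 0.4
        got = censored_loglik("exponential", [lam], toy_exp_ipd)
        assert got == pytest.approx(4 * np.log(lam) - 10 * lam, abs=1e-12)
        assert got == pytest.approx(-7.66516292749662, abs=1e-10)

    def test_censoring_contributes_logsf(self, toy_exp_ipd):
        lam = 0.3
        cens = IPDSet(time=toy_exp_ipd.time, event=np.zeros(4, int))
        assert censored_loglik("exponential", [lam], cens) == pytest.approx(
            -lam * 10, abs=1e-12)

    def test_weibull_shape_one_is_exponential(self, weibull_arm):
        a = censored_loglik("weibull", [1.0, 5.0], weibull_arm)
        b = censored_loglik("exponential", [1.0 / 5.0], weibull_arm)
        assert a == pytest.approx(b, abs=1e-9)

    def test_domain_error_not_nan(self, toy_exp_ipd):
        with pytest.raises(InvalidParameterError):
            censored_loglik("exponential", [-1.0], toy_exp_ipd)
        with pytest.raises(InvalidParameterError):
            censored_loglik("weibull", [1.0], toy_exp_ipd)


@pytest.fixture(scope="module")
def data():
    return fx.simulate_arm("weibull", [1.2, 15.0], 300, 1.0, 40.0, rng=9)


class TestNesting:
    """Generalized gamma reduces exactly to Weibull / gamma / log-normal."""

    def test_q1_is_weibull(self, data):
        mu, sigma = 2.5, 0.8
        a = censored_loglik("generalized-gamma", [mu, sigma, 1.0], data)
        b = censored_loglik("weibull", [1.0 / sigma, np.exp(mu)], data)
        assert a == pytest.approx(b, abs=1e-6)

    def test_q_eq_sigma_is_gamma(self, data):
        mu, sigma = 2.5, 0.8
        a = censored_loglik("generalized-gamma", [mu, sigma, sigma], data)
        b = censored_loglik("gamma",
                            [sigma**-2, np.exp(-mu) * sigma**-2], data)
        assert a == pytest.approx(b, abs=1e-6)

    def test_q0_is_lognormal(self, data):
        mu, sigma = 2.5, 0.8
        a = censored_loglik("generalized-gamma", [mu, sigma, 0.0], data)
        b = censored_loglik("log-normal", [mu, sigma], data)
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("q", [0.7, -0.7])
    def test_genf_limit_is_gengamma(self, data, q):
        mu, sigma = 2.5, 0.8
        a = censored_loglik("generalized-F", [mu, sigma, q, 1e-7], data)
        b = censored_loglik("generalized-gamma", [mu, sigma, q], data)
        assert a == pytest.approx(b, rel=1e-5)


class TestFitParametric:
    def test_exponential_mle_closed_form(self, toy_exp_ipd):
        m = fit_parametric(toy_exp_ipd, "exponential")
        assert m.params["rate"] == pytest.approx(0.4, abs=1e-15)
        assert m.aic == pytest.approx(2 - 2 * (-7.66516292749662), abs=1e-9)
        assert m.converged

    def test_weibull_parameter_recovery(self):
        ipd = fx.simulate_arm("weibull", [1.3, 20.0], 2000, 1.0, 26.0, rng=17)
        assert 0.6 < ipd.n_events / ipd.n < 0.8  # ~30% censoring
        m = fit_parametric(ipd, "weibull")
        assert m.converged
        assert m.params["shape"] == pytest.approx(1.3, abs=0.1)

    def test_requires_an_event(self):
        ipd = IPDSet(time=np.array([1.0, 2.0]), event=np.array([0, 0]))
        with pytest.raises(InvalidParameterError):
            fit_parametric(ipd, "weibull")

    def test_genf_few_events_warns(self):
        ipd = IPDSet(time=np.arange(1.0, 21.0),
                     event=np.r_[np.ones(5, int), np.zeros(15, int)])
        m = fit_parametric(ipd, "generalized-F")
        assert any("events" in w for w in m.warnings)

    def test_time_scaling_invariance(self, weibull_arm):
        # scaling all times by c rescales the scale parameter by c, leaves
        # the shape alone, and shifts loglik by -n_events ln c
        c = 3.0
        m1 = fit_parametric(weibull_arm, "weibull")
        scaled = IPDSet(time=weibull_arm.time * c, event=weibull_arm.event)
        m2 = fit_parametric(scaled, "weibull")
        assert m2.params["shape"] == pytest.approx(m1.params["shape"], rel=1e-4)
        assert m2.params["scale"] == pytest.approx(c * m1.params["scale"], rel=1e-4)
        assert m2.loglik == pytest.approx(
            m1.loglik - m1.n_events * np.log(c), rel=1e-7)


class TestFitMenu:
    def test_all_families_present_sorted(self, weibull_arm):
        menu = fit_menu(weibull_arm)
        assert {m.family for m in menu} == set(FAMILIES)
        aics = [m.aic for m in menu if m.converged]
        assert aics == sorted(aics)

    def test_aic_definition(self, weibull_arm):
        for m in fit_menu(weibull_arm):
            if m.converged:
                k = len(m.params)
                assert m.aic == pytest.approx(2 * k - 2 * m.loglik, abs=1e-9)

    def test_exponential_truth_competitive(self):
        # AIC consistency: on exponential data the exponential fit is
        # within 2 of the menu minimum
        ipd = fx.simulate_arm("exponential", [0.06], 2000, 1.0, 40.0, rng=21)
        menu = fit_menu(ipd)
        best = min(m.aic for m in menu if m.converged)
        expo = next(m for m in menu if m.family == "exponential")
        assert expo.aic <= best + 2.0


class TestEvaluate:
    def test_survival_at_zero_is_one(self):
        for fam, params in [("exponential", [0.1]), ("weibull", [1.5, 10]),
                            ("gompertz", [0.05, 0.02]),
                            ("generalized-gamma", [2.0, 0.8, 0.5])]:
            c = ParametricCurve(fam, params)
            assert evaluate(c, 0.0, "survival") == pytest.approx(1.0)

    def test_exponential_closed_forms(self):
        lam, t = 0.07, 13.0
        c = ParametricCurve("exponential", [lam])
        assert evaluate(c, t, "survival") == pytest.approx(np.exp(-lam * t))
        assert evaluate(c, t, "cumhazard") == pytest.approx(lam * t)
        assert evaluate(c, t, "hazard") == pytest.approx(lam)

    def test_gompertz_cumhazard_vs_quadrature(self):
        a, b = 0.02, 0.04  # rate, shape
        c = ParametricCurve("gompertz", [b, a])
        for t in (1.0, 5.0, 20.0):
            ref, _ = quad(lambda u: a * np.exp(b * u), 0, t)
            assert evaluate(c, t, "cumhazard") == pytest.approx(ref, rel=1e-9)

    def test_negative_time_rejected(self):
        c = ParametricCurve("exponential", [0.1])
        with pytest.raises(InvalidParameterError):
            evaluate(c, -1.0, "survival")


class TestFamilyInvariants:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_survival_axioms(self, family, data):
        params = data.draw(PARAM_STRATEGIES[family])
        c = ParametricCurve(family, list(params))
        # grid to ~10x a representative scale
        scale = params[1] if family in ("weibull", "log-logistic") else (
            np.exp(params[0]) if family in ("log-normal", "generalized-gamma",
                                            "generalized-F")
            else 1.0 / params[-1])
        grid = np.linspace(0.0, 10.0 * min(scale, 100.0), 50)
        s = c.survival(grid)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all((s >= -1e-12) & (s <= 1 + 1e-12))
        assert np.all(np.diff(s) <= 1e-10)
        with np.errstate(divide="ignore", over="ignore"):
            h = c.cumhazard(grid[1:])
            # compare H with -ln S only where S has not underflowed
            mask = s[1:] > 1e-12
            assert np.allclose(h[mask], -np.log(s[1:][mask]), atol=1e-8)
            assert np.all(c.hazard(grid[1:] + 1e-9) >= -1e-12)
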