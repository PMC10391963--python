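import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmforge import fixtures as fx
from psmforge.errors import (DegenerateArmsError, InsufficientEventsError,
                             InvalidParameterError)
from psmforge.hazard_tools import apply_hr, cox_hr, cox_loglik, ph_test
from psmforge.km_reconstruct import IPDSet
from psmforge.surv_models import ParametricCurve


class TestCoxHR:
    def test_identical_arms_hr_one(self, weibull_arm):
        est = cox_hr(weibull_arm, weibull_arm)
        assert 0.95 <= est.hr <= 1.05
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_brute_force_oracle(self):
        # 4-subject toy set: the estimate must maximize the enumerated
        # partial likelihood on a fine grid
        ctrl = IPDSet(time=np.array([1.0, 3.0]), event=np.array([1, 1]))
        intv = IPDSet(time=np.array([2.0, 4.0]), event=np.array([1, 1]))
        est = cox_hr(ctrl, intv)

        def brute(beta):
            th = np.exp(beta)
            # risk sets: {c1,c3,i2,i4}, {c3,i2,i4}, {c3,i4}, {i4}
            return (np.log(1 / (2 + 2 * th)) + np.log(th / (1 + 2 * th))
                    + np.log(1 / (1 + th)) + np.log(th / th))

        grid = np.linspace(-4, 4, 40001)
        beta_star = grid[np.argmax([brute(b) for b in grid])]
        assert np.log(est.hr) == pytest.approx(beta_star, abs=1e-3)
        # and the implementation's own loglik agrees with the enumeration
        assert cox_loglik(0.3, ctrl, intv) == pytest.approx(brute(0.3), abs=1e-12)

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        c = fx.simulate_arm("exponential", [0.06], 300, 1.0, 30.0, rng=11)
        i = fx.simulate_arm("exponential", [0.06], 300, 0.55, 30.0, rng=12)
        c.time, i.time = np.ceil(c.time), np.ceil(i.time)  # monthly ties
        est = cox_hr(c, i)
        df = pd.DataFrame({
            "t": np.r_[c.time, i.time], "e": np.r_[c.event, i.event],
            "x": np.r_[np.zeros(c.n), np.ones(i.n)]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert est.hr == pytest.approx(float(np.exp(cph.params_.iloc[0])),
                                       rel=1e-6)
        assert est.se_log_hr == pytest.approx(
            float(cph.standard_errors_.iloc[0]), rel=1e-4)

    def test_ci_definition(self):
        c = fx.simulate_arm("exponential", [0.06], 200, 1.0, 30.0, rng=1)
        i = fx.simulate_arm("exponential", [0.06], 200, 0.6, 30.0, rng=2)
        est = cox_hr(c, i)
        assert est.ci_low == pytest.approx(
            np.exp(np.log(est.hr) - 1.959963984540054 * est.se_log_hr))
        assert est.ci_low <= est.hr <= est.ci_high

    def test_no_events_degenerate(self):
        c = IPDSet(time=np.array([1.0, 2.0]), event=np.array([0, 0]))
        i = IPDSet(time=np.array([1.0, 2.0]), event=np.array([1, 1]))
        with pytest.raises(DegenerateArmsError):
            cox_hr(c, i)

    def test_separation_flagged_not_fatal(self):
        # complete separation: every control event precedes every
        # intervention event by a wide margin -> monotone likelihood
        c = IPDSet(time=np.array([1.0, 1.5, 2.0]), event=np.array([1, 1, 1]))
        i = IPDSet(time=np.array([100.0, 101.0, 102.0]),
                   event=np.array([1, 1, 1]))
        with pytest.warns(UserWarning, match="converge"):
            est = cox_hr(c, i)
        assert not est.converged
        assert est.ci_low == 0.0 or not np.isfinite(est.ci_high)

    def test_bias_shrinks_with_n(self):
        def lnhr_bias(n, seed):
            reps = []
            for s in range(20):
                c = fx.simulate_arm("exponential", [0.08], n, 1.0, 24.0,
                                    rng=seed + s)
                i = fx.simulate_arm("exponential", [0.08], n, 0.5, 24.0,
                                    rng=seed + 1000 + s)
                reps.append(np.log(cox_hr(c, i).hr))
            return abs(np.mean(reps) - np.log(0.5))

        assert lnhr_bias(800, 40) < lnhr_bias(50, 40) + 0.02


class TestPHTest:
    def test_p_in_unit_interval_and_label_symmetry(self):
        c = fx.simulate_arm("exponential", [0.08], 300, 1.0, 24.0, rng=31)
        i = fx.simulate_arm("exponential", [0.08], 300, 0.6, 24.0, rng=32)
        r1 = ph_test(c, i)
        r2 = ph_test(i, c)
        assert 0.0 <= r1.p <= 1.0
        # symmetric up to the optimizer tolerance on the fitted log-HR
        assert r1.chisq == pytest.approx(r2.chisq, rel=1e-4)
        assert r1.df == 1

    def test_insufficient_events(self):
        c = IPDSet(time=np.array([1.0, 5.0]), event=np.array([1, 0]))
        i = IPDSet(time=np.array([1.0, 5.0]), event=np.array([1, 0]))
        with pytest.raises(InsufficientEventsError):
            ph_test(c, i)

    def test_power_against_crossing_hazards(self):
        # Weibull shapes 0.7 vs 1.8 with a common median: hazards cross
        med = 12.0
        reject = 0
        reps = 60
        for s in range(reps):
            sc = med / np.log(2.0) ** (1 / 0.7)
            si = med / np.log(2.0) ** (1 / 1.8)
            c = fx.simulate_arm("weibull", [0.7, sc], 500, 1.0, 36.0, rng=600 + s)
            i = fx.simulate_arm("weibull", [1.8, si], 500, 1.0, 36.0, rng=9600 + s)
            if ph_test(c, i).p < 0.05:
                reject += 1
        assert reject / reps >= 0.8


class TestApplyHR:
    def test_identity(self):
        base = ParametricCurve("weibull", [1.4, 18.0])
        adj = apply_hr(base, 1.0)
        t = np.linspace(0, 60, 61)
        assert np.allclose(adj.survival(t), base.survival(t), atol=1e-14)

    def test_exponential_exact(self):
        lam, hr = 0.06, 0.45
        base = ParametricCurve("exponential", [lam])
        adj = apply_hr(base, hr)
        t = np.linspace(0, 100, 201)
        assert np.allclose(adj.survival(t), np.exp(-hr * lam * t), atol=1e-10)

    def test_weibull_at_scale(self):
        # S_ctrl(sigma) = e^-1, so S_int = e^-0.5 under hr = 0.5
        base = ParametricCurve("weibull", [1.7, 14.0])
        adj = apply_hr(base, 0.5)
        assert adj.survival(14.0) == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_nonpositive_hr_rejected(self):
        base = ParametricCurve("exponential", [0.1])
        for hr in (0.0, -1.0):
            with pytest.raises(InvalidParameterError):
                apply_hr(base, hr)

    @settings(max_examples=30, deadline=None)
    @given(hr=st.floats(0.05, 5.0), a=st.floats(0.1, 3.0), b=st.floats(0.1, 3.0))
    def test_ordering_and_composition(self, hr, a, b):
        base = ParametricCurve("weibull", [1.3, 20.0])
        t = np.linspace(0.0, 80.0, 33)
        s0, s1 = base.survival(t), apply_hr(base, hr).survival(t)
        if hr < 1:
            assert np.all(s1 >= s0 - 1e-12)
        elif hr > 1:
            assert np.all(s1 <= s0 + 1e-12)
        composed = apply_hr(apply_hr(base, a), b)
        direct = apply_hr(base, a * b)
        assert np.allclose(composed.survival(t), direct.survival(t), atol=1e-10)
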