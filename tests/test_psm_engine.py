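import copy

import numpy as np
import pytest

from psmforge import fixtures as fx
from psmforge.errors import InvalidParameterError, LogicalInconsistencyError
from psmforge.psm_engine import (_trapz_ly_months, discount_factor, icer,
                                 run_psm, state_occupancy)
from psmforge.surv_models import ParametricCurve


def exp_curve(rate):
    return ParametricCurve("exponential", [rate])


class TestStateOccupancy:
    def test_equal_curves_zero_pps(self):
        c = exp_curve(0.05)
        occ = state_occupancy(c, c, 24)
        assert np.allclose(occ["pps"], 0.0, atol=1e-12)

    def test_occupancies_sum_to_one(self):
        occ = state_occupancy(exp_curve(0.07), exp_curve(0.04), 60)
        total = occ["pfs"] + occ["pps"] + occ["dead"]
        assert np.allclose(total, 1.0, atol=1e-9)
        assert np.all(np.diff(occ["dead"]) >= -1e-12)

    def test_os_below_pfs_aborts(self):
        # crossing configuration: heavy-tailed PFS vs faster-dying OS
        pfs = ParametricCurve("weibull", [0.5, 5.0])
        os_ = ParametricCurve("weibull", [1.5, 20.0])
        with pytest.raises(LogicalInconsistencyError) as exc:
            state_occupancy(pfs, os_, 200)
        assert exc.value.cycle is not None


class TestDiscountFactor:
    def test_zero_rate(self):
        assert discount_factor(0.0, 37.5) == 1.0

    def test_annual_equivalence(self):
        assert discount_factor(0.03, 12.0) == pytest.approx(1 / 1.03)

    def test_monotone_in_time(self):
        t = np.linspace(0, 120, 50)
        f = discount_factor(0.035, t)
        assert np.all(np.diff(f) < 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            discount_factor(-0.01, 10)


class TestICER:
    def test_plain_ratio(self):
        v = icer(1000.0, 0.5)
        assert v.value == 2000.0 and v.flag == "ok"

    def test_zero_effect_undefined(self):
        v = icer(1000.0, 0.0)
        assert v.value is None and v.flag == "undefined"
        assert v.render() == "undefined"

    def test_negative_cost_flagged(self):
        v = icer(-500.0, 0.5)
        assert v.value == -1000.0
        assert v.flag == "dominant-or-check-signs"

    def test_negative_effect_flagged(self):
        assert icer(500.0, -0.5).flag == "dominated-negative"


class TestRunPSM:
    @pytest.fixture()
    def ly_inputs(self):
        # utilities all 1, no discounting, zero costs: pure life-years
        econ = fx.EconParams(annual_discount_rate=0.0, horizon_months=100,
                             drug_cost_intervention=0.0, drug_cost_control=0.0)
        return fx.build_inputs(fx.TrialSpec(seed=1), econ)

    def test_ly_mode_qaly_equals_ly(self, ly_inputs):
        tr, res = run_psm(ly_inputs, exp_curve(0.06), exp_curve(0.05),
                          hr_pfs=0.8, hr_os=0.8)
        for arm in ("control", "intervention"):
            assert res.totals[arm]["qaly"] == pytest.approx(
                res.totals[arm]["ly"], abs=1e-12)

    def test_exponential_ly_closed_form(self, ly_inputs):
        lam, T = 0.05, 100
        _, res = run_psm(ly_inputs, exp_curve(lam), exp_curve(lam),
                         hr_pfs=1.0, hr_os=1.0)
        ly_months = res.totals["control"]["ly"] * 12.0
        assert ly_months == pytest.approx((1 - np.exp(-lam * T)) / lam,
                                          abs=0.05)

    def test_cost_linearity(self, base_inputs):
        pfs, os_ = exp_curve(0.07), exp_curve(0.05)
        _, res1 = run_psm(base_inputs, pfs, os_, hr_pfs=0.6, hr_os=0.7)
        doubled = copy.deepcopy(base_inputs)
        for it in doubled.resources:
            it.unit_cost *= 2
        _, res2 = run_psm(doubled, pfs, os_, hr_pfs=0.6, hr_os=0.7)
        assert res2.inc_cost == pytest.approx(2 * res1.inc_cost, rel=1e-12)
        if res1.icer.flag == "ok":
            assert res2.icer.value == pytest.approx(2 * res1.icer.value,
                                                    rel=1e-12)

    def test_hr_one_no_effect(self, base_inputs):
        _, res = run_psm(base_inputs, exp_curve(0.07), exp_curve(0.05),
                         hr_pfs=1.0, hr_os=1.0)
        assert abs(res.inc_qaly) < 1e-9
        assert abs(res.inc_ly) < 1e-9

    def test_discount_monotonicity(self, base_inputs):
        prev = np.inf
        for rate in (0.0, 0.015, 0.03, 0.045, 0.06):
            mod = copy.deepcopy(base_inputs)
            mod.annual_discount_rate = rate
            _, res = run_psm(mod, exp_curve(0.07), exp_curve(0.05),
                             hr_pfs=0.6, hr_os=0.7)
            assert res.totals["control"]["qaly_disc"] <= prev + 1e-12
            assert res.totals["control"]["cost_disc"] <= (
                res.totals["control"]["cost"] + 1e-9)
            prev = res.totals["control"]["qaly_disc"]

    def test_conservation_every_cycle(self, base_inputs):
        tr, _ = run_psm(base_inputs, exp_curve(0.07), exp_curve(0.05),
                        hr_pfs=0.6, hr_os=0.7)
        for arm in ("control", "intervention"):
            a = tr.arms[arm]
            assert np.max(np.abs(a.pfs + a.pps + a.dead - 1.0)) < 1e-9

    def test_half_cycle_second_order(self):
        # halving the integration step changes LY by < 0.01 months
        os_ = ParametricCurve("weibull", [1.3, 25.0])
        coarse = _trapz_ly_months(os_, 60, substeps=1)
        fine = _trapz_ly_months(os_, 60, substeps=2)
        assert abs(coarse - fine) < 0.01

    def test_midpoint_mode_close_to_trapezoid(self, base_inputs):
        args = (base_inputs, exp_curve(0.07), exp_curve(0.05))
        _, r1 = run_psm(*args, hr_pfs=0.6, hr_os=0.7, half_cycle="trapezoid")
        _, r2 = run_psm(*args, hr_pfs=0.6, hr_os=0.7, half_cycle="midpoint")
        assert r2.totals["control"]["ly"] == pytest.approx(
            r1.totals["control"]["ly"], abs=0.01)

    def test_estimate_sentinel_requires_explicit_hr(self, base_inputs):
        mod = copy.deepcopy(base_inputs)
        mod.hr_os = "estimate"
        with pytest.raises(InvalidParameterError):
            run_psm(mod, exp_curve(0.07), exp_curve(0.05), hr_pfs=0.6)

    def test_failure_reports_cycle(self, base_inputs):
        pfs = ParametricCurve("weibull", [0.5, 5.0])
        os_ = ParametricCurve("weibull", [1.5, 20.0])
        mod = copy.deepcopy(base_inputs)
        mod.horizon_months = 200
        with pytest.raises(LogicalInconsistencyError) as exc:
            run_psm(mod, pfs, os_, hr_pfs=1.0, hr_os=1.0)
        assert isinstance(exc.value.cycle, int)
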