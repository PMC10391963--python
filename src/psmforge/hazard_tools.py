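"""Between-arm hazard-ratio machinery.

* :func:`cox_hr` - Cox proportional-hazards model for a single binary
  covariate (intervention vs control), Efron correction for tied event
  times, Wald 95% CI on the log scale.
* :func:`ph_test` - Grambsch-Therneau score test on Schoenfeld residuals
  against a Kaplan-Meier transform of event time.
* :func:`apply_hr` - constant-HR extrapolation: multiply the control
  cumulative hazard, i.e. ``S_int = S_ctrl ** hr``.  Works for any curve
  through its cumulative-hazard contract, independent of whether the
  family was fitted on a PH or an AFT metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateArmsError, InsufficientEventsError, InvalidParameterError
from .km_reconstruct import IPDSet, km_curve
from .surv_models import SurvivalCurve

__all__ = ["HREstimate", "PHTestResult", "HRAdjustedCurve",
           "apply_hr", "cox_hr", "cox_loglik", "ph_test"]

Z95 = 1.959963984540054


@dataclass
class HREstimate:
    hr: float
    se_log_hr: float
    ci_low: float
    ci_high: float
    endpoint: str = ""
    converged: bool = True


@dataclass
class PHTestResult:
    chisq: float
    df: int
    p: float
    endpoint: str = ""


class PHAssumptionWarning(UserWarning):
    """Raised (as a warning, never a hard stop) when the PH test rejects."""


# ---------------------------------------------------------------------------
# Cox model, one binary covariate
# ---------------------------------------------------------------------------

def _stack(ipd_control: IPDSet, ipd_intervention: IPDSet):
    time = np.concatenate([ipd_control.time, ipd_intervention.time])
    event = np.concatenate([ipd_control.event, ipd_intervention.event])
    x = np.concatenate(
        [np.zeros(ipd_control.n), np.ones(ipd_intervention.n)]
    )
    order = np.argsort(time, kind="stable")
    return time[order], event[order].astype(int), x[order]


def _event_groups(time, event, x):
    """Per unique event time (vectorized): deaths (d0, d1) and risk counts
    (n0, n1).  ``time`` must be sorted ascending."""
    et = np.unique(time[event == 1])
    lo = np.searchsorted(time, et, side="left")
    hi = np.searchsorted(time, et, side="right")
    # at risk at t: observed time >= t
    n_ge = len(time) - lo
    ones_from = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    n1 = ones_from[lo]
    n0 = n_ge - n1
    pe = np.concatenate([[0.0], np.cumsum(event)])
    pex = np.concatenate([[0.0], np.cumsum(event * x)])
    d = pe[hi] - pe[lo]
    d1 = pex[hi] - pex[lo]
    return np.column_stack([et, d - d1, d1, n0, n1])


def cox_loglik(beta: float, ipd_control: IPDSet, ipd_intervention: IPDSet,
               ties: str = "efron") -> float:
    """Cox partial log-likelihood at log-HR ``beta`` (binary covariate)."""
    time, event, x = _stack(ipd_control, ipd_intervention)
    return _cox_loglik_groups(beta, _event_groups(time, event, x), ties)


def _cox_loglik_groups(beta, groups, ties="efron"):
    theta = np.exp(beta)
    d0, d1, n0, n1 = groups[:, 1], groups[:, 2], groups[:, 3], groups[:, 4]
    d = d0 + d1
    R = n1 * theta + n0
    D = d1 * theta + d0
    ll = float(np.sum(d1) * beta)
    if ties == "breslow":
        return ll - float(np.sum(d * np.log(R)))
    # Efron: untied groups vectorized, tied groups looped (rarely many)
    single = d == 1
    ll -= float(np.sum(np.log(R[single])))
    for i in np.nonzero(~single)[0]:
        di = int(round(d[i]))
        ell = np.arange(di)
        ll -= float(np.sum(np.log(R[i] - (ell / di) * D[i])))
    return ll


def cox_hr(ipd_control: IPDSet, ipd_intervention: IPDSet,
           ties: str = "efron", endpoint: str = "") -> HREstimate:
    """Maximum partial-likelihood HR (intervention vs control) with Wald CI.

    Monotone-likelihood / separation cases return a flagged estimate with
    infinite confidence bounds rather than raising.
    """
    if ipd_control.n_events < 1 or ipd_intervention.n_events < 1:
        raise DegenerateArmsError(
            "hazard-ratio estimation requires at least one event per arm",
            events_control=ipd_control.n_events,
            events_intervention=ipd_intervention.n_events,
        )
    time, event, x = _stack(ipd_control, ipd_intervention)
    groups = _event_groups(time, event, x)

    def nll(beta):
        return -_cox_loglik_groups(float(beta), groups, ties)

    res = optimize.minimize_scalar(nll, bounds=(-30.0, 30.0), method="bounded",
                                   options={"xatol": 1e-10})
    beta = float(res.x)
    # numeric observed information
    h = 1e-4
    info = -(_cox_loglik_groups(beta + h, groups, ties)
             - 2.0 * _cox_loglik_groups(beta, groups, ties)
             + _cox_loglik_groups(beta - h, groups, ties)) / h**2
    diverged = abs(beta) > 25.0 or not np.isfinite(info) or info <= 0
    if diverged:
        warnings.warn("Cox model did not converge (monotone likelihood or "
                      "separation); returning infinite confidence bounds")
        se = float("inf")
    else:
        se = float(1.0 / np.sqrt(info))
    hr = float(np.exp(beta))
    return HREstimate(
        hr=hr, se_log_hr=se,
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        endpoint=endpoint, converged=not diverged,
    )


# ---------------------------------------------------------------------------
# proportional-hazards test (Grambsch-Therneau, KM time transform)
# ---------------------------------------------------------------------------

def ph_test(ipd_control: IPDSet, ipd_intervention: IPDSet,
            endpoint: str = "", transform: str = "km") -> PHTestResult:
    """Score test for a time trend in scaled Schoenfeld residuals.

    ``transform`` is 'km' (default: left-continuous pooled Kaplan-Meier of
    event time, the reference default), 'identity' or 'rank'.
    """
    if ipd_control.n_events < 1 or ipd_intervention.n_events < 1:
        raise DegenerateArmsError(
            "the PH test requires at least one event per arm")
    time, event, x = _stack(ipd_control, ipd_intervention)
    if np.unique(time[event == 1]).size < 3:
        raise InsufficientEventsError(
            "the PH test requires at least 3 distinct event times")
    beta = np.log(cox_hr(ipd_control, ipd_intervention).hr)
    theta = np.exp(beta)

    # per-event Schoenfeld residuals and risk-set variances, vectorized
    # over the per-event-time groups
    groups = _event_groups(time, event, x)
    et, d0, d1, n0, n1 = groups.T
    R = n1 * theta + n0
    xbar = n1 * theta / R
    v = xbar * (1.0 - xbar)
    counts = (d0 + d1).astype(int)
    ev_t = np.repeat(et, counts)
    var = np.repeat(v, counts)
    # within a tie group: d1 residuals of (1 - xbar), d0 of (0 - xbar)
    resid = np.concatenate([
        np.concatenate([np.full(int(a), 1.0 - xb), np.full(int(b), -xb)])
        for a, b, xb in zip(d1, d0, xbar)
    ]) if len(et) else np.array([])
    d = len(ev_t)

    if transform == "km":
        pooled = km_curve(IPDSet(time=time, event=event))
        # left-continuous: S just before each event time
        g = 1.0 - pooled.evaluate(ev_t - 1e-9)
    elif transform == "identity":
        g = ev_t.astype(float)
    elif transform == "rank":
        g = stats.rankdata(ev_t, method="average")
    else:
        raise InvalidParameterError(f"unknown time transform '{transform}'")

    gc = g - g.mean()
    denom = float(np.sum(gc**2)) * float(np.sum(var)) / d
    if denom <= 0:
        raise InsufficientEventsError("degenerate PH-test denominator")
    chisq = float(np.sum(gc * resid)) ** 2 / denom
    p = float(stats.chi2.sf(chisq, 1))
    if p < 0.05:
        warnings.warn(
            f"proportional-hazards test rejects at 5% (p = {p:.4g}) for "
            f"{endpoint or 'this endpoint'}; review whether a constant HR "
            "is appropriate", PHAssumptionWarning)
    return PHTestResult(chisq=chisq, df=1, p=p, endpoint=endpoint)


# ---------------------------------------------------------------------------
# constant-HR curve
# ---------------------------------------------------------------------------

class HRAdjustedCurve(SurvivalCurve):
    """Curve with cumulative hazard ``hr * H_base(t)``."""

    def __init__(self, base: SurvivalCurve, hr: float):
        if not (hr > 0) or not np.isfinite(hr):
            raise InvalidParameterError(f"hazard ratio must be > 0, got {hr}")
        self.base = base
        self.hr = float(hr)
        self.label = f"{getattr(base, 'label', 'curve')} x HR {hr:g}"

    def cumhazard(self, t):
        return self.hr * self.base.cumhazard(t)

    def hazard(self, t, step: float = 1e-5):
        return self.hr * self.base.hazard(t)


def apply_hr(control_curve: SurvivalCurve, hr: float) -> HRAdjustedCurve:
    """Intervention-arm curve: S_int(t) = S_ctrl(t) ** hr."""
    return HRAdjustedCurve(control_curve, hr)
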