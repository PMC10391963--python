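"""Parametric survival models for right-censored time-to-event data.

Eight families are supported: exponential, gamma, log-logistic, Weibull,
log-normal, Gompertz, generalized gamma and generalized F.  All are fitted
by maximum likelihood on log-transformed positive parameters with a fixed,
deterministic multi-start grid (no RNG), and ranked by AIC.

Parameterizations (chosen so the nesting identities are exact):

========================  =============================================
exponential               ``rate``; S(t) = exp(-rate * t)
weibull                   ``shape, scale``; S(t) = exp(-(t/scale)^shape)
gamma                     ``shape, rate``; S = 1 - P(shape, rate * t)
log-logistic              ``shape, scale``; S = 1 / (1 + (t/scale)^shape)
log-normal                ``meanlog, sdlog``; S = 1 - Phi((ln t - meanlog)/sdlog)
gompertz                  ``shape, rate``; h(t) = rate * exp(shape * t),
                          shape may be negative (improper survival allowed,
                          with a warning)
generalized-gamma         stable ``(mu, sigma, Q)`` form; Q = 0 is the
                          log-normal, Q = 1 the Weibull, Q = sigma the gamma
generalized-F             stable ``(mu, sigma, Q, P)`` form; P -> 0 recovers
                          the generalized gamma
========================  =============================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import InvalidParameterError

__all__ = [
    "FAMILIES",
    "FittedModel",
    "ParametricCurve",
    "SurvivalCurve",
    "censored_loglik",
    "evaluate",
    "fit_menu",
    "fit_parametric",
    "inverse_survival",
]

_EPS = 1e-300


# ---------------------------------------------------------------------------
# family definitions: log-density, log-survival, parameter domains, seeds
# ---------------------------------------------------------------------------

def _as_arr(t):
    return np.asarray(t, dtype=float)


def _exp_logpdf(p, t):
    (rate,) = p
    return np.log(rate) - rate * _as_arr(t)


def _exp_logsf(p, t):
    (rate,) = p
    return -rate * _as_arr(t)


def _weibull_logpdf(p, t):
    shape, scale = p
    t = _as_arr(t)
    z = t / scale
    with np.errstate(divide="ignore"):
        return np.log(shape / scale) + (shape - 1.0) * np.log(z) - z**shape


def _weibull_logsf(p, t):
    shape, scale = p
    return -(_as_arr(t) / scale) ** shape


def _gamma_logpdf(p, t):
    shape, rate = p
    return stats.gamma.logpdf(_as_arr(t), shape, scale=1.0 / rate)


def _gamma_logsf(p, t):
    shape, rate = p
    return stats.gamma.logsf(_as_arr(t), shape, scale=1.0 / rate)


def _llogis_logpdf(p, t):
    shape, scale = p
    return stats.fisk.logpdf(_as_arr(t), shape, scale=scale)


def _llogis_logsf(p, t):
    shape, scale = p
    return stats.fisk.logsf(_as_arr(t), shape, scale=scale)


def _lnorm_logpdf(p, t):
    meanlog, sdlog = p
    return stats.lognorm.logpdf(_as_arr(t), sdlog, scale=np.exp(meanlog))


def _lnorm_logsf(p, t):
    meanlog, sdlog = p
    return stats.lognorm.logsf(_as_arr(t), sdlog, scale=np.exp(meanlog))


def _gompertz_cumhaz(p, t):
    shape, rate = p
    t = _as_arr(t)
    if abs(shape) < 1e-9:
        # series expansion around shape = 0 avoids 0/0
        return rate * t * (1.0 + 0.5 * shape * t + shape**2 * t**2 / 6.0)
    return rate / shape * np.expm1(shape * t)


def _gompertz_logpdf(p, t):
    shape, rate = p
    return np.log(rate) + shape * _as_arr(t) - _gompertz_cumhaz(p, t)


def _gompertz_logsf(p, t):
    return -_gompertz_cumhaz(p, t)


def _gengamma_logpdf(p, t):
    mu, sigma, Q = p
    t = _as_arr(t)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    # the general formula cancels catastrophically as Q -> 0 (terms of
    # size Q^-2 log Q^-2); below this cutoff the log-normal limit is
    # more accurate than the direct evaluation
    if abs(Q) < 2e-4:
        return stats.lognorm.logpdf(t, sigma, scale=np.exp(mu))
    qq = Q**-2
    return (
        -np.log(sigma * t)
        + np.log(abs(Q))
        + qq * np.log(qq)
        - special.gammaln(qq)
        + qq * (Q * w - np.exp(Q * w))
    )


def _gengamma_logsf(p, t):
    mu, sigma, Q = p
    t = _as_arr(t)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) / sigma
    if abs(Q) < 2e-4:  # see _gengamma_logpdf
        return stats.lognorm.logsf(t, sigma, scale=np.exp(mu))
    qq = Q**-2
    u = qq * np.exp(Q * w)
    if Q > 0:
        sf = special.gammaincc(qq, u)
    else:
        sf = special.gammainc(qq, u)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(sf, _EPS))


def _genf_sdelta(Q, P):
    delta = np.sqrt(Q**2 + 2.0 * P)
    s1 = 2.0 / (Q**2 + 2.0 * P + Q * delta)
    s2 = 2.0 / (Q**2 + 2.0 * P - Q * delta)
    return delta, s1, s2


def _genf_logpdf(p, t):
    mu, sigma, Q, P = p
    t = _as_arr(t)
    delta, s1, s2 = _genf_sdelta(Q, P)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) * delta / sigma
    # log(1 + s1*e^w/s2) computed stably for large |w|
    logterm = np.logaddexp(0.0, w + np.log(s1 / s2))
    return (
        np.log(delta)
        + s1 * (np.log(s1) - np.log(s2))
        + s1 * w
        - np.log(sigma * t)
        - (s1 + s2) * logterm
        - special.betaln(s1, s2)
    )


def _genf_logsf(p, t):
    mu, sigma, Q, P = p
    t = _as_arr(t)
    delta, s1, s2 = _genf_sdelta(Q, P)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - mu) * delta / sigma
    # S(t) = I_{1-u}(s2, s1) with u = s1 e^w / (s2 + s1 e^w)
    ew = np.exp(np.clip(w, -700, 700))
    x = s2 / (s2 + s1 * ew)
    sf = special.betainc(s2, s1, x)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(sf, _EPS))


@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    positive: tuple[bool, ...]  # per-parameter: constrained to (0, inf)?
    logpdf: callable
    logsf: callable

    @property
    def k(self) -> int:
        return len(self.param_names)

    def check_domain(self, params: Sequence[float]) -> np.ndarray:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.k,):
            raise InvalidParameterError(
                f"{self.name} expects {self.k} parameters "
                f"({', '.join(self.param_names)}), got {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise InvalidParameterError(f"{self.name}: non-finite parameters {p}")
        for name, pos, v in zip(self.param_names, self.positive, p):
            if pos and v <= 0:
                raise InvalidParameterError(
                    f"{self.name}: parameter '{name}' must be > 0, got {v}"
                )
        return p


FAMILIES: dict[str, _Family] = {
    f.name: f
    for f in [
        _Family("exponential", ("rate",), (True,), _exp_logpdf, _exp_logsf),
        _Family("gamma", ("shape", "rate"), (True, True), _gamma_logpdf, _gamma_logsf),
        _Family("log-logistic", ("shape", "scale"), (True, True), _llogis_logpdf, _llogis_logsf),
        _Family("weibull", ("shape", "scale"), (True, True), _weibull_logpdf, _weibull_logsf),
        _Family("log-normal", ("meanlog", "sdlog"), (False, True), _lnorm_logpdf, _lnorm_logsf),
        _Family("gompertz", ("shape", "rate"), (False, True), _gompertz_logpdf, _gompertz_logsf),
        _Family(
            "generalized-gamma", ("mu", "sigma", "Q"), (False, True, False),
            _gengamma_logpdf, _gengamma_logsf,
        ),
        _Family(
            "generalized-F", ("mu", "sigma", "Q", "P"), (False, True, False, True),
            _genf_logpdf, _genf_logsf,
        ),
    ]
}


def _get_family(family: str) -> _Family:
    try:
        return FAMILIES[family]
    except KeyError:
        raise InvalidParameterError(
            f"unknown family '{family}'; choose from {sorted(FAMILIES)}"
        ) from None


# ---------------------------------------------------------------------------
# survival-curve contract
# ---------------------------------------------------------------------------

class SurvivalCurve:
    """Evaluation contract shared by fitted and HR-adjusted curves.

    Subclasses implement :meth:`survival` and :meth:`cumhazard`; the
    relation ``H(t) = -ln S(t)`` is maintained by construction.
    """

    label: str = "curve"

    def survival(self, t):
        return np.exp(-self.cumhazard(t))

    def cumhazard(self, t):
        raise NotImplementedError

    def hazard(self, t, step: float = 1e-5):
        """Instantaneous hazard; central difference of H with the given step
        unless a subclass provides an analytic form."""
        t = np.asarray(t, dtype=float)
        lo = np.maximum(t - step, 0.0)
        return (self.cumhazard(t + step) - self.cumhazard(lo)) / (t + step - lo)


class ParametricCurve(SurvivalCurve):
    """Survival curve of one parametric family at fixed parameters."""

    def __init__(self, family: str, params: Sequence[float], label: str | None = None):
        self._family = _get_family(family)
        self._params = self._family.check_domain(params)
        self.family = self._family.name
        self.label = label or self.family

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        _check_nonneg_time(t)
        return np.exp(self._family.logsf(self._params, t))

    def cumhazard(self, t):
        t = np.asarray(t, dtype=float)
        _check_nonneg_time(t)
        return -self._family.logsf(self._params, t)

    def hazard(self, t, step: float = 1e-5):
        t = np.asarray(t, dtype=float)
        _check_nonneg_time(t)
        # analytic: h = f / S
        return np.exp(
            self._family.logpdf(self._params, t) - self._family.logsf(self._params, t)
        )


def _check_nonneg_time(t) -> None:
    if np.any(np.asarray(t) < 0):
        raise InvalidParameterError("time must be >= 0")


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def censored_loglik(family: str, params: Sequence[float], ipd) -> float:
    """Right-censored log-likelihood: sum ln f over events + sum ln S over
    censored records."""
    fam = _get_family(family)
    p = fam.check_domain(params)
    time = np.asarray(ipd.time, dtype=float)
    event = np.asarray(ipd.event, dtype=int)
    ll = 0.0
    if event.sum() > 0:
        ll += float(np.sum(fam.logpdf(p, time[event == 1])))
    if (event == 0).sum() > 0:
        ll += float(np.sum(fam.logsf(p, time[event == 0])))
    return ll


@dataclass
class FittedModel(SurvivalCurve):
    """One parametric family fitted to right-censored IPD by MLE."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int
    n_events: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = self.family
        self._curve = ParametricCurve(self.family, self.param_vector, self.label)

    @property
    def param_vector(self) -> np.ndarray:
        fam = _get_family(self.family)
        return np.array([self.params[name] for name in fam.param_names])

    def survival(self, t):
        return self._curve.survival(t)

    def cumhazard(self, t):
        return self._curve.cumhazard(t)

    def hazard(self, t, step: float = 1e-5):
        return self._curve.hazard(t)


def _transform(fam: _Family, p: np.ndarray) -> np.ndarray:
    out = p.copy()
    for i, pos in enumerate(fam.positive):
        if pos:
            out[i] = np.log(p[i])
    return out


def _untransform(fam: _Family, x: np.ndarray) -> np.ndarray:
    out = x.copy()
    for i, pos in enumerate(fam.positive):
        if pos:
            out[i] = np.exp(np.clip(x[i], -300, 300))
    return out


def _data_stats(ipd):
    time = np.asarray(ipd.time, dtype=float)
    event = np.asarray(ipd.event, dtype=int)
    et = time[event == 1]
    ref = et if et.size else time
    ref = np.maximum(ref, 1e-8)
    lm = float(np.mean(np.log(ref)))
    ls = float(np.std(np.log(ref)))
    ls = max(ls, 0.2)
    tbar = max(float(np.mean(time)), 1e-8)
    d = int(event.sum())
    rate0 = max(d, 1) / max(float(time.sum()), 1e-8)
    return lm, ls, tbar, rate0


def _starts(fam: _Family, ipd) -> list[np.ndarray]:
    """Five deterministic starting points per family, seeded from data
    moments (method-of-moments flavoured)."""
    lm, ls, tbar, rate0 = _data_stats(ipd)
    scale0 = float(np.exp(lm))
    name = fam.name
    if name == "exponential":
        grid = [[rate0], [rate0 * 2], [rate0 / 2], [1.0 / tbar], [rate0 * 5]]
    elif name == "weibull":
        grid = [[s, scale0] for s in (0.5, 0.8, 1.0, 1.5, 2.5)]
    elif name == "gamma":
        mom = max(1.0 / ls**2, 0.05)
        grid = [[s, s / max(tbar, 1e-8)] for s in (0.5, 1.0, 2.0, 4.0, mom)]
    elif name == "log-logistic":
        grid = [[s, scale0] for s in (0.5, 1.0, 1.5, 2.5, 1.0 / ls)]
    elif name == "log-normal":
        grid = [[lm, s] for s in (0.5 * ls, ls, 1.5 * ls, 2.5 * ls, 1.0)]
    elif name == "gompertz":
        grid = [[b, rate0] for b in (-0.05, -0.01, 0.0, 0.02, 0.08)]
    elif name == "generalized-gamma":
        grid = [[lm, ls, q] for q in (-1.0, 0.0, 0.5, 1.0, 2.0)]
    elif name == "generalized-F":
        grid = [
            [lm, ls, 0.0, 0.5],
            [lm, ls, 1.0, 0.5],
            [lm, ls, -1.0, 0.5],
            [lm, ls, 0.5, 1.5],
            [lm, 1.5 * ls, 0.0, 1.0],
        ]
    else:  # pragma: no cover
        raise AssertionError(name)
    return [np.asarray(g, dtype=float) for g in grid]


def fit_parametric(ipd, family: str) -> FittedModel:
    """Fit one family to an IPDSet by maximum likelihood.

    Deterministic: quasi-Newton (BFGS) from a fixed multi-start grid on
    log-transformed positive parameters, no RNG.  The exponential rate has
    the closed form d / sum(t) and is computed directly.
    """
    fam = _get_family(family)
    time = np.asarray(ipd.time, dtype=float)
    event = np.asarray(ipd.event, dtype=int)
    n = len(time)
    d = int(event.sum())
    if d < 1:
        raise InvalidParameterError("fitting requires at least one event")
    warns: list[str] = []

    if fam.name == "exponential":
        rate = d / float(time.sum())
        ll = censored_loglik("exponential", [rate], ipd)
        return FittedModel(
            family="exponential", params={"rate": rate}, loglik=ll,
            aic=2 * 1 - 2 * ll, n=n, n_events=d, converged=True,
        )

    if fam.name == "generalized-F" and d < 10:
        warns.append(
            f"generalized-F fitted on only {d} events; estimates are unstable"
        )

    def nll(x):
        p = _untransform(fam, np.asarray(x, dtype=float))
        try:
            with np.errstate(all="ignore"):
                val = censored_loglik(fam.name, p, ipd)
        except InvalidParameterError:
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    candidates = []
    for start in _starts(fam, ipd):
        x0 = _transform(fam, start)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, x0, method="BFGS",
                                    options={"gtol": 1e-8, "maxiter": 500})
            # polish with Nelder-Mead; helps when BFGS stalls on a kink
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-9, "fatol": 1e-9,
                                              "maxiter": 2000})
        cand = res2 if res2.fun <= res.fun else res
        ok = bool(np.isfinite(cand.fun) and cand.fun < 1e11)
        candidates.append((cand, ok and bool(res.success or res2.success)))

    finite = [c for c in candidates if np.isfinite(c[0].fun) and c[0].fun < 1e11]
    res, converged = min(finite or candidates, key=lambda c: c[0].fun)
    p = _untransform(fam, res.x)
    ll = -float(res.fun)
    if not np.isfinite(ll) or res.fun >= 1e11:
        converged = False
        warns.append("optimizer failed to find a finite likelihood")
    if fam.name == "gompertz" and p[0] < 0:
        warns.append(
            "Gompertz shape < 0: survival plateaus above 0 (improper distribution)"
        )
    return FittedModel(
        family=fam.name,
        params=dict(zip(fam.param_names, map(float, p))),
        loglik=ll, aic=2 * fam.k - 2 * ll, n=n, n_events=d,
        converged=bool(converged), warnings=warns,
    )


def fit_menu(ipd, families: Sequence[str] | None = None) -> list[FittedModel]:
    """Fit every family and return the menu sorted by AIC (non-converged
    fits are kept, flagged and sorted last)."""
    fams = list(families) if families is not None else list(FAMILIES)
    menu = []
    for name in fams:
        try:
            menu.append(fit_parametric(ipd, name))
        except InvalidParameterError as exc:
            menu.append(
                FittedModel(family=name, params={}, loglik=float("nan"),
                            aic=float("inf"), n=len(ipd.time),
                            n_events=int(np.sum(ipd.event)), converged=False,
                            warnings=[str(exc)])
            )
    menu.sort(key=lambda m: (not m.converged, m.aic))
    return menu


def evaluate(model, t, kind: str = "survival"):
    """Evaluate a survival curve at times ``t`` (months, >= 0).

    kind is one of 'survival', 'hazard', 'cumhazard'.
    """
    t = np.asarray(t, dtype=float)
    _check_nonneg_time(t)
    if kind == "survival":
        return model.survival(t)
    if kind == "hazard":
        return model.hazard(t)
    if kind == "cumhazard":
        return model.cumhazard(t)
    raise InvalidParameterError(f"unknown kind '{kind}'")


# ---------------------------------------------------------------------------
# analytic quantile helpers (used by the synthetic-trial generator)
# ---------------------------------------------------------------------------

def inverse_survival(family: str, params: Sequence[float], u):
    """Return t such that S(t) = u, for the families with a closed-form or
    library-backed inverse.  ``u`` in (0, 1]."""
    fam = _get_family(family)
    p = fam.check_domain(params)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u > 1)):
        raise InvalidParameterError("survival level must be in (0, 1]")
    name = fam.name
    H = -np.log(u)
    if name == "exponential":
        return H / p[0]
    if name == "weibull":
        shape, scale = p
        return scale * H ** (1.0 / shape)
    if name == "gompertz":
        shape, rate = p
        if abs(shape) < 1e-9:
            return H / rate
        arg = 1.0 + shape * H / rate
        if np.any(arg <= 0):
            raise InvalidParameterError(
                "improper Gompertz: requested survival level never reached"
            )
        return np.log(arg) / shape
    if name == "log-logistic":
        shape, scale = p
        return scale * (1.0 / u - 1.0) ** (1.0 / shape)
    if name == "log-normal":
        meanlog, sdlog = p
        return np.exp(meanlog + sdlog * stats.norm.isf(u))
    if name == "gamma":
        shape, rate = p
        return stats.gamma.isf(u, shape, scale=1.0 / rate)
    raise InvalidParameterError(
        f"inverse survival not implemented for family '{name}'"
    )
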