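"""Univariate (one-at-a-time) deterministic sensitivity analysis.

Sweepable parameters: hazard ratios, the discount rate, unit costs and the
three utility weights (resource-use quantities are deliberately not
swept).  Each scenario reruns the full engine with every other parameter
held at base; a scenario in which the engine halts on the OS < PFS guard
is recorded with status ``engine-failure`` and the sweep continues.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidParameterError, InvalidRangeError, LogicalInconsistencyError
from .psm_engine import PSMResults, icer, run_psm

__all__ = ["DSAResult", "DSAScenario", "run_dsa", "tornado_order"]


@dataclass
class DSAScenario:
    parameter: str
    side: str  # low | high
    value: float
    status: str  # ok | engine-failure | icer-undefined
    icer: float | None = None
    icer_flag: str = ""
    inc_cost: float | None = None
    inc_qaly: float | None = None
    failure_cycle: int | None = None


@dataclass
class DSAResult:
    base_icer: float | None
    base_icer_flag: str
    base_results: PSMResults
    scenarios: list[DSAScenario]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        params = sorted({s.parameter for s in self.scenarios})
        by_key = {(s.parameter, s.side): s for s in self.scenarios}
        for p in params:
            lo, hi = by_key[(p, "low")], by_key[(p, "high")]
            rows.append({
                "parameter": p,
                "low": lo.value, "high": hi.value,
                "icer_low": "" if lo.icer is None else lo.icer,
                "icer_high": "" if hi.icer is None else hi.icer,
                "status_low": lo.status, "status_high": hi.status,
                "inc_cost_low": lo.inc_cost, "inc_cost_high": hi.inc_cost,
                "inc_qaly_low": lo.inc_qaly, "inc_qaly_high": hi.inc_qaly,
            })
        return pd.DataFrame(rows)


def _apply_override(inputs, name: str, value: float):
    """Return a deep copy of ``inputs`` with one parameter replaced."""
    out = copy.deepcopy(inputs)
    if name == "hr_os":
        out.hr_os = value
    elif name == "hr_pfs":
        out.hr_pfs = value
    elif name == "discount_rate":
        out.annual_discount_rate = value
    elif name in ("u_pfs_intervention", "u_pfs_control", "u_pps"):
        out.utilities[name] = value
    elif name.startswith("cost:"):
        target = name[len("cost:"):]
        hit = False
        for item in out.resources:
            if item.name == target:
                item.unit_cost = value
                hit = True
        if not hit:
            raise InvalidParameterError(
                f"DSA names unknown cost parameter '{target}'")
    else:
        raise InvalidParameterError(f"DSA cannot sweep parameter '{name}'")
    return out


def _base_value(inputs, name: str) -> float:
    if name == "hr_os":
        return float(inputs.hr_os)
    if name == "hr_pfs":
        return float(inputs.hr_pfs)
    if name == "discount_rate":
        return float(inputs.annual_discount_rate)
    if name in ("u_pfs_intervention", "u_pfs_control", "u_pps"):
        return float(inputs.utilities[name])
    if name.startswith("cost:"):
        target = name[len("cost:"):]
        for item in inputs.resources:
            if item.name == target:
                return float(item.unit_cost)
    raise InvalidParameterError(f"DSA names unknown parameter '{name}'")


def run_dsa(inputs, pfs_model, os_model,
            hr_pfs: float | None = None, hr_os: float | None = None,
            half_cycle: str = "trapezoid") -> DSAResult:
    """One-at-a-time sweep over every range in ``inputs.dsa_ranges``.

    ``hr_pfs``/``hr_os`` override the template values when the HRs were
    estimated from the data; HR sweeps then perturb around those.
    """
    base_inputs = copy.deepcopy(inputs)
    if hr_pfs is not None:
        base_inputs.hr_pfs = float(hr_pfs)
    if hr_os is not None:
        base_inputs.hr_os = float(hr_os)

    _, base_results = run_psm(base_inputs, pfs_model, os_model,
                              half_cycle=half_cycle)
    scenarios: list[DSAScenario] = []
    for name, (low, high) in base_inputs.dsa_ranges.items():
        base = _base_value(base_inputs, name)
        if not (low <= base + 1e-12 and base - 1e-12 <= high):
            raise InvalidRangeError(
                f"DSA range for '{name}' [{low}, {high}] does not bracket "
                f"the base value {base}")
        for side, value in (("low", low), ("high", high)):
            scen = DSAScenario(parameter=name, side=side, value=value,
                               status="ok")
            try:
                mod = _apply_override(base_inputs, name, value)
                _, res = run_psm(mod, pfs_model, os_model,
                                 half_cycle=half_cycle)
            except LogicalInconsistencyError as exc:
                scen.status = "engine-failure"
                scen.failure_cycle = exc.cycle
            else:
                scen.inc_cost = res.inc_cost_disc
                scen.inc_qaly = res.inc_qaly_disc
                val = icer(res.inc_cost_disc, res.inc_qaly_disc)
                scen.icer, scen.icer_flag = val.value, val.flag
                if val.flag == "undefined":
                    scen.status = "icer-undefined"
            scenarios.append(scen)

    return DSAResult(
        base_icer=base_results.icer.value,
        base_icer_flag=base_results.icer.flag,
        base_results=base_results,
        scenarios=scenarios,
    )


def tornado_order(dsa: DSAResult, include: list[str] | None = None,
                  exclude: list[str] | None = None) -> pd.DataFrame:
    """Tornado-chart table: parameters sorted by descending ICER range.

    Parameters with a failed or undefined scenario are ordered by their
    one-sided excursion from the base ICER and placed after fully-ok
    parameters, flagged in the status columns.
    """
    by_key = {(s.parameter, s.side): s for s in dsa.scenarios}
    params = sorted({s.parameter for s in dsa.scenarios})
    if include is not None:
        params = [p for p in params if p in include]
    if exclude is not None:
        params = [p for p in params if p not in exclude]
    base = dsa.base_icer if dsa.base_icer is not None else 0.0

    rows = []
    for p in params:
        lo, hi = by_key[(p, "low")], by_key[(p, "high")]
        ok = lo.status == "ok" and hi.status == "ok"
        if ok:
            extent = abs(hi.icer - lo.icer)
        else:
            vals = [s.icer for s in (lo, hi) if s.icer is not None]
            extent = max((abs(v - base) for v in vals), default=0.0)
        rows.append({
            "parameter": p,
            "icer_low": lo.icer if lo.icer is not None else "",
            "icer_high": hi.icer if hi.icer is not None else "",
            "status_low": lo.status, "status_high": hi.status,
            "extent": extent, "all_ok": ok,
        })
    rows.sort(key=lambda r: (not r["all_ok"], -r["extent"]))
    frame = pd.DataFrame(rows)
    return frame.drop(columns=["all_ok"]) if len(frame) else frame
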