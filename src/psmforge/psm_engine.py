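"""Three-state partitioned survival engine.

State occupancy comes directly from the two survival curves: at time t,
progression-free = S_PFS(t), post-progression = S_OS(t) - S_PFS(t),
dead = 1 - S_OS(t).  Cycles are one month, 1-based, cycle c spanning
(c-1, c].  The half-cycle correction is the trapezoid (life-table) form
by default - per-cycle occupancy = mean of the start- and end-of-cycle
values - with the midpoint-evaluation alternative available behind
``half_cycle='midpoint'``.  Discounting uses the annual rate converted to
a monthly equivalent and is evaluated at the cycle midpoint.

If OS falls below PFS at any evaluated boundary the engine raises
:class:`~psmforge.errors.LogicalInconsistencyError` and halts; it never
silently clamps the curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, LogicalInconsistencyError
from .hazard_tools import apply_hr
from .resource_costing import cycle_costs
from .surv_models import SurvivalCurve

__all__ = ["ArmTrace", "ICERValue", "PSMResults", "Trace",
           "discount_factor", "icer", "run_psm", "state_occupancy"]

_GUARD_TOL = 1e-9
ARMS = ("control", "intervention")


# ---------------------------------------------------------------------------
# occupancy and discounting
# ---------------------------------------------------------------------------

def state_occupancy(pfs: SurvivalCurve, os: SurvivalCurve,
                    horizon_months: int) -> pd.DataFrame:
    """State occupancy at cycle boundaries 0..T (months).

    Columns: time, pfs, pps, dead.  Aborts with a logical-inconsistency
    error when S_OS < S_PFS - 1e-9 at any boundary.
    """
    if horizon_months < 1:
        raise InvalidParameterError("horizon must be >= 1 month")
    t = np.arange(int(horizon_months) + 1, dtype=float)
    s_pfs = np.asarray(pfs.survival(t), dtype=float)
    s_os = np.asarray(os.survival(t), dtype=float)
    bad = np.nonzero(s_os < s_pfs - _GUARD_TOL)[0]
    if bad.size:
        c = int(bad[0])
        raise LogicalInconsistencyError(
            f"OS probability ({s_os[c]:.6f}) fell below PFS "
            f"({s_pfs[c]:.6f}) at month {c}; the partitioned survival "
            "structure is logically inconsistent over this horizon",
            cycle=c,
        )
    return pd.DataFrame(
        {"time": t, "pfs": s_pfs, "pps": s_os - s_pfs, "dead": 1.0 - s_os}
    )


def discount_factor(annual_rate: float, t_months) -> np.ndarray:
    """(1 + r)^(-t/12): the annual rate compounded at its monthly
    equivalent for ``t_months`` months."""
    if annual_rate < 0:
        raise InvalidParameterError("discount rate must be >= 0")
    t = np.asarray(t_months, dtype=float)
    return (1.0 + annual_rate) ** (-t / 12.0)


def _per_cycle(values: np.ndarray, half_cycle: str,
               curve=None, t=None) -> np.ndarray:
    """Collapse boundary values (length T+1) to per-cycle values (length T)."""
    if half_cycle == "trapezoid":
        return 0.5 * (values[:-1] + values[1:])
    if half_cycle == "midpoint":
        mid = np.asarray(t[:-1] + 0.5, dtype=float)
        return np.asarray(curve(mid), dtype=float)
    raise InvalidParameterError(f"unknown half-cycle mode '{half_cycle}'")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class ArmTrace:
    arm: str
    cycle: np.ndarray  # 1..T
    pfs: np.ndarray  # half-cycle-corrected per-cycle occupancy
    pps: np.ndarray
    dead: np.ndarray
    cost: np.ndarray
    cost_disc: np.ndarray
    qaly: np.ndarray  # years
    qaly_disc: np.ndarray
    ly: np.ndarray  # years
    ly_disc: np.ndarray


@dataclass
class Trace:
    arms: dict[str, ArmTrace]
    boundaries: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in ARMS:
            a = self.arms[arm]
            rows.append(pd.DataFrame({
                "arm": arm, "cycle": a.cycle.astype(int),
                "pfs": a.pfs, "pps": a.pps, "dead": a.dead,
                "cost": a.cost, "cost_disc": a.cost_disc,
                "qaly": a.qaly, "qaly_disc": a.qaly_disc,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ICERValue:
    value: float | None
    flag: str  # ok | undefined | dominant-or-check-signs | dominated-negative

    def render(self) -> str:
        if self.flag == "undefined" or self.value is None:
            return "undefined"
        return f"{self.value:.6g}"


@dataclass
class PSMResults:
    totals: dict[str, dict[str, float]]  # arm -> metric -> value
    inc_cost: float
    inc_qaly: float
    inc_ly: float
    inc_cost_disc: float
    inc_qaly_disc: float
    inc_ly_disc: float
    icer: ICERValue
    icer_undisc: ICERValue

    def to_frame(self) -> pd.DataFrame:
        metrics = ["cost", "cost_disc", "ly", "ly_disc", "qaly", "qaly_disc"]
        incs = {"cost": self.inc_cost, "cost_disc": self.inc_cost_disc,
                "ly": self.inc_ly, "ly_disc": self.inc_ly_disc,
                "qaly": self.inc_qaly, "qaly_disc": self.inc_qaly_disc}
        rows = [
            {"metric": m, "control": self.totals["control"][m],
             "intervention": self.totals["intervention"][m],
             "incremental": incs[m]}
            for m in metrics
        ]
        rows.append({"metric": "icer_disc", "control": "", "intervention": "",
                     "incremental": self.icer.render()})
        rows.append({"metric": "icer_undisc", "control": "", "intervention": "",
                     "incremental": self.icer_undisc.render()})
        rows.append({"metric": "icer_flag", "control": "", "intervention": "",
                     "incremental": self.icer.flag})
        return pd.DataFrame(rows)


def icer(inc_cost: float, inc_effect: float) -> ICERValue:
    """Incremental cost-effectiveness ratio with explicit sign bookkeeping.

    A zero incremental effect yields the 'undefined' sentinel; negative
    ratios are reported but flagged, never masked.
    """
    if inc_effect == 0:
        return ICERValue(value=None, flag="undefined")
    value = inc_cost / inc_effect
    if inc_effect > 0 and inc_cost < 0:
        return ICERValue(value=value, flag="dominant-or-check-signs")
    if inc_effect < 0 and inc_cost > 0:
        return ICERValue(value=value, flag="dominated-negative")
    if inc_effect < 0 and inc_cost < 0:
        return ICERValue(value=value, flag="dominant-or-check-signs")
    return ICERValue(value=value, flag="ok")


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def run_psm(inputs, pfs_model: SurvivalCurve, os_model: SurvivalCurve,
            hr_pfs: float | None = None, hr_os: float | None = None,
            half_cycle: str = "trapezoid") -> tuple[Trace, PSMResults]:
    """Run the three-state model for both arms.

    ``pfs_model`` / ``os_model`` are the CONTROL-arm curves; the
    intervention arm is derived by multiplying their hazards by the
    hazard ratios (taken from ``inputs`` unless given explicitly, which
    is required when the template says "estimate").
    """
    if hr_pfs is None:
        hr_pfs = _numeric_hr(inputs.hr_pfs, "PFS")
    if hr_os is None:
        hr_os = _numeric_hr(inputs.hr_os, "OS")
    T = int(inputs.horizon_months)
    rate = float(inputs.annual_discount_rate)
    u_pps = float(inputs.utilities["u_pps"])
    u_pfs = {"control": float(inputs.utilities["u_pfs_control"]),
             "intervention": float(inputs.utilities["u_pfs_intervention"])}
    costmat = cycle_costs(inputs.resources, T)

    curves = {
        "control": (pfs_model, os_model),
        "intervention": (apply_hr(pfs_model, hr_pfs), apply_hr(os_model, hr_os)),
    }
    df_mid = discount_factor(rate, np.arange(1, T + 1) - 0.5)

    arm_traces: dict[str, ArmTrace] = {}
    boundaries: dict[str, pd.DataFrame] = {}
    totals: dict[str, dict[str, float]] = {}
    for arm, (pfs_c, os_c) in curves.items():
        occ = state_occupancy(pfs_c, os_c, T)
        boundaries[arm] = occ
        t = occ["time"].to_numpy()
        pfs_cc = _per_cycle(occ["pfs"].to_numpy(), half_cycle, pfs_c.survival, t)
        os_b = occ["pfs"].to_numpy() + occ["pps"].to_numpy()
        os_cc = _per_cycle(os_b, half_cycle, os_c.survival, t)
        pps_cc = os_cc - pfs_cc
        dead_cc = 1.0 - os_cc

        cost_c = (pfs_cc * costmat[(arm, "PFS")] + pps_cc * costmat[(arm, "PPS")])
        ly_c = os_cc / 12.0  # one month of survival, in years
        qaly_c = (u_pfs[arm] * pfs_cc + u_pps * pps_cc) / 12.0

        arm_traces[arm] = ArmTrace(
            arm=arm, cycle=np.arange(1, T + 1),
            pfs=pfs_cc, pps=pps_cc, dead=dead_cc,
            cost=cost_c, cost_disc=cost_c * df_mid,
            qaly=qaly_c, qaly_disc=qaly_c * df_mid,
            ly=ly_c, ly_disc=ly_c * df_mid,
        )
        a = arm_traces[arm]
        totals[arm] = {
            "cost": float(a.cost.sum()), "cost_disc": float(a.cost_disc.sum()),
            "ly": float(a.ly.sum()), "ly_disc": float(a.ly_disc.sum()),
            "qaly": float(a.qaly.sum()), "qaly_disc": float(a.qaly_disc.sum()),
        }

    inc = {m: totals["intervention"][m] - totals["control"][m]
           for m in totals["control"]}
    results = PSMResults(
        totals=totals,
        inc_cost=inc["cost"], inc_qaly=inc["qaly"], inc_ly=inc["ly"],
        inc_cost_disc=inc["cost_disc"], inc_qaly_disc=inc["qaly_disc"],
        inc_ly_disc=inc["ly_disc"],
        icer=icer(inc["cost_disc"], inc["qaly_disc"]),
        icer_undisc=icer(inc["cost"], inc["qaly"]),
    )
    return Trace(arms=arm_traces, boundaries=boundaries), results


def _numeric_hr(value, endpoint: str) -> float:
    if isinstance(value, str):
        raise InvalidParameterError(
            f"hazard ratio for {endpoint} is '{value}'; estimate it first "
            "(hr_source='estimate') and pass the numeric value to run_psm")
    v = float(value)
    if not v > 0:
        raise InvalidParameterError(f"hazard ratio for {endpoint} must be > 0")
    return v


# test-only helper: mean months in the OS state by trapezoid integration on
# a sub-cycle grid; verifies the half-cycle correction is second order
def _trapz_ly_months(os_curve: SurvivalCurve, horizon_months: int,
                     substeps: int = 1) -> float:
    t = np.linspace(0.0, horizon_months, horizon_months * substeps + 1)
    s = np.asarray(os_curve.survival(t), dtype=float)
    return float(np.trapezoid(s, t))
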