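"""Synthetic-trial generator: ground-truth IPD, digitized curves, risk
tables and complete input templates, so every pipeline stage is testable
without any external download.

Coupling device (a QA construction, not a clinical claim): overall
survival is drawn first, then progression-free survival is the minimum of
that death time and an independent progression time, which guarantees
PFS <= OS subject by subject.  The intervention arm is drawn through the
constant-HR power rule S**hr, consistent with the extrapolation engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .io_template import ModelInputs, write_template
from .km_reconstruct import DigitizedCurve, IPDSet, km_curve
from .resource_costing import ResourceItem, Schedule
from .surv_models import inverse_survival

__all__ = ["TrialSpec", "digitize", "make_template", "simulate_arm",
           "simulate_trial"]


@dataclass
class TrialSpec:
    """Control-arm truth + hazard ratios for one synthetic two-arm trial."""

    os_family: str = "weibull"
    os_params: tuple[float, ...] = (1.2, 24.0)
    progression_family: str = "weibull"  # time to progression, independent
    progression_params: tuple[float, ...] = (1.1, 10.0)
    hr_os: float = 0.7
    hr_pfs: float = 0.5
    n_per_arm: int = 300
    censor_time: float = 36.0  # administrative censoring, months
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 10:
            raise InvalidParameterError("n_per_arm must be >= 10")
        if not (self.hr_os > 0 and self.hr_pfs > 0):
            raise InvalidParameterError("hazard ratios must be > 0")
        if not self.censor_time > 0:
            raise InvalidParameterError("censor_time must be > 0")


def _draw(family, params, hr, n, rng):
    """Event times with survival S_ctrl**hr via inverse transform."""
    u = rng.uniform(size=n)
    return np.asarray(inverse_survival(family, params, u ** (1.0 / hr)))


def simulate_arm(family: str, params, n: int, hr: float = 1.0,
                 censor_time: float = np.inf, rng=None,
                 arm: str = "", endpoint: str = "") -> IPDSet:
    """One single-endpoint arm with administrative censoring."""
    rng = np.random.default_rng(rng)
    t = _draw(family, params, hr, n, rng)
    event = (t <= censor_time).astype(int)
    return IPDSet(time=np.minimum(t, censor_time), event=event,
                  arm=arm, endpoint=endpoint)


def simulate_trial(spec: TrialSpec) -> tuple[dict[tuple[str, str], IPDSet], dict]:
    """Simulate both arms and endpoints.

    Returns ``({(endpoint, arm): IPDSet}, truth)`` where truth records the
    generating parameters.  PFS <= OS holds for every subject.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ipd: dict[tuple[str, str], IPDSet] = {}
    for arm, hr_os, hr_pfs in (("control", 1.0, 1.0),
                               ("intervention", spec.hr_os, spec.hr_pfs)):
        t_os = _draw(spec.os_family, spec.os_params, hr_os, spec.n_per_arm, rng)
        t_prog = _draw(spec.progression_family, spec.progression_params,
                       hr_pfs, spec.n_per_arm, rng)
        t_pfs = np.minimum(t_os, t_prog)
        for endpoint, t in (("OS", t_os), ("PFS", t_pfs)):
            event = (t <= spec.censor_time).astype(int)
            ipd[(endpoint, arm)] = IPDSet(
                time=np.minimum(t, spec.censor_time), event=event,
                arm=arm, endpoint=endpoint)
    truth = {
        "os_family": spec.os_family, "os_params": list(spec.os_params),
        "progression_family": spec.progression_family,
        "progression_params": list(spec.progression_params),
        "hr_os": spec.hr_os, "hr_pfs": spec.hr_pfs,
        "n_per_arm": spec.n_per_arm, "censor_time": spec.censor_time,
        "seed": spec.seed,
    }
    return ipd, truth


def digitize(ipd: IPDSet, grid, risk_times=None,
             include_total_events: bool = False) -> DigitizedCurve:
    """Emulate what a user extracts from a published plot: KM probabilities
    at the grid times plus a numbers-at-risk table."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0:
        grid = np.concatenate([[0.0], grid])
    if risk_times is None:
        risk_times = grid
    risk_times = np.asarray(risk_times, dtype=float)
    curve = km_curve(ipd)
    probs = curve.evaluate(grid)
    n_at_risk = np.array([int(np.sum(ipd.time >= t - 1e-12))
                          for t in risk_times])
    return DigitizedCurve(
        endpoint=ipd.endpoint or "OS", arm=ipd.arm or "control",
        times=grid, surv_probs=probs,
        risk_times=risk_times, n_at_risk=n_at_risk,
        total_events=int(ipd.event.sum()) if include_total_events else None,
    )


@dataclass
class EconParams:
    """Economic side of a generated template."""

    annual_discount_rate: float = 0.03
    horizon_months: int = 60
    utilities: dict[str, float] = field(default_factory=lambda: {
        "u_pfs_intervention": 1.0, "u_pfs_control": 1.0, "u_pps": 1.0})
    drug_cost_intervention: float = 2000.0
    drug_cost_control: float = 1500.0
    next_line_cost: float = 0.0
    dsa_ranges: dict[str, tuple[float, float]] | None = None


def build_inputs(spec: TrialSpec, econ: EconParams | None = None,
                 grid=None, risk_times=None, hr_mode: str = "truth",
                 include_total_events: bool = False,
                 dist_pfs: str = "weibull", dist_os: str = "weibull") -> ModelInputs:
    """Simulate a trial and assemble a fully validated ModelInputs."""
    econ = econ or EconParams()
    ipd, _ = simulate_trial(spec)
    if grid is None:
        grid = np.arange(0.0, np.floor(spec.censor_time) + 1)
    if risk_times is None:
        risk_times = np.asarray(grid, dtype=float)[::6]
    curves = {}
    for key, arm_ipd in ipd.items():
        c = digitize(arm_ipd, grid, risk_times,
                     include_total_events=include_total_events)
        curves[key] = c

    resources = [
        ResourceItem(name="drug_intervention", arm="intervention", state="PFS",
                     unit_cost=econ.drug_cost_intervention,
                     schedule=Schedule.constant(1.0, "per_month")),
        ResourceItem(name="drug_control", arm="control", state="PFS",
                     unit_cost=econ.drug_cost_control,
                     schedule=Schedule.constant(1.0, "per_month")),
        ResourceItem(name="next_line", arm="intervention", state="PPS",
                     unit_cost=econ.next_line_cost,
                     schedule=Schedule.constant(1.0, "per_month")),
        ResourceItem(name="next_line", arm="control", state="PPS",
                     unit_cost=econ.next_line_cost,
                     schedule=Schedule.constant(1.0, "per_month")),
    ]
    if hr_mode == "truth":
        hr_os, hr_pfs = spec.hr_os, spec.hr_pfs
    elif hr_mode == "estimate":
        hr_os = hr_pfs = "estimate"
    else:
        raise InvalidParameterError("hr_mode must be 'truth' or 'estimate'")
    dsa = econ.dsa_ranges
    if dsa is None:
        dsa = {"discount_rate": (0.0, 0.06)}
        if hr_mode == "truth":
            dsa["hr_os"] = (max(0.5 * spec.hr_os, 1e-3), min(1.5 * spec.hr_os, 5.0))
    inputs = ModelInputs(
        curves=curves, hr_os=hr_os, hr_pfs=hr_pfs,
        annual_discount_rate=econ.annual_discount_rate,
        horizon_months=econ.horizon_months,
        utilities=dict(econ.utilities), resources=resources,
        dsa_ranges=dsa, dist_pfs=dist_pfs, dist_os=dist_os,
    )
    inputs.validate()
    return inputs


def make_template(spec: TrialSpec, econ: EconParams | None = None,
                  out_dir=".", **kwargs) -> Path:
    """Write a complete, read_template-valid CSV template plus a sidecar
    ``truth.json`` recording the generating parameters."""
    out = Path(out_dir)
    inputs = build_inputs(spec, econ, **kwargs)
    write_template(inputs, out)
    _, truth = simulate_trial(spec)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return out
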