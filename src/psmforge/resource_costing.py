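"""Translate posology / resource-use schedules into exact per-model-cycle
unit consumption and costs.

Conventions (applied consistently everywhere):

* one model cycle = one month = 365.25 / 12 = 30.4375 days; a week = 7 days;
* administration events on a cycle boundary belong to the LATER cycle
  (half-open binning ``[start, end)``);
* treatment-cycle caps count from model start.

Schedule grammar - each phase has a quantity, a frequency unit and a
window.  Frequency units:

``per_day`` / ``per_week`` / ``per_month``
    rate-type: continuous consumption, converted by exact day-count
    proportioning so no units are lost at cycle boundaries;
``every_K_weeks`` (K >= 1; ``every_1_weeks`` = weekly)
    event-type: one administration of ``quantity`` units at the phase
    start day and every 7K days thereafter while inside the window;
``on_days:d1;d2;...``
    event-type: administrations on the listed days counted from model
    start.

Windows are 1-based inclusive ordinal ranges in ``phase_unit`` periods
(``day``, ``week``, ``month``, ``txcycle`` of ``txcycle_length_weeks``
weeks): a phase over treatment cycles 1-2 of 4 weeks covers days [0, 56).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, InvalidScheduleError

__all__ = ["DAYS_PER_MONTH", "Phase", "ResourceItem", "Schedule",
           "cycle_costs", "dose_units", "expand_schedule"]

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375
_PERIOD_DAYS = {"per_day": 1.0, "per_week": 7.0, "per_month": DAYS_PER_MONTH}
_PHASE_UNIT_DAYS = {"day": 1.0, "week": 7.0, "month": DAYS_PER_MONTH}


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    quantity: float
    unit: str  # per_day | per_week | per_month | every_K_weeks | on_days:...
    start: float = 1.0  # 1-based ordinal of the first period in the window
    end: float = math.inf  # ordinal of the last period (inclusive)
    phase_unit: str = "month"  # day | week | month | txcycle
    txcycle_length_weeks: float | None = None

    def window_days(self) -> tuple[float, float]:
        if self.phase_unit == "txcycle":
            if not self.txcycle_length_weeks or self.txcycle_length_weeks <= 0:
                raise InvalidScheduleError(
                    "phase_unit 'txcycle' requires txcycle_length_weeks > 0")
            u = 7.0 * self.txcycle_length_weeks
        else:
            try:
                u = _PHASE_UNIT_DAYS[self.phase_unit]
            except KeyError:
                raise InvalidScheduleError(
                    f"unknown phase_unit '{self.phase_unit}'") from None
        lo = (self.start - 1.0) * u
        hi = self.end * u if math.isfinite(self.end) else math.inf
        if self.quantity < 0:
            raise InvalidScheduleError("phase quantity must be >= 0")
        if hi <= lo:
            raise InvalidScheduleError(
                f"empty phase window [{self.start}, {self.end}] in "
                f"{self.phase_unit}s")
        return lo, hi


@dataclass
class Schedule:
    phases: list[Phase]
    cap_txcycles: float | None = None  # max treatment cycles from model start
    cap_administrations: int | None = None

    def validate(self) -> None:
        if not self.phases:
            raise InvalidScheduleError("schedule has no phases")
        windows = sorted(p.window_days() for p in self.phases)
        for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
            if lo2 < hi1 - 1e-9:
                raise InvalidScheduleError(
                    f"overlapping phases: [{lo1:g}, {hi1:g}) and "
                    f"[{lo2:g}, {hi2:g}) days")

    def cap_day(self) -> float:
        if self.cap_txcycles is None:
            return math.inf
        lengths = {p.txcycle_length_weeks for p in self.phases
                   if p.txcycle_length_weeks}
        if not lengths:
            raise InvalidScheduleError(
                "cap in treatment cycles requires txcycle_length_weeks")
        if len(lengths) > 1:
            raise InvalidScheduleError(
                "cap in treatment cycles is ambiguous: phases declare "
                f"different txcycle lengths {sorted(lengths)}")
        return self.cap_txcycles * 7.0 * lengths.pop()

    @classmethod
    def constant(cls, quantity: float, unit: str) -> "Schedule":
        """Time-constant rate schedule (the only kind allowed in PPS)."""
        if unit not in _PERIOD_DAYS:
            raise InvalidScheduleError(
                f"a constant schedule needs a rate unit (per_day/per_week/"
                f"per_month), got '{unit}'")
        return cls(phases=[Phase(quantity=quantity, unit=unit)])


@dataclass
class ResourceItem:
    name: str
    arm: str  # intervention | control
    state: str  # PFS | PPS
    unit_cost: float
    schedule: Schedule
    dsa_range: tuple[float, float] | None = field(default=None)

    def validate(self) -> None:
        if self.unit_cost < 0:
            raise InvalidParameterError(
                f"resource '{self.name}': unit cost must be >= 0")
        if self.state not in ("PFS", "PPS"):
            raise InvalidParameterError(
                f"resource '{self.name}': state must be PFS or PPS")
        if self.arm not in ("intervention", "control"):
            raise InvalidParameterError(
                f"resource '{self.name}': arm must be intervention or control")
        self.schedule.validate()
        if self.state == "PPS":
            for p in self.schedule.phases:
                if p.unit not in _PERIOD_DAYS or math.isfinite(p.end) or p.start != 1.0:
                    raise InvalidScheduleError(
                        f"resource '{self.name}': post-progression consumption "
                        "cannot vary over time (constant rate schedules only)")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dose_units(dose_mg_per_kg: float, weight_kg: float, vial_mg: float,
               wastage: str = "none") -> float:
    """Units (vials) per administration for a weight-based dose.

    ``wastage='none'`` allows fractional vials; ``'round-up-vial'`` takes
    the ceiling (whole vials only).
    """
    for name, v in (("dose_mg_per_kg", dose_mg_per_kg),
                    ("weight_kg", weight_kg), ("vial_mg", vial_mg)):
        if not v > 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v}")
    units = dose_mg_per_kg * weight_kg / vial_mg
    if wastage == "none":
        return units
    if wastage == "round-up-vial":
        return float(math.ceil(units - 1e-9))
    raise InvalidParameterError(f"unknown wastage policy '{wastage}'")


def _parse_every_k_weeks(unit: str) -> float | None:
    if unit.startswith("every_") and unit.endswith("_weeks"):
        mid = unit[len("every_"):-len("_weeks")]
        try:
            k = float(mid)
        except ValueError:
            raise InvalidScheduleError(f"cannot parse frequency unit '{unit}'")
        if k <= 0:
            raise InvalidScheduleError(f"'{unit}': interval must be positive")
        return 7.0 * k
    return None


def _admin_days(phase: Phase, cap_day: float) -> np.ndarray:
    lo, hi = phase.window_days()
    hi = min(hi, cap_day)
    if phase.unit.startswith("on_days:"):
        listed = [float(s) for s in phase.unit[len("on_days:"):].split(";") if s]
        days = np.array([d for d in listed if lo <= d < hi])
        return np.sort(days)
    period = _parse_every_k_weeks(phase.unit)
    if period is None:
        raise InvalidScheduleError(
            f"'{phase.unit}' is not an administration-type frequency unit")
    if not math.isfinite(hi):
        raise InvalidScheduleError(
            "an administration-type phase needs a finite window or cap")
    n = int(math.ceil((hi - lo) / period - 1e-9))
    return lo + period * np.arange(max(n, 0))


def expand_schedule(item: ResourceItem, horizon_months: int) -> np.ndarray:
    """Per-cycle unit consumption vector of length ``horizon_months``.

    Rate phases are converted by exact day-count overlap with each cycle;
    administration events are binned half-open (boundary -> later cycle).
    """
    if horizon_months < 1:
        raise InvalidParameterError("horizon must be >= 1 month")
    item.schedule.validate()
    out = np.zeros(int(horizon_months))
    bounds = DAYS_PER_MONTH * np.arange(horizon_months + 1)
    cap_day = item.schedule.cap_day()
    n_admin_left = (item.schedule.cap_administrations
                    if item.schedule.cap_administrations is not None else None)

    for phase in sorted(item.schedule.phases, key=lambda p: p.window_days()[0]):
        if phase.unit in _PERIOD_DAYS:
            lo, hi = phase.window_days()
            hi = min(hi, bounds[-1])
            if hi <= lo:
                continue
            rate_per_day = phase.quantity / _PERIOD_DAYS[phase.unit]
            overlap = np.clip(np.minimum(bounds[1:], hi)
                              - np.maximum(bounds[:-1], lo), 0.0, None)
            out += rate_per_day * overlap
        else:
            days = _admin_days(phase, cap_day)
            if n_admin_left is not None:
                days = days[:n_admin_left]
                n_admin_left -= len(days)
            days = days[days < bounds[-1] - 1e-12]
            idx = np.floor(days / DAYS_PER_MONTH + 1e-12).astype(int)
            np.add.at(out, idx, phase.quantity)
    return out


def cycle_costs(items: list[ResourceItem],
                horizon_months: int) -> dict[tuple[str, str], np.ndarray]:
    """Per-cycle cost vectors keyed by (arm, state); all four keys present."""
    mat = {(arm, state): np.zeros(int(horizon_months))
           for arm in ("intervention", "control") for state in ("PFS", "PPS")}
    for item in items:
        item.validate()
        mat[(item.arm, item.state)] += (
            item.unit_cost * expand_schedule(item, horizon_months))
    return mat
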