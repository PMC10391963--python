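"""Read and validate the tabular input template; write result tables.

A template is either a directory of CSV files or a single XLSX workbook
with these sheets (CSV files drop the ``.csv`` extension):

=================  ========================================================
``surv_probs``     endpoint, arm, time, surv_prob  (monthly KM coordinates)
``n_at_risk``      endpoint, arm, time, n_at_risk
``events``         endpoint, arm, total_events  (optional sheet)
``hr``             endpoint, value  (positive number or "estimate")
``discount``       annual_rate, horizon_months, dist_pfs, dist_os
``costs``          name, unit_cost, dsa_low, dsa_high  (dsa_* may be blank)
``resources_pfs``  name, arm, quantity, unit, phase_start, phase_end,
                   phase_unit, txcycle_length_weeks, cap
``resources_pps``  name, arm, quantity, unit
``utilities``      u_pfs_intervention, u_pfs_control, u_pps
``dsa``            parameter, low, high  (hr_os, hr_pfs, discount_rate,
                   u_pfs_intervention, u_pfs_control, u_pps; unit-cost
                   ranges live in the ``costs`` sheet)
=================  ========================================================

Decimals are dot-decimal with no thousands separators.  Setting all three
utility weights to 1 switches the model to life years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import (
    InvalidCurveError,
    InvalidParameterError,
    InvalidRangeError,
    TemplateIncompleteError,
)
from .km_reconstruct import DigitizedCurve
from .resource_costing import Phase, ResourceItem, Schedule

__all__ = ["ModelInputs", "read_template", "write_results", "write_template"]

SHEETS = ["surv_probs", "n_at_risk", "events", "hr", "discount", "costs",
          "resources_pfs", "resources_pps", "utilities", "dsa"]
_OPTIONAL_SHEETS = {"events"}
ENDPOINTS = ("OS", "PFS")
ARMS = ("intervention", "control")


@dataclass
class ModelInputs:
    """Validated in-memory model inputs (the template's data model)."""

    curves: dict[tuple[str, str], DigitizedCurve]  # (endpoint, arm) -> curve
    hr_os: float | str  # positive number or "estimate"
    hr_pfs: float | str
    annual_discount_rate: float
    horizon_months: int
    utilities: dict[str, float]
    resources: list[ResourceItem]
    dsa_ranges: dict[str, tuple[float, float]]
    dist_pfs: str = "weibull"
    dist_os: str = "weibull"

    @property
    def ly_mode(self) -> bool:
        """All utility weights 1 -> the model reports life years."""
        return all(abs(u - 1.0) < 1e-12 for u in self.utilities.values())

    def validate(self) -> None:
        missing = [k for e in ENDPOINTS for a in ARMS
                   if (k := (e, a)) not in self.curves]
        if missing:
            raise TemplateIncompleteError(
                f"missing digitized curves for {missing}")
        if len(self.curves) != 4:
            raise InvalidCurveError(
                f"expected exactly 4 curves, got {len(self.curves)}")
        for curve in self.curves.values():
            curve.validate()
        for name, hr in (("hr_os", self.hr_os), ("hr_pfs", self.hr_pfs)):
            if isinstance(hr, str):
                if hr != "estimate":
                    raise InvalidParameterError(
                        f"sheet 'hr': {name} must be a positive number or "
                        f"'estimate', got '{hr}'")
            elif not (float(hr) > 0):
                raise InvalidParameterError(
                    f"sheet 'hr': {name} must be > 0, got {hr}")
        if not (0 <= self.annual_discount_rate < 1):
            raise InvalidParameterError(
                "sheet 'discount': annual_rate must be in [0, 1), got "
                f"{self.annual_discount_rate}")
        if self.horizon_months < 1:
            raise InvalidParameterError(
                "sheet 'discount': horizon_months must be >= 1")
        for key in ("u_pfs_intervention", "u_pfs_control", "u_pps"):
            if key not in self.utilities:
                raise TemplateIncompleteError(
                    f"sheet 'utilities': missing column '{key}'")
            u = self.utilities[key]
            if not (0 <= u <= 1):
                raise InvalidParameterError(
                    f"sheet 'utilities': {key} must be in [0, 1], got {u}")
        for item in self.resources:
            item.validate()
        for name, (low, high) in self.dsa_ranges.items():
            base = self._dsa_base(name)
            if base is None:
                continue  # base is "estimate"; checked at run time
            if not (low <= base + 1e-12 and base - 1e-12 <= high):
                raise InvalidRangeError(
                    f"sheet 'dsa': range for '{name}' [{low}, {high}] does "
                    f"not bracket the base value {base}")

    def _dsa_base(self, name: str) -> float | None:
        if name == "hr_os":
            return None if isinstance(self.hr_os, str) else float(self.hr_os)
        if name == "hr_pfs":
            return None if isinstance(self.hr_pfs, str) else float(self.hr_pfs)
        if name == "discount_rate":
            return float(self.annual_discount_rate)
        if name in self.utilities:
            return float(self.utilities[name])
        if name.startswith("cost:"):
            target = name[len("cost:"):]
            for item in self.resources:
                if item.name == target:
                    return float(item.unit_cost)
            raise InvalidParameterError(
                f"sheet 'dsa'/'costs': range for unknown cost '{target}'")
        raise InvalidParameterError(
            f"sheet 'dsa': parameter '{name}' cannot be swept (only hazard "
            "ratios, the discount rate, unit costs and utilities)")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _load_sheets(path: Path) -> dict[str, pd.DataFrame]:
    if path.is_dir():
        sheets = {}
        for name in SHEETS:
            f = path / f"{name}.csv"
            if f.exists():
                sheets[name] = pd.read_csv(f)
        return sheets
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        all_sheets = pd.read_excel(path, sheet_name=None)
        return {k: v for k, v in all_sheets.items() if k in SHEETS}
    raise TemplateIncompleteError(
        f"template must be a directory of CSVs or an XLSX workbook: {path}")


def _require_columns(df: pd.DataFrame, sheet: str, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TemplateIncompleteError(
            f"sheet '{sheet}': missing columns {missing}")


def _num(value, sheet: str, row, col: str, allow_nan: bool = False) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise InvalidParameterError(
            f"sheet '{sheet}', row {row}: column '{col}' is not numeric "
            f"({value!r})") from None
    if math.isnan(v) and not allow_nan:
        raise InvalidParameterError(
            f"sheet '{sheet}', row {row}: column '{col}' is empty")
    return v


def read_template(path) -> ModelInputs:
    """Parse and validate a template; every failure names the offending
    sheet, row and rule."""
    path = Path(path)
    if not path.exists():
        raise TemplateIncompleteError(f"template not found: {path}")
    sheets = _load_sheets(path)
    for name in SHEETS:
        if name not in sheets and name not in _OPTIONAL_SHEETS:
            raise TemplateIncompleteError(f"missing sheet '{name}'")

    # --- curves ---
    sp = sheets["surv_probs"]
    _require_columns(sp, "surv_probs", ["endpoint", "arm", "time", "surv_prob"])
    nar = sheets["n_at_risk"]
    _require_columns(nar, "n_at_risk", ["endpoint", "arm", "time", "n_at_risk"])
    ev = sheets.get("events")
    if ev is not None:
        _require_columns(ev, "events", ["endpoint", "arm", "total_events"])

    curves: dict[tuple[str, str], DigitizedCurve] = {}
    for endpoint in ENDPOINTS:
        for arm in ARMS:
            mask = (sp["endpoint"] == endpoint) & (sp["arm"] == arm)
            sub = sp[mask].sort_values("time")
            if sub.empty:
                raise TemplateIncompleteError(
                    f"sheet 'surv_probs': no rows for {endpoint}/{arm}")
            rmask = (nar["endpoint"] == endpoint) & (nar["arm"] == arm)
            rsub = nar[rmask].sort_values("time")
            if rsub.empty:
                raise TemplateIncompleteError(
                    f"sheet 'n_at_risk': no rows for {endpoint}/{arm}")
            total_events = None
            if ev is not None:
                emask = (ev["endpoint"] == endpoint) & (ev["arm"] == arm)
                esub = ev[emask]
                if not esub.empty and not pd.isna(esub["total_events"].iloc[0]):
                    total_events = int(esub["total_events"].iloc[0])
            curve = DigitizedCurve(
                endpoint=endpoint, arm=arm,
                times=sub["time"].to_numpy(dtype=float),
                surv_probs=sub["surv_prob"].to_numpy(dtype=float),
                risk_times=rsub["time"].to_numpy(dtype=float),
                n_at_risk=rsub["n_at_risk"].to_numpy(),
                total_events=total_events,
            )
            curves[(endpoint, arm)] = curve

    # --- hazard ratios ---
    hr_df = sheets["hr"]
    _require_columns(hr_df, "hr", ["endpoint", "value"])
    hr: dict[str, float | str] = {}
    for endpoint in ENDPOINTS:
        sub = hr_df[hr_df["endpoint"] == endpoint]
        if sub.empty:
            raise TemplateIncompleteError(
                f"sheet 'hr': no row for endpoint {endpoint}")
        raw = sub["value"].iloc[0]
        if isinstance(raw, str) and raw.strip().lower() == "estimate":
            hr[endpoint] = "estimate"
        else:
            hr[endpoint] = _num(raw, "hr", int(sub.index[0]), "value")

    # --- discount / horizon / distribution choices ---
    disc = sheets["discount"]
    _require_columns(disc, "discount", ["annual_rate", "horizon_months"])
    if disc.empty:
        raise TemplateIncompleteError("sheet 'discount': no rows")
    annual_rate = _num(disc["annual_rate"].iloc[0], "discount", 0, "annual_rate")
    horizon = int(_num(disc["horizon_months"].iloc[0], "discount", 0,
                       "horizon_months"))
    dist_pfs = str(disc["dist_pfs"].iloc[0]) if "dist_pfs" in disc else "weibull"
    dist_os = str(disc["dist_os"].iloc[0]) if "dist_os" in disc else "weibull"

    # --- utilities ---
    ut = sheets["utilities"]
    _require_columns(ut, "utilities",
                     ["u_pfs_intervention", "u_pfs_control", "u_pps"])
    if ut.empty:
        raise TemplateIncompleteError("sheet 'utilities': no rows")
    utilities = {c: _num(ut[c].iloc[0], "utilities", 0, c)
                 for c in ("u_pfs_intervention", "u_pfs_control", "u_pps")}

    # --- costs ---
    costs_df = sheets["costs"]
    _require_columns(costs_df, "costs", ["name", "unit_cost"])
    unit_costs: dict[str, float] = {}
    dsa_ranges: dict[str, tuple[float, float]] = {}
    for idx, row in costs_df.iterrows():
        name = str(row["name"])
        cost = _num(row["unit_cost"], "costs", idx, "unit_cost")
        if cost < 0:
            raise InvalidParameterError(
                f"sheet 'costs', row {idx}: unit_cost must be >= 0, got {cost}")
        unit_costs[name] = cost
        lo = row.get("dsa_low")
        hi = row.get("dsa_high")
        if lo is not None and hi is not None and not (pd.isna(lo) or pd.isna(hi)):
            dsa_ranges[f"cost:{name}"] = (float(lo), float(hi))

    # --- resources ---
    resources: list[ResourceItem] = []
    rp = sheets["resources_pfs"]
    _require_columns(rp, "resources_pfs", ["name", "arm", "quantity", "unit"])
    grouped: dict[tuple[str, str], list[Phase]] = {}
    caps: dict[tuple[str, str], float | None] = {}
    for idx, row in rp.iterrows():
        name, arm = str(row["name"]), str(row["arm"])
        if arm not in ARMS:
            raise InvalidParameterError(
                f"sheet 'resources_pfs', row {idx}: arm must be one of {ARMS}")
        if name not in unit_costs:
            raise TemplateIncompleteError(
                f"sheet 'resources_pfs', row {idx}: resource '{name}' has no "
                "unit cost in sheet 'costs'")
        txlen = row.get("txcycle_length_weeks")
        txlen = None if txlen is None or pd.isna(txlen) else float(txlen)
        start = row.get("phase_start")
        end = row.get("phase_end")
        phase = Phase(
            quantity=_num(row["quantity"], "resources_pfs", idx, "quantity"),
            unit=str(row["unit"]),
            start=1.0 if start is None or pd.isna(start) else float(start),
            end=math.inf if end is None or pd.isna(end) else float(end),
            phase_unit=(str(row["phase_unit"])
                        if "phase_unit" in row and not pd.isna(row.get("phase_unit"))
                        else "month"),
            txcycle_length_weeks=txlen,
        )
        grouped.setdefault((name, arm), []).append(phase)
        cap = row.get("cap")
        if cap is not None and not pd.isna(cap):
            caps[(name, arm)] = float(cap)
    for (name, arm), phases in grouped.items():
        resources.append(ResourceItem(
            name=name, arm=arm, state="PFS", unit_cost=unit_costs[name],
            schedule=Schedule(phases=phases, cap_txcycles=caps.get((name, arm))),
        ))

    rq = sheets["resources_pps"]
    _require_columns(rq, "resources_pps", ["name", "arm", "quantity", "unit"])
    for idx, row in rq.iterrows():
        name, arm = str(row["name"]), str(row["arm"])
        if arm not in ARMS:
            raise InvalidParameterError(
                f"sheet 'resources_pps', row {idx}: arm must be one of {ARMS}")
        if name not in unit_costs:
            raise TemplateIncompleteError(
                f"sheet 'resources_pps', row {idx}: resource '{name}' has no "
                "unit cost in sheet 'costs'")
        resources.append(ResourceItem(
            name=name, arm=arm, state="PPS", unit_cost=unit_costs[name],
            schedule=Schedule.constant(
                _num(row["quantity"], "resources_pps", idx, "quantity"),
                str(row["unit"])),
        ))

    # --- dsa sheet ---
    dsa_df = sheets["dsa"]
    if len(dsa_df):
        _require_columns(dsa_df, "dsa", ["parameter", "low", "high"])
        for idx, row in dsa_df.iterrows():
            dsa_ranges[str(row["parameter"])] = (
                _num(row["low"], "dsa", idx, "low"),
                _num(row["high"], "dsa", idx, "high"),
            )

    inputs = ModelInputs(
        curves=curves, hr_os=hr["OS"], hr_pfs=hr["PFS"],
        annual_discount_rate=annual_rate, horizon_months=horizon,
        utilities=utilities, resources=resources, dsa_ranges=dsa_ranges,
        dist_pfs=dist_pfs, dist_os=dist_os,
    )
    inputs.validate()
    return inputs


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_template(inputs: ModelInputs, out_dir) -> list[Path]:
    """Write a ModelInputs back to a directory of template CSVs
    (read_template of the result reproduces an equal ModelInputs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    sp_rows, nar_rows, ev_rows = [], [], []
    for (endpoint, arm), c in inputs.curves.items():
        for t, s in zip(c.times, c.surv_probs):
            sp_rows.append({"endpoint": endpoint, "arm": arm,
                            "time": t, "surv_prob": s})
        for t, n in zip(c.risk_times, c.n_at_risk):
            nar_rows.append({"endpoint": endpoint, "arm": arm,
                             "time": t, "n_at_risk": int(n)})
        if c.total_events is not None:
            ev_rows.append({"endpoint": endpoint, "arm": arm,
                            "total_events": int(c.total_events)})

    def dump(name, frame):
        f = out / f"{name}.csv"
        frame.to_csv(f, index=False)
        written.append(f)

    dump("surv_probs", pd.DataFrame(sp_rows))
    dump("n_at_risk", pd.DataFrame(nar_rows))
    if ev_rows:
        dump("events", pd.DataFrame(ev_rows))
    dump("hr", pd.DataFrame([{"endpoint": "OS", "value": inputs.hr_os},
                             {"endpoint": "PFS", "value": inputs.hr_pfs}]))
    dump("discount", pd.DataFrame([{
        "annual_rate": inputs.annual_discount_rate,
        "horizon_months": inputs.horizon_months,
        "dist_pfs": inputs.dist_pfs, "dist_os": inputs.dist_os,
    }]))
    dump("utilities", pd.DataFrame([inputs.utilities]))

    cost_rows = {}
    for item in inputs.resources:
        rng = inputs.dsa_ranges.get(f"cost:{item.name}")
        cost_rows[item.name] = {
            "name": item.name, "unit_cost": item.unit_cost,
            "dsa_low": rng[0] if rng else "",
            "dsa_high": rng[1] if rng else "",
        }
    dump("costs", pd.DataFrame(list(cost_rows.values())))

    pfs_rows, pps_rows = [], []
    for item in inputs.resources:
        if item.state == "PFS":
            for ph in item.schedule.phases:
                pfs_rows.append({
                    "name": item.name, "arm": item.arm,
                    "quantity": ph.quantity, "unit": ph.unit,
                    "phase_start": ph.start,
                    "phase_end": "" if math.isinf(ph.end) else ph.end,
                    "phase_unit": ph.phase_unit,
                    "txcycle_length_weeks": ph.txcycle_length_weeks or "",
                    "cap": item.schedule.cap_txcycles
                    if item.schedule.cap_txcycles is not None else "",
                })
        else:
            ph = item.schedule.phases[0]
            pps_rows.append({"name": item.name, "arm": item.arm,
                             "quantity": ph.quantity, "unit": ph.unit})
    dump("resources_pfs", pd.DataFrame(
        pfs_rows, columns=["name", "arm", "quantity", "unit", "phase_start",
                           "phase_end", "phase_unit", "txcycle_length_weeks",
                           "cap"]))
    dump("resources_pps", pd.DataFrame(
        pps_rows, columns=["name", "arm", "quantity", "unit"]))

    dsa_rows = [{"parameter": k, "low": v[0], "high": v[1]}
                for k, v in inputs.dsa_ranges.items()
                if not k.startswith("cost:")]
    dump("dsa", pd.DataFrame(dsa_rows, columns=["parameter", "low", "high"]))
    return written


def write_results(results, trace, dsa, out_dir, tornado=None) -> list[Path]:
    """Write results.csv, trace.csv and dsa.csv (plus tornado.csv when an
    ordering is supplied).

    * results.csv: metric, control, intervention, incremental - metrics are
      cost/ly/qaly each undiscounted and discounted, then the ICER rows
      (an undefined ICER renders as the string "undefined").
    * trace.csv: arm, cycle, pfs, pps, dead, cost, cost_disc, qaly, qaly_disc.
    * dsa.csv: parameter, low, high, icer_low, icer_high, status_low,
      status_high, inc_cost/inc_qaly per side; failed scenarios carry the
      status "engine-failure" and empty ICER cells.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    f = out / "results.csv"
    results.to_frame().to_csv(f, index=False)
    written.append(f)
    f = out / "trace.csv"
    trace.to_frame().to_csv(f, index=False)
    written.append(f)
    if dsa is not None:
        f = out / "dsa.csv"
        dsa.to_frame().to_csv(f, index=False)
        written.append(f)
        if tornado is not None:
            f = out / "tornado.csv"
            tornado.to_csv(f, index=False)
            written.append(f)
    return written
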