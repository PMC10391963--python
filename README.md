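# psmforge

Three-state partitioned survival cost-effectiveness models built from
digitized Kaplan–Meier curves, end to end:

1. **KM → IPD** (`psmforge.km_reconstruct`) — reconstruct approximate
   individual patient data from monthly survival coordinates, a
   numbers-at-risk table and (optionally) total event counts.
2. **Parametric fitting** (`psmforge.surv_models`) — maximum-likelihood
   fits of eight families (exponential, gamma, log-logistic, Weibull,
   log-normal, Gompertz, generalized gamma, generalized F) with an AIC
   menu, deterministic multi-start optimization.
3. **Hazard ratios** (`psmforge.hazard_tools`) — Cox partial-likelihood HR
   (Efron ties) with Wald CI, a Grambsch–Therneau proportional-hazards
   test (KM time transform), and constant-HR extrapolation
   `S_int = S_ctrl ** hr` via the cumulative-hazard contract.
4. **Resource costing** (`psmforge.resource_costing`) — a schedule grammar
   (rates per day/week/month, every-K-weeks administrations, listed days,
   treatment-cycle windows and caps) converted exactly into per-model-cycle
   unit consumption; 1 cycle = 1 month = 365.25/12 days.
5. **Engine** (`psmforge.psm_engine`) — state occupancy
   (PFS, OS−PFS, 1−OS) at monthly boundaries, trapezoid half-cycle
   correction, midpoint discounting, (Q)ALY/cost totals, increments and
   ICER with explicit sentinels. If OS falls below PFS at any boundary the
   engine **halts** with a `logical-inconsistency` error — it never clamps.
6. **DSA** (`psmforge.dsa`) — one-at-a-time sweeps over hazard ratios,
   discount rate, unit costs and utilities, with engine failures recorded
   per scenario and a tornado ordering.
7. **Template I/O** (`psmforge.io_template`) — CSV-directory or XLSX
   workbook templates (sheet schemas documented in the module docstring;
   a complete example lives in `examples/template/`), result/trace/DSA
   CSV writers.
8. **Fixtures** (`psmforge.fixtures`) — seeded synthetic trial generator
   (coupled PFS ≤ OS), curve digitizer and template writer, so the whole
   pipeline is testable offline.

Setting all three utility weights to 1 switches the model from QALYs to
life years.

## CLI

```bash
# full analysis
psmforge run --template examples/template --dist-pfs weibull \
    --dist-os weibull --horizon 60 --hr-source template \
    --out results/ [--plots]

# AIC menu only
psmforge fit --template examples/template

# sensitivity analysis only
psmforge dsa --template examples/template --out results/
```

`--hr-source estimate` forces Cox estimation of both hazard ratios from
the reconstructed IPD; otherwise template values are used (the sentinel
value `estimate` in the `hr` sheet requests estimation per endpoint).

## Output files

* `results.csv` — columns `metric, control, intervention, incremental`;
  rows `cost, cost_disc, ly, ly_disc, qaly, qaly_disc`, then the
  discounted and undiscounted ICER (the string `undefined` when the
  incremental effect is zero) and the ICER flag.
* `trace.csv` — `arm, cycle, pfs, pps, dead, cost, cost_disc, qaly,
  qaly_disc` (per-cycle, half-cycle corrected).
* `dsa.csv` / `tornado.csv` — per-parameter low/high ICERs with per-side
  status (`ok`, `engine-failure`, `icer-undefined`).
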