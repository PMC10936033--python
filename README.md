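# twamap

Reusable pipeline linking intraoperative hypotension during cardiopulmonary
bypass (CPB) to cardiac surgery-associated acute kidney injury (AKI) and
postoperative CRRT, built around four components:

- **Exposure metrics** (`twamap.exposure`) — area between a MAP threshold
  (default 65 mmHg) and the piecewise-linear MAP curve where MAP sits below
  it, via the composite trapezoidal rule with threshold-crossing
  interpolation (exact for the interpolated curve; a clipped-at-samples
  variant is available), plus the time-weighted average (AUC / window
  duration) and a sampling-resolution check.
- **KDIGO adjudication** (`twamap.kdigo`) — creatinine-criteria AKI staging
  (≥ 0.3 mg/dL rise within a rolling 48-h window, ≥ 1.5× baseline within
  7 days; stages 1–3 incl. SCr ≥ 4.0 with an acute rise and RRT), and the
  postoperative CRRT secondary outcome.
- **Cohort assembly** (`twamap.io`, `twamap.cohort`) — readers for
  INSPIRE-style relational CSV tables (long-format vitals/labs, wide-format
  operations/patients, two CPB-event dialects), eligibility rules (valid CPB
  window, ≤ 5-min MAP resolution, one operation per patient), covariate
  assembly (norepinephrine-equivalent vasopressor dose, CKD-EPI eGFR
  strata), attrition and QC accounting.
- **Association analysis** (`twamap.analysis`) — rank-sum comparisons, crude
  and multivariable logistic models (ORs with 95% Wald CIs), delta-method
  predicted-probability curves, a 75-mmHg threshold sensitivity analysis and
  hypertension subgroup fits, with figures.

A synthetic-data module (`twamap.simulate`) generates full relational
cohorts with known ground truth (exact logistic outcome models, MAP
trajectories bisection-matched to a drawn exposure, creatinine trajectories
that adjudicate to their assigned stage), so every stage is testable without
any external data.

## CLI

```sh
# generate a synthetic relational cohort (4 CSV tables + ground-truth JSON)
twamap simulate --out data/ --seed 1 --n 2500

# eligibility -> exposures -> KDIGO outcomes -> analysis-ready cohort CSV
twamap build-cohort --data data/ --out cohort/

# descriptives, crude/adjusted ORs, sensitivity + subgroup fits, figures
twamap analyze --cohort cohort/cohort.csv --out results/ \
    --vitals data/vitals.csv --operations data/operations.csv
```

Every policy the source data do not determine (artifact filters, duplicate
handling, baseline-creatinine definition, vasopressor equivalence weights,
categorical reference levels, thresholds) is explicit configuration; pass
`--config config.yaml` to any subcommand (see `twamap.config` for the
schema and defaults).

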