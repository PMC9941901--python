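# portal-its

Propensity-score-matched, open-cohort, interrupted time-series (ITS)
evaluation of patient-portal registration effects on primary-care encounter
rates — implemented as a reusable, fully tested pipeline with a synthetic
EMR generator, so every stage can be exercised without any real patient
data.

## What it does

- **`portal_its.synthetic_emr`** — coefficient presets for the two-arm
  segmented linear model, the segmented outcome-mean function, a fast
  matched person-year panel simulator (Poisson counts), and a full EMR-style
  bundle generator (patients, dated encounters, prescriptions, provider
  messages) with covariate-driven portal registration and known ground
  truth.
- **`portal_its.cohort`** — eligibility rules: portal patients anchor on
  their registration date (≥ 1 year of adult observation on each side);
  never-registered patients enter the control pool once per eligible year
  2010–2018 with a July-1 index date (open cohort).
- **`portal_its.covariates`** — 12-month lookback encounter/medication
  counts (half-open window, index day included; schedule-class filter for
  distinct ATC codes), diagnosis flags at index, exact ages, and the
  baseline-table bands.
- **`portal_its.matching`** — logistic propensity model, caliper (0.2
  pooled-SD on the logit scale) and ±366-day index-date constraints,
  iterative unique-first greedy 1:1 allocation without replacement, and
  standardized-difference balance diagnostics with pooled PS quintiles.
- **`portal_its.its`** — person-year panel construction and the 8-term
  segmented OLS (level + slope change anchored at year 2 post-index, years
  0 and 1 excluded), with conventional and cluster-robust (by patient)
  standard errors, plus Monte-Carlo coefficient-recovery studies.
- **`portal_its.reporting`** — workload arithmetic (minutes/message ×
  messages/patient/year), 3-year running-average registration-cohort
  curves, observed-vs-fitted ITS overlays, and deterministic file
  rendering (all plotted numbers materialized as CSV first).
- **`portal_its.cli`** — orchestration with per-stage child seeds, a run
  manifest, and console commands.

## CLI

```bash
# full synthetic run: generate -> cohort -> covariates -> match -> ITS -> report
portal-its run --config run.yaml

# individual stages
portal-its simulate --config synth.yaml --out bundle/
portal-its match --covariates out/covariates.csv --out matches.csv --caliper 0.2
portal-its fit --panel out/panel.csv --channel md --out fit.json
portal-its report --run-dir out/
```

Minimal `run.yaml`:

```yaml
mode: synthetic        # or "files" with input_dir pointing at the 4 CSVs
out_dir: out
seed: 42
synth:
  n_patients: 5000
```

Identical config + seed reproduces byte-identical numeric outputs; the run
manifest records the config hash, per-stage row counts and wall time.

## Data formats

All tables are plain CSV with ISO-8601 dates:
`patients.csv` (demographics, observation window, portal date, diagnosis
onsets), `encounters.csv` (patient_id, date, channel ∈ {MD, NPPA, TC}),
`prescriptions.csv` (patient_id, date, atc_code, schedule_class),
`messages.csv` (provider_id, patient_id, sent_date, minutes).
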