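# casecohort

Cox-model inference for stratified (and unstratified) case-cohort designs:

- weighted partial-likelihood estimation of log-relative hazards, Breslow
  cumulative baseline hazard, and covariate-specific pure risk on a
  half-open interval;
- per-subject empirical influences (Taylor deviates) for every estimand;
- design-based two-phase variance estimation using joint inclusion weights
  and covariances for stratified without-replacement (or Bernoulli)
  subcohort sampling, alongside the classical "robust" sum of squared
  deviates and their difference diagnostic;
- survey-weight calibration (raking) against auxiliary variables built from
  imputed phase-two covariates, with calibrated influence functions whose
  weighted phase-two parts are residuals orthogonal to the auxiliaries;
- missing phase-two covariates treated as a third sampling phase with
  estimated (or known) per-stratum missingness weights and a four-block
  variance that accounts for weight-estimation variability;
- a synthetic-cohort generator and study runner that reproduces the
  design-comparison experiment (stratified/unstratified, design/calibrated
  weights, full cohort) with coverage and variance-ratio metrics.

## CLI

```sh
# design-weight analysis: estimates, variances (two-phase + robust), CIs
casecohort fit --data cohort.csv --config config.yaml --out report.json

# calibrated weights / three-phase missing data
casecohort fit --data cohort.csv --config config.yaml --weights calibrated --out report.json
casecohort fit --data cohort.csv --config config.yaml --phase3 estimated --out report.json

# simulation study
casecohort simulate --config scenario.yaml --methods SCC,SCC.Calib --reps 500 --out table.tsv

# identity/oracle battery on user data
casecohort check --data cohort.csv --config config.yaml
```

The config file is YAML:

```yaml
columns:
  subject_id: id
  stratum: stratum
  entry_time: entry
  exit_time: exit
  event: event
  xi: xi
  v: v                      # optional phase-three indicator
  covariates: [x1, x2, x3]
  proxies: [xt1, xt3, w1, w2, w3]
design:
  m: {"0": 27, "1": 34, "2": 111, "3": 33}   # subcohort draws per stratum
  mode: without_replacement                  # or bernoulli
risk:
  tau1: 0.0
  tau2: 8.0
  profiles: [[-1, 1, -0.6], [1, -1, 0.6]]
calibration:
  impute:                    # phase-two covariate -> phase-one predictors
    x1: [xt1, w1, w2, w3]
    x3: [xt1, xt3]
```

## Package layout

| module | contents |
| --- | --- |
| `casecohort.data_model` | `CohortFrame`, `DesignWeights`, `RiskRequest`, delimited-text I/O, design weights |
| `casecohort.cox_engine` | weighted score solver, risk-set sums, Breslow jumps, pure risk |
| `casecohort.influence` | per-subject influences for beta, hazard increments, cumulative hazard, (log) pure risk |
| `casecohort.variance` | pair rule (joint weights/covariances), two-phase + robust variances, CIs |
| `casecohort.calibration` | imputation, auxiliary construction, raking, calibrated estimation/influences/variance |
| `casecohort.phase3` | estimated missingness weights, three-phase estimation/influences/variance |
| `casecohort.simulate` | scenario generator, subcohort allocation and sampling, study runner |
| `casecohort.cli` | `fit`, `simulate`, `check` subcommands |
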