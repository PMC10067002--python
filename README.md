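# healthvep

A tested, reusable pipeline for analysing health-poverty vulnerability in
survey microdata:

* **`healthvep.synthetic`** — a survey-microdata generator with known ground
  truth (heteroskedastic log-welfare, log-log income–expenditure link,
  deprivation indicators tied to welfare, a logistic binary vulnerability
  outcome with interaction effects), so every downstream estimator is
  testable without any restricted-access data.
* **`healthvep.af_index`** — Alkire-Foster multidimensional scoring with
  built-in 7-indicator physical-health and 10-indicator mental-health systems
  (equal weights, predisposing/enabling/need dimensions, cutoff `k = 30%`,
  boundary inclusive).
* **`healthvep.vep`** — vulnerability as expected poverty via three-stage
  feasible GLS (OLS mean equation → FGLS variance equation → WLS mean
  equation), per-row `Phi((ln z - X·alpha) / sqrt(X·beta))`, binarised at a
  configurable cutoff.
* **`healthvep.elasticity`** — income elasticity of health-care demand from
  log-log OLS, stratified by urban/rural × income quintile, truncated below
  at zero, assigned per row.
* **`healthvep.logit`** — two-layer logistic regression (baseline and
  elasticity-interaction designs) with province-dummy fixed effects, average
  marginal effects (derivative for continuous, discrete-change for binary
  regressors, delta-method SEs), joint Wald tests, and urban/rural plus
  east/central/west subgroup harnesses.
* **`healthvep.inequality`** — coefficient-of-variation and Theil T indices
  with urban-minus-rural gaps per region and province.
* **`healthvep.pipeline`** — end-to-end orchestration writing per-stage CSV
  artifacts and a `manifest.json` whose row-count ledger makes the exclusion
  cascade auditable.

## CLI

```sh
healthvep simulate --seed 1 --n 8831 --out pop.csv
healthvep af-score --input pop.csv --index both --gamma 0.30 --out scores.csv
healthvep vep --input pop.csv --welfare af-score --cutoff 0.5 --out vep.csv
healthvep elasticity --input pop.csv --strategy stratified --out eh.csv
healthvep fit --input eh.csv --design all --out-dir results/
healthvep inequality --input pop.csv --value income --out ineq.csv
healthvep run-pipeline --seed 1 --out-dir results/
```

`run-pipeline` executes simulate/ingest → af-score → vep → elasticity → fit →
inequality and writes every stage artifact plus `manifest.json`.
Configuration is a flat YAML file (see `healthvep.config.PipelineConfig`);
every generator ground-truth parameter lives in
`healthvep.config.PopulationConfig`.

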