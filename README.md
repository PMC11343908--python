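# pafkit

Estimation and display of population attributable fractions (PAF) and impact
fractions in Python:

* **Discrete risk factors** under cross-sectional, case-control, cohort and
  survey designs — weighted standardisation (g-formula) and the case-only
  Bruzzi formula, plus survival `PAF(t)` from proportional-hazards models.
* **Impact fractions** for arbitrary interventions described by a
  counterfactual copy of the data.
* **Summary-data PAF** — Levin and Miettinen formulas with seeded Monte-Carlo
  propagation of interval imprecision, approximate PAF, fan plots and
  attributable-fraction nomograms.
* **Continuous exposures** — `PAF_q`: the impact fraction of projecting
  everyone outside the lowest-risk 100q% of exposure values onto that region,
  with risk-curve and region plots.
* **Pathway-specific PAF** — disease burden attributable to a single
  risk factor → mediator → outcome pathway (continuous and discrete
  mediators), plus the direct pathway.
* **Joint / sequential / average PAF** on a user-declared causal DAG via
  recursive do-operator simulation: per-node model fitting
  (`automatic_fit`), counterfactual data simulation, exact subset-lattice and
  permutation-sampled average PAF with stratified sampling and a margin-of-
  error report.
* **Bootstrap confidence intervals** (norm / basic / perc / BCa), with
  matched-set resampling for paired case-control data.
* A **synthetic-data module** that simulates populations from configurable
  causal Bayesian networks, samples matched case-control designs, and
  computes ground-truth PAFs by paired counterfactual Monte-Carlo — used as
  the oracle throughout the test suite.

## Quick start

```python
import pafkit

table = pafkit.read_table("data/stroke_reduced.csv",
                          sidecar="data/stroke_reduced.roles.yaml")

model = pafkit.fit_model(
    table,
    "case ~ age + education + exercise + ns(diet, df=3) + smoking + alcohol"
    " + stress + ns(lipids, df=3) + ns(waist_hip_ratio, df=3)"
    " + high_blood_pressure",
    "conditional_logit",
)
pafkit.paf_bruzzi(model, table, "exercise")      # case-only formula
pafkit.paf_direct(model, table, "exercise", prevalence=0.0035)
```

Formulas use patsy syntax plus a natural-spline term `ns(x, df=k)`.
Model families: `binomial_logit`, `binomial_log`, `linear`, `ordinal_logit`,
`conditional_logit` (needs declared matched strata), `prop_hazards` (needs
declared time/event columns).

DAG-based estimation:

```python
dag = pafkit.CausalDAG.from_yaml("dag.yaml")   # nodes / parents / risk_nodes / outcome
models = pafkit.automatic_fit(table, dag, prevalence=0.0035,
                              spline_nodes=("diet",),
                              common_terms="region * ns(age, df=5)")
pafkit.joint_paf(table, dag, models, ["smoking", "high_blood_pressure"],
                 prevalence=0.0035, seed=1)
pafkit.average_paf(table, dag, models,
                   ["smoking", "high_blood_pressure", "diabetes"],
                   exact=True, prevalence=0.0035, seed=1)
```

## CLI

Every estimator is exposed through a single entry point:

```bash
paf discrete   --input data.csv --outcome case --model-formula "case ~ a + c" \
               --riskfactor a --refval 0 --method B --ci --boot-rep 200
paf summary    --formula miettinen --conf-prev 0.843,0.855 \
               --conf-rr 1.427,1.806 --conf-rru 1.514,1.833
paf continuous --input data.csv --outcome case --model-formula "case ~ ns(x, df=3)" \
               --riskfactors x --q 0.01,0.1,0.3
paf ps         --input data.csv --outcome case --model-formula "case ~ a + m + c" \
               --mediator-formulas "m ~ a + c" --riskfactor a --prev 0.0035
paf joint|seq|average --input data.csv --outcome case --dag dag.yaml \
               --riskfactors a,b --prev 0.0035 --seed 1
paf simulate   --preset stroke --n 10000 --out synthetic.csv
paf fanplot    --input rf_summary.csv --fig fan.svg
```

Column roles are declared with flags (`--outcome`, `--weights-col`,
`--strata-col`, `--time-col`, `--event-col`, `--categorical`) or with a
YAML sidecar (see `data/stroke_reduced.roles.yaml`).

## Data

`data/stroke_reduced.csv` and `data/Hordaland_data.csv` are the simulated
matched case-control stroke dataset (13,712 rows; binary, ordinal and
continuous risk factors; weights; matched strata; a survival sub-cohort) and
the simulated chronic-cough case-control dataset used in the examples and in
the replication tests, exported to plain CSV.

## Tests and acceptance report

```bash
python -m pytest -q                   # full suite, incl. tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` refits every model from the raw CSV and recomputes
the headline results (joint/average/sequential PAF on the declared DAG,
survival PAF at 1 and 9 years, the inactivity impact fraction, the waist-hip
ratio pathway PAF, and the q=0.3 exposure projection for lipids), writing
them to a JSON report.
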