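# greencomp

Parametric g-computation for simulated interventions on residential
greenspace (NDVI) and metabolic health.

## What problem this addresses

Observational cohorts can measure how green a participant's neighborhood
is (NDVI — normalized difference vegetation index, a satellite-derived
greenness score in [-1, 1]) alongside metabolic biomarkers: fasting
glucose, total/LDL/HDL cholesterol, triglycerides, hemoglobin A1c, blood
pressure, waist circumference, and metabolic syndrome (≥ 3 of 5 clinical
criteria). The policy-relevant question is counterfactual: *what would the
population's biomarker distribution look like if everyone's greenspace
exposure were raised to a given level?* `greencomp` answers it with the
parametric g-formula (standardization),

    E[Y^a] = Σ_l E[Y | A = a, L = l] · Pr[L = l],

fitting one outcome regression per biomarker (Gaussian GLM for continuous
outcomes, logistic for metabolic syndrome, adjusted for sex, income, race,
ethnicity, age and education), predicting every participant's outcome with
exposure set to each intervention level, and averaging over the observed
confounder distribution. Interventions form a fixed grid: the sample
minimum NDVI as reference plus the nine deciles and the maximum. Risk
differences (RDs) against the reference get 95% percentile-bootstrap CIs
(1000 refits by default). The package also provides:

- **effect modification via partial interventions** — only one stratum
  (e.g. participants ≥ 65) receives the intervention exposure while
  everyone else keeps their observed NDVI, with exposure×modifier
  interaction models and per-level Cochran Q heterogeneity tests;
- **a super-learner sensitivity arm** — a 10-fold cross-validated stacking
  ensemble (main-terms GLM, random forest, elastic net, gradient boosted
  trees; NNLS meta-weights on the probability simplex) swapped in as the
  prediction engine to probe outcome-model misspecification;
- **a synthetic-cohort generator with known ground truth**, so every stage
  is testable without access to any real cohort: confounded exposure,
  linear outcome models with known slopes, optional interactions, MCAR
  missingness, and an exact `true_rd` oracle.

It is aimed at epidemiologists and biostatisticians who want a tested,
reproducible g-computation pipeline for continuous environmental exposures,
and at methods students who want a transparent reference implementation.

## Worked example

```python
from greencomp import (default_config, generate_cohort, complete_case_filter,
                       intervention_grid, bootstrap_rds, OutcomeModelSpec,
                       make_rd_table)

cfg = default_config(n_participants=602, seed=7)   # study-scale synthetic cohort
cohort = generate_cohort(cfg)
analysis, report = complete_case_filter(cohort)
print(f"retained {report.n_retained}/{report.n_input} ({report.retention_pct:.1f}%)")
grid = intervention_grid(analysis["ndvi"])
print(grid.describe())
ests = bootstrap_rds(analysis, OutcomeModelSpec("glucose"), grid,
                     n_boot=1000, seed=1)
print(make_rd_table(ests).to_string(index=False))
```

prints

```
retained 544/602 (90.4%)
reference -0.054; levels 0.045, 0.074, 0.095, 0.112, 0.126, 0.143, 0.163, 0.189, 0.222, 0.347
outcome    level               rd_95ci
glucose 0.044894   -1.23 (-4.89, 2.56)
glucose 0.073762   -1.59 (-6.32, 3.31)
...
glucose 0.222200  -3.44 (-13.65, 7.16)
glucose 0.346549 -4.99 (-19.79, 10.38)
```

Reading: raising every participant's NDVI from the sample minimum (-0.054)
to the sample maximum (0.347) is estimated to lower mean fasting glucose
by 4.99 mg/dl (95% CI -19.79 to 10.38) — a point estimate in the direction
of the generating model's true effect, with a CI reflecting n ≈ 550. RDs
grow monotonically along the grid because the outcome model is linear in
exposure.

The same analysis runs from the shell:

```bash
greencomp simulate --n 602 --seed 7 --out cohort.csv
greencomp run --cohort cohort.csv --out results/ --seed 1 --n-boot 1000
greencomp report --rd-table results/rd_glm.csv
```

`run` writes tidy CSVs (`rd_glm.csv`, `stratified_rds.csv`,
`heterogeneity.csv`), a complete-case report, and a JSON provenance
sidecar recording the seed, grid, and reference categories; the whole
bundle is byte-identical when re-run with the same seed.

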