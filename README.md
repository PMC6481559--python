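# cohortmi

Multiple imputation of missing covariates in **nested case-control (NCC)**
and **case-cohort (CC)** substudies of prospective cohorts analysed with Cox
proportional-hazards models.

Substudies measure expensive covariates only on the cases and a sampled
subset of non-cases, so those covariates are *missing by design* in the rest
of the cohort; routinely collected confounders are additionally *missing by
chance*. Dropping incomplete rows (complete-case analysis) wastes the design
and can bias the hazard-ratio estimates. `cohortmi` provides the modelling
stack to do better, for epidemiologists and biostatisticians running or
evaluating such substudies:

- a synthetic-cohort simulator (correlated covariates, Weibull hazard
  `h(t | x) = t λ e^{β'x}`, administrative censoring, calibrated
  missing-at-random masking, and a deliberately misspecified variant);
- Cox fitting by the full partial likelihood and by the modified (substudy)
  partial likelihood over sampled risk sets, with model-based or robust
  sandwich variances, plus Nelson–Aalen and Breslow estimators;
- NCC and CC design sampling, and design-adapted cumulative-hazard
  estimators (the weighted CC estimator, Nelson–Aalen on the CC sample, the
  modified Breslow baseline, the sampled-risk-set baseline, Samuelsen
  inclusion probabilities for IPW);
- three imputation methods: the **approximate** method (regress the missing
  covariate on the other covariates, the event indicator `D` and `Ĥ(T)`),
  the **substantive-model-compatible (SMC)** method (rejection sampling
  against the Cox model's own density, so transformations of imputed
  covariates in the hazard are handled correctly), and the **matched-set**
  method for NCC studies that needs nothing beyond the sampled sets;
- Rubin's-rules pooling and a simulation-study harness reporting bias,
  empirical and model SEs, coverage, and efficiency relative to the
  complete-data substudy analysis.

Each method runs under the *full-cohort* approach (impute and analyse the
cohort), the *intermediate* approach (impute the cohort, analyse the
substudy), or the *substudy* approach (impute and analyse the substudy
only), matching what information an analyst actually has.

## Worked example

Compare the complete-data substudy analysis, the complete-case analysis and
intermediate-approach approximate imputation on simulated case-cohort
studies (true log hazard ratios all 0.2, 50% of `x2` missing at random,
`x1` missing by design outside the subcohort):

```python
from cohortmi import StudyConfig, run_study, standard_scenario

scenario = standard_scenario(effect=0.2, missing_frac=0.5, n_cohort=4000, seed=0)
config = StudyConfig(design="cc", n_subcohort=400, M=10)
result = run_study(
    scenario,
    ["complete_data_substudy", "complete_case_substudy", "mi_approx_intermediate"],
    n_reps=50,
    base_seed=2024,
    config=config,
)
cols = ["method", "coef", "mean_est", "bias", "emp_se", "coverage_pct", "rel_eff"]
print(result.summary[cols].round(3).to_string(index=False))
```

```
                method coef  mean_est   bias  emp_se  coverage_pct  rel_eff
complete_data_substudy   x1     0.200  0.000   0.076          98.0    1.000
complete_data_substudy   x2     0.215  0.015   0.160          96.0    1.000
complete_data_substudy    z     0.174 -0.026   0.172          96.0    1.000
complete_case_substudy   x1     0.219  0.019   0.132          96.0    0.326
complete_case_substudy   x2     0.184 -0.016   0.265          94.0    0.365
complete_case_substudy    z    -0.041 -0.241   0.261          84.0    0.434
mi_approx_intermediate   x1     0.210  0.010   0.079         100.0    0.916
mi_approx_intermediate   x2     0.160 -0.040   0.209          98.0    0.586
mi_approx_intermediate    z     0.185 -0.015   0.178          94.0    0.931
```

The complete-case analysis is biased for the `z` coefficient (mean −0.04
against a truth of 0.2, 84% coverage) because missingness in `x2` depends on
`z` and the outcome, and it discards two thirds of the efficiency
(`rel_eff` ≈ 0.3–0.4). Imputation removes the bias and restores most of the
efficiency (`rel_eff` ≈ 0.9 for `x1` and `z`).

## Command line

```bash
cohortmi simulate   --scenario scen.yaml --out cohort.csv
cohortmi sample-ncc --cohort cohort.csv --c 2 --seed 3 --out ncc_sets.csv
cohortmi sample-cc  --cohort cohort.csv --subcohort-size 750 --seed 3 --out cc_sets.csv
cohortmi impute     --cohort cohort.csv --m 10 --seed 5 --out-prefix imp
cohortmi study      --scenario scen.yaml --design cc \
    --methods complete_data_full,mi_approx_intermediate --reps 100 --seed 2 --out results/
```

Scenario files are flat YAML (`seed` is mandatory); see
`examples/small_effect.yaml`.

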