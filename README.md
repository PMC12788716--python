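# pa-optim

Individually optimal physical-activity (PA) patterns for adults with high
blood pressure, via counterfactual survival prediction.

## The problem

Accelerometer studies classify adults into four weekly activity patterns:

| pattern | rule |
|---|---|
| active weekend warrior (WW) | ≥150 min/week MVPA with ≥50% in the two highest days |
| active regular | ≥150 min/week MVPA, spread more evenly |
| active LPA | <150 min/week MVPA but ≥1900 min/week light PA |
| baseline PA | below both thresholds |

Average hazard ratios say that the active patterns beat baseline, but the
*best* pattern for a given person plausibly depends on age, sex, and
comorbidity (a stroke survivor should not be told to chase 150 MVPA
minutes). `pa-optim` implements the full analysis pipeline that makes that
idea testable:

1. **Exposure processing** — per-minute device output (waist counts/min or
   wrist milligravity) → wear-validity checks → weekly MVPA/LPA totals and
   top-2-day share → the four pattern labels; plus the restricted-cubic-
   spline Cox dose–response of light activity that motivates the
   1900 min/week threshold.
2. **Cohort building** — high-BP classification (elevated BP vs
   hypertension), ordered inclusion/exclusion with a conserved ledger, and
   ICC / Cohen κ covariate-reliability statistics.
3. **The S-learner base model** — an 80/20 split; LASSO-penalized Cox
   covariate selection (10-fold CV, pattern dummies forced); a multivariable
   Cox model with all second-order pattern×covariate interactions; AIC/Wald
   backward elimination; Breslow baseline hazard; IPCW Brier score and
   cumulative/dynamic AUC.
4. **Counterfactual profiling** — each person's predicted survival
   S(t | x, pattern) under all four patterns; the recommended pattern is the
   argmax (ties broken toward less MVPA); people whose observed pattern
   differs are *inconsistent*, subdivided by whether the optimum demands
   more MVPA or is LPA-primary.
5. **Heterogeneity tree** — a conditional inference tree (permutation-
   framework association tests, Bonferroni-adjusted) relating covariates to
   the predicted optimum.
6. **Association analysis** — adjusted Cox hazard ratios for the
   inconsistency contrasts, a nonbaseline subgroup analysis, and a
   sensitivity harness (alternate cohort, cause-specific mortality,
   truncated follow-up, internal test split).

Real cohorts of this kind are access-restricted, so the package ships a
first-class synthetic-cohort generator with a known Weibull
proportional-hazards truth — every downstream stage is testable against the
generating model, including a "deviation world" in which not following
one's optimal pattern multiplies the hazard by a configurable factor.

## Worked example

```python
from pa_optim import (
    TruthConfig, generate_cohort, run_pipeline,
)

cohort, truth = generate_cohort(TruthConfig(n=20_000, seed=1))
result = run_pipeline(
    cohort,
    covariates=list(TruthConfig().covariate_spec),
    seed=1,
    use_lasso=True,
    evaluate=True,
    interactions=["stroke", "diabetes", "sex_male", "age"],
)
lab = result.labelled
print(lab["optimal"].value_counts(normalize=True).round(3).to_dict())
print("agreement with truth:",
      (lab["optimal"].to_numpy() == truth.optimal.to_numpy()).mean())
for r in result.associations:
    print(f"{r.contrast}: HR {r.hr:.2f} ({r.ci_lower:.2f}-{r.ci_upper:.2f})")
```

prints (seed 1):

```
{'active_lpa': 0.427, 'active_ww': 0.295, 'active_regular': 0.256, 'baseline': 0.022}
agreement with truth: 0.96135
inconsistent vs consistent: HR 1.44 (1.32-1.56)
inconsistent_mvpa vs consistent: HR 1.48 (1.35-1.62)
inconsistent_lpa vs consistent: HR 1.36 (1.21-1.53)
```

Read: in this synthetic high-BP cohort the model recommends light activity
for 43% of participants (predominantly women and diabetics), regular MVPA
for 26% (younger men), weekend-warrior for 30% (older participants) and
baseline for the 2% with stroke history; following a pattern other than
one's predicted optimum is associated with a 44% higher all-cause mortality
hazard, with the larger penalty in the stratum whose optimum demands MVPA —
the same qualitative structure reported for real cohorts.

The CLI mirrors the library (`pa-optim simulate`, `classify-activity`,
`build-cohort`, `fit`, `evaluate`, `recommend`, `tree`, `associate`);
`pa-optim recommend --model model.json --input person.csv` prints the four
predicted survival probabilities and the recommended pattern for one
person — a shell twin of an interactive recommender.

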