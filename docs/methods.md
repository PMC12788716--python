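# Methods

This note documents the models, the synthetic data-generating processes,
the numerical choices and the known limitations of `pa-optim`.

## The base learner

The single base learner of the S-learner is a Cox proportional-hazards
model whose design matrix contains

* three PA-pattern dummies (baseline PA is the reference),
* the selected covariate main effects, continuous covariates centred at
  their training means, binary covariates entered raw,
* a full second-order interaction block (3 columns) between the pattern
  dummies and each covariate granted interactions.

Estimation is by partial likelihood with the Efron tie correction
(lifelines). The baseline cumulative hazard H0(t) is the Breslow step
estimator evaluated at the design origin, recomputed in-package so that
predicted survival is exactly S(t|x,p) = exp(−H0(t)·exp(lp(x,p))) with
S(0) = 1 and S monotone non-increasing in t. Predictions outside the
training covariate support are allowed (the recommender accepts arbitrary
inputs); no extrapolation guard beyond the step function's last jump is
applied.

**Covariate selection.** A LASSO-penalized Cox path
(scikit-survival's coxnet) with penalty factor 0 on the pattern dummies —
they are forced so the model can always predict under all four patterns —
and 1 elsewhere; candidates are standardized internally. The shrinkage
parameter minimizes the 10-fold cross-validated partial-likelihood
deviance, computed glmnet-style as
D(λ) = −2 Σ_folds [pl_full(β̂^(−f)) − pl_train(β̂^(−f))] with a
Breslow-form partial likelihood. The deviance-minimizing rule (rather than
a 1-SE rule) is the package default.

**Backward elimination.** Removable units are (a) a covariate's whole
interaction block and (b) a main effect once its block is gone; pattern
dummies are never removed, so hierarchy is preserved by construction. The
default criterion is AIC (remove the unit whose removal lowers AIC most,
stop at a local minimum); a Wald rule (drop the least significant unit
while its block p-value exceeds 0.05, diagonal-covariance approximation) is
available where the O(units²) AIC refits are too expensive. The
elimination trace is stored in the model metadata.

**Evaluation.** The IPCW Brier score and the cumulative/dynamic (Uno) AUC
at a horizon t are computed through scikit-survival, with the censoring
distribution estimated by Kaplan–Meier on the evaluation sample; event
terms are weighted by G(T−), survivor terms by G(t). Percentile bootstrap
CIs (default 200 seeded resamples) re-estimate the censoring distribution
per resample. Calibration uses deciles of predicted risk with
Kaplan–Meier observed risk per bin.

## Counterfactual profiling and consistency labels

The fitted model is evaluated four times per person, varying only the
pattern input; the recommended pattern is the survival argmax at the
decision horizon (default 10 years; the profile can be computed at any
horizon, and the CLI reports 5 and 10). Exact ties break toward the
pattern demanding less MVPA (baseline < active LPA < active regular <
active WW) — the conservative recommendation. The margin (best minus
second-best survival) is retained so users can flag clinically negligible
differences; no margin threshold is imposed.

A person is *consistent* when the observed pattern equals the predicted
optimum. The three-level label follows the predicted optimum:
inconsistent-MVPA when it is regular/WW, inconsistent-LPA when it is
active-LPA — and, by package convention, also when it is baseline, the
cell a two-way MVPA/LPA split leaves ambiguous (a small group in
practice).

## The conditional inference tree

Node-level association tests use the permutation framework: the linear
statistic T = Σ g(x_i)h(y_i)ᵀ (g identity for ordered covariates,
indicator coding for categorical; h the 4-class indicators) standardized by
its conditional mean and covariance under permutations, with the quadratic
form referred to χ² on the rank of the covariance (Moore–Penrose inverse).
A seeded Monte-Carlo permutation p-value is available for small nodes.
P-values are compared on the log scale (with an asymptotic upper-tail
expansion where `chi2.logsf` underflows), so far-significant predictors
remain distinguishable instead of collapsing into a p = 0 tie.

Growth: at each node all non-constant predictors are tested, Bonferroni
adjustment multiplies the best p by the number tested, and the node
becomes a leaf when the adjusted p exceeds α (default 0.05), fewer than
`min_node` (200) samples remain, or `max_depth` (5) is reached. The split
point maximizes the standardized two-sample statistic over observed
thresholds, subject to a minimum child size of 50; ties in adjusted
p-values resolve by predictor order. The outcome is treated as an
unordered multinomial.

Under the null, the Bonferroni adjustment makes the familywise root error
at most α; the acceptance suite verifies the node test's 5% level to
within Monte-Carlo error and root-leaf conservatism across replicates.

## Association analysis

Hazard ratios for the binary and three-level inconsistency contrasts come
from multivariable Cox models adjusted for the LASSO-selected covariates.
The observed PA pattern itself is *excluded* from the adjustment set: the
label is a deterministic function of pattern and covariates, and adjusting
for the pattern would absorb the contrast of interest. Adjustment columns
that are exactly linearly dependent on the exposure columns (possible
inside subgroups, where a label can coincide with a covariate) are dropped
with a warning rather than letting the partial likelihood go singular.
Cause-specific mortality is handled as cause-specific hazards (competing
causes censored at their event time). Presentation order of result rows is
by hazard ratio. Significance is two-sided at 0.05; no multiplicity
adjustment is applied across the result table.

## Synthetic data

`TruthConfig` defines a Weibull proportional-hazards world:
S(t|x,p) = exp(−(t/λ)^k · exp(lp)) with k = 1.2, λ = 80 years, an
administrative horizon of 15 years and Uniform(0, 40) dropout — sized once
to give a ~15% event fraction at the default covariate effects. Event
times are drawn by inverse transform, so the world is exactly PH and the
downstream Cox model is correctly specified when given the right terms.
The default covariate set mirrors the 14-variable input space of the
prediction model (pattern, age, sex, sedentary time, smoking,
antihypertensive medication, cancer, diabetes, MI, stroke, BP class, waist
circumference, glucose, HbA1c) with qualitatively realistic marginals
(e.g. age N(62, 8), hypertension 55%, stroke 2%). Observed patterns come
from a multinomial logit on z-scored covariates whose intercepts
approximate observed pattern shares in real high-BP accelerometer cohorts
(~18/18/21/44%), with a tunable confounding strength.

The default interaction structure encodes the heterogeneity the method is
meant to detect: stroke makes every active pattern harmful (true optimum
baseline), diabetes pushes the optimum to light activity, female sex
favours light activity, and age moves the regular/weekend-warrior
boundary (−0.035/yr on the WW log-hazard). Three named variants serve
specific regimes:

* `no_interaction_config` — homogeneous truth; one shared optimum.
* `strong_heterogeneity_config` — every binary interaction ≥ 0.5 in
  |log-HR| and wide decision margins, the regime where a model fitted at
  n ≈ 20,000 recovers the individual optimum for ~95% of participants.
  In the *default* config the female light-vs-regular gap is only 0.15
  log-HR, so estimation noise can flip that whole stratum's argmax — a
  realistic feature, not a bug, and the reason recovery claims are made in
  the strong regime.
* `stroke_dominant_config` — stroke prevalence 0.15 and stroke the only
  strong driver, for studying whether the tree roots at the dominant
  covariate.

`DeviationConfig` defines the *deviation world*: one frail binary sets the
optimum (frail → baseline, else → active regular), observed patterns are
uniform at random, and deviating multiplies the hazard by a configured
penalty (default 1.30 in both strata). Because the optimum is driven by a
single binary, the interaction Cox model is exactly correctly specified
and the true hazard ratio of the inconsistency contrast equals the
penalty — the end-to-end estimand is known. For the three-level variant
(distinct penalties 1.40/1.15) the frail prevalence is raised to 0.40: the
low-penalty stratum's 0.14 log-HR margin needs the larger stratum for its
optimum to be identified reliably at n = 20,000.

Activity weeks are built constructively: MVPA minutes are placed on the
two weekend days in exactly the proportion requested (the top-2 share must
be achievable in whole minutes), light activity is spread round-robin, and
worn sedentary minutes carry a small nonzero count so waist-dialect
zero-run recoding does not fire. Wear-invalid weeks violate precisely one
protocol rule (71 h total for the 72-h rule; 590 worn min/day for the
10-h-day rule). The generator emulates epoch-level summaries only — no
raw waveforms, device noise, sleep, or nonwear imputation — so passing
tests certify the processing rules, not device physics.

## Numerical and convention choices

* Intensity thresholds are inclusive as printed: sedentary < 100 cpm,
  LPA [100, 2020), MVPA ≥ 2020 for the waist dialect; wrist cut-points
  must be user-supplied and are echoed in output metadata (no packaged
  wrist classifier is implied).
* Days are calendar days in device-local time; the top-2-day share uses
  calendar days, not a rolling 48-h window.
* Restricted cubic splines use Harrell's basis (k knots → k−1 columns),
  default 4 knots at the (0.05, 0.35, 0.65, 0.95) quantiles, reference at
  the cohort median (HR ≡ 1 there by construction).
* ICC is fixed to ICC(2,1) (two-way, single measure, absolute agreement);
  κ is unweighted. Perfect agreement returns exactly 1.
* Exclusion steps run in a fixed order (calibration → wear → BP →
  missingness), each participant counted once at its first failing step,
  so ledger counts plus survivors always equal the input count and the
  operation is idempotent.
* Duplicating every row changes Efron-tie estimates by ~1e-4 (it would be
  exact under Breslow); this is documented rather than "fixed".

## Problem sizes in the test suite

Acceptance-style checks run at the sizes the properties demand
(n = 20,000 cohorts, 50–200 replicates for coverage/type-I simulations);
unit tests use compact four-covariate worlds at n ≈ 800–6,000, and the
backward-elimination selection-consistency check runs at n = 6,000 —
stepwise AIC refits O(units²) Cox models, and the property is already
decisive at that size.

## Limitations

* The pipeline is associational; no causal identification is claimed, and
  the synthetic worlds are exactly PH with independent censoring —
  violations of either are not modelled.
* The S-learner shares one model across patterns; T-/X-learner variants
  and CIs on individual counterfactual differences are out of scope.
* Missing data are handled by exclusion (complete cases), matching the
  study design the pipeline emulates; no imputation or survey weighting.
* The wrist dialect ships without default cut-points on purpose: published
  wrist classifications come from trained classifiers the package does not
  reproduce.
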