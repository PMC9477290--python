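# Methods

## Model and state space

The simulator tracks, for each person: the current and previous TICS27
scores (the two- and four-year lags of the next transition), vital status,
an absorbing verified cognitive status, and a covariate vector. Time moves
in two-year waves.

The cognition transition is an ordered probit over the 28 score levels:
latent index y\* = x′β + ε with ε standard normal, S = j when
κⱼ₋₁ < y\* ≤ κⱼ (κ₋₁ = −∞, κ₂₇ = +∞). There is no free intercept — the 27
cutpoints absorb it. Mortality is a probit Φ(c + x′γ) with an explicit
intercept, since the published mortality coefficient table prints none and
the simulated death level needs calibrating.

Covariates follow the published specification: lagged scores, race and
education dummies (reference non-Hispanic white / high school), sex,
piecewise-linear age splines — basis (min(a,k₁), clamped mid-segments,
max(a−k_last,0)) with knots (65, 75) for cognition and (65, 75, 85) for
mortality — condition-ever flags, a two-year heart-attack flag, working,
widowhood, smoking, a verified-impairment-ever flag, `delta_age`, and a
lagged log-BMI spline with knot log 30. ADL/IADL category dummies, current
smoking and by-age-50 condition histories enter only the mortality model.

`delta_age` is defined as interview_gap_years − 2: the deviation of the
realized wave gap from the nominal two years. In a strictly biennial panel
any other reading is constant across rows and unidentifiable; the
synthetic generator jitters gaps by ±0.5 years so the coefficient is
estimable, which also mirrors real fieldwork timing.

## Verified status: two timing conventions

A category is *verified* by a second adjacent wave or by death (dementia:
dementia→{dementia, death}; MCI: MCI→{MCI, dementia, death} or
dementia→MCI at the MCI wave). Two conventions coexist:

* **Retrospective labelling** (`verify_trajectory`): the status is
  effective from the first wave of the confirming pair. This is the
  natural convention for describing an observed trajectory after the fact
  and is the one the exhaustive state-machine oracle tests.
* **Information-set labelling** (`verified_known_by_wave`, the
  `verified_status` panel column): the status counts only once the
  confirming observation exists. The forward simulation *must* use this
  convention — when drawing wave t, the pair (t−1, t) is not yet complete —
  and estimation uses it too, for congeniality with the generating
  process: labelling a person "verified at t−1" because of what happens at
  t would condition a regressor on the outcome being modelled. Transition
  matrices and observed outcomes use the same convention, with death
  confirming a still-provisional category.

Status at death is the verified status in the last wave before death,
death itself acting as confirming event. An MCI death counts as "dead
without dementia" in the 3×5 transition matrix, whose structural zeros
(MCI→normal; dementia→anything but dementia or dead-with-dementia) follow
from absorption and are enforced.

## Estimation

Both models are fitted by unweighted maximum likelihood (survey weights
enter only population-level summaries). Cutpoint monotonicity is enforced
by optimizing (κ₀, log Δκ); L-BFGS-B from a zero-coefficient start with
cutpoints at the empirical-CDF normal quantiles, followed by up to five
Newton polish steps in the natural parametrization. Convergence is flagged
when the per-observation score norm falls below 1e−5. Standard errors come
from the inverse observed information, computed by central finite
differences of the analytic score in the natural (β, κ) space. Score
levels absent from the training data are dropped from the category set
with a logged warning; the fitted model then cannot emit them. Probability
floors at 1e−300 keep the log-likelihood finite; rank deficiency and
complete separation raise errors naming the offending columns. A
two-category ordered probit reproduces the probit (κ₀ = −c) to 1e−6, and
estimates agree with statsmodels' OrderedModel/Probit to ~1e−4 on shared
problems — statsmodels serves only as a cross-check, never as the
implementation.

Sample entry conditions on being alive at baseline, so transitions into
the two entry waves are left-truncated and carry no mortality
information; mortality outcomes therefore begin at the first
post-baseline wave (including the entry transitions would dilute the
fitted death rate and propagate into every downstream mortality count).

Average marginal effects are sample means of analytic derivatives for
continuous covariates and of discrete 0→1 contrasts for binary ones — on
the death probability for the probit and on E[S|x] = Σⱼ j·P(j|x) for the
ordered probit.

## Simulation engine

Per step, in fixed person order: (1) mortality draw against Φ(c + x′γ)
at start-of-step covariates; a death freezes the state and records the
death-confirmed status; (2) survivors draw the next score by inverse CDF
over the ordered-probit category probabilities; (3) the two-wave rule
updates verified status; (4) lags shift, age advances by the drawn gap,
and exogenous covariates update ("synthetic" process) or stay fixed
("frozen"). Mortality-before-cognition makes status-at-death equal the
last wave's status, matching the observed-data rule.

Randomness is counter-based (Philox): each (draw kind, wave, replicate)
triple owns a substream keyed by the base seed, and person i consumes
draw i, each covariate field drawing from its own substream. Runs are
bit-reproducible and appending persons never perturbs existing persons'
draws. The synthetic cohort's forward evolution and the projection engine
share one `step` implementation, so truth panels and simulations have
identical dynamics by construction.

## Synthetic cohort (the study conditions)

The generator emulates a 2006-style 53+ survey cohort: baseline
prevalences set to the published sample means (e.g. hypertension 0.517,
working 0.429, smoker-ever 0.571; race shares 0.811/0.091/0.073;
education 0.181/0.347/0.472), ages uniform 53–90, log-normal mean-one
weights (σ = 0.5). Baseline scores are a discretized normal centered at
15.6 (reproducing the published weighted mean 15.57 within sampling
noise), with dispersion rising in age and falling with education. A
pre-baseline wave supplies the four-year lag: its score is the baseline
score plus N(0.3, 1.6²), i.e. slightly higher two years earlier.

Forward dynamics use the published coefficient vectors as latent-index
truth. Two quantities the coefficient table does not print are
calibrated once against the baseline cohort: the cognition cutpoints by
quantile matching (κⱼ = m + s·Φ⁻¹(F(j)) with m the mean realized index,
s² = var(index) + 1, F the baseline score CDF), which makes the one-step
score distribution approximately stationary; and the mortality intercept,
set so the mean per-wave death probability is 0.07 (≈31% ten-year
mortality, the order observed in the published transition table).
Exogenous covariates evolve by absorbing per-wave incidences (e.g. heart
0.025, stroke 0.012, widowhood 0.020), a BMI random walk (sd 0.02),
age-increasing retirement, occasional smoking cessation, and upward
ADL/IADL drift — stand-in processes chosen to keep every coefficient
identifiable, not claims about any particular survey.

Proxy-respondent missingness is MNAR by construction: outside a 25%
never-missing share, a live score is masked with probability
logistic(−0.7 − 0.15·score), giving ≈4–5% masked interviews with
impaired-range scorers several times more likely to be masked — about
half of masked rows come from the impaired bands, matching published
proxy-interview cognition ratings. What the generator does *not* emulate:
item-level test content, survey strata/clusters, nonresponse other than
death, covariate feedback from cognition (covariates are exogenous).
Passing self-consistency tests therefore demonstrates that estimation,
simulation and validation are mutually coherent at realistic sizes — not
that the model is correct for any real survey.

## Multiple imputation

Sequential-regression MI with predictive mean matching (5 donors, m = 5):
wave by wave, a linear regression of observed scores on demographics,
health and economic covariates plus adjacent-wave cognition is fitted;
parameters are drawn from their approximate posterior, with a small
diagonal ridge (1e−4, scaled) on the normal equations — the adjacent-wave
score blocks are nearly collinear, and unregularized draws have exploding
variance along near-null directions that sweep feedback amplifies;
missing cells copy
the observed score of a donor with a near-matching prediction, so imputed
values are always observed integers in 0–27. After the forward pass, two
further chained sweeps re-impute each wave conditioning on the previous
two and the next wave's (imputed) cognition. Both refinements are
deliberate: the twice-prior score keeps the imputation model congenial
with the analysis model's two lags, and next-wave conditioning shrinks
the residual variance that score-dependent masking tilts — without it the
earliest wave (which has no prior-wave predictor) is imputed with bias
roughly slope×residual-variance. Pooling averages coefficient vectors
across the m completed-panel fits and reports between-imputation variance
as a diagnostic.

A known limitation, visible in the test suite: with masking driven by the
score alone, complete-case ordered-probit estimation is nearly unbiased
for the *coefficients* (the category-specific selection factor is
absorbed almost exactly by the 27 free cutpoints), so MI — whose imputed
cells inherit an MNAR tilt no observable-based imputation can remove —
improves the imputed cells and the score distribution but not the lag
coefficient relative to dropping incomplete rows. The corresponding
acceptance test states the stronger claim and is left failing rather than
weakened; see the test for the exact comparison.

## Validation framework

K-fold cross-validation partitions persons uniformly (fold sizes differ by
at most one); each fold's baseline is simulated by models fitted on the
other folds, and held-out outcomes are pooled. Weighted percentiles use
the left-continuous inverse of the weighted empirical CDF (type-1 at
uniform weights; integer scores give integer percentiles). ROC curves
sweep distinct risk thresholds; AUROC equals (concordant + ½·tied) /
(cases × controls) exactly, verified against an O(n²) count. Conditional
predicates ("dementia given alive") divide the alive-with-status replicate
fraction by the alive fraction and are evaluated among persons observed
alive at the horizon. Individual-level metrics use the full-follow-up
subsample (observed every wave until the horizon or death); the
significant-decline outcome (drop ≥ 3 points, the MMSE-crosswalk
threshold) is evaluated at the two-year horizon among baseline-MCI
persons.

## Problem sizes and numerical choices

Default study conditions: 20,000-person cohorts, 6 waves (baseline + 5
transitions ≙ ten years), 5-fold cross-validation. The engine's default is
500 replicates; self-consistency checks in the test suite run 100
replicates at 20,000 persons (population-level quantities stabilize well
below that, e.g. transition-matrix Monte Carlo error < 0.1pp), and
parameter-recovery experiments use 100,000–200,000 single-transition rows,
where every targeted coefficient is recovered within estimator noise
(≲2 reported SEs). Percentile comparisons on integer scores use the exact
match implied by sub-point tolerances; the 1st percentile sits on a knife
edge at small n and stabilizes at the 20,000-person scale. Ties in PMM
donor selection are broken by a uniform draw among the k nearest; all
randomness everywhere derives from explicit seeds through counter-based
streams.

## Panel CSV schema

Long format, one row per person per wave, written/read by
`write_panel`/`read_panel` with missing scores as empty fields:
`person_id`, `wave` (−1 is the pre-baseline wave), `calendar_year`, `age`,
`male`, `race_ethnicity` ∈ {nh_white, nh_black, hispanic}, `education` ∈
{lt_hs, hs, some_college}, `tics27` (integer 0–27 or empty), `proxy`,
`alive`, `weight`, the condition-ever flags (`heart_ever`, `stroke_ever`,
`cancer_ever`, `hypertension_ever`, `diabetes_ever`, `lung_ever`,
`chf_ever`), `heart_attack_2yr`, `working`, `widowed`, `smoke_ever`,
`smoke_current`, `log_bmi`, `adl_count` (0–3), `iadl_count` (0–2), the
by-age-50 history flags (`heart50`, `stroke50`, `cancer50`,
`hypertension50`, `diabetes50`, `lung50`, `smoke_ever50`,
`smoke_current50`), and `interview_gap_years` (years since the previous
wave's interview). A death contributes one final row with `alive = 0`,
an empty score, and covariates frozen at their last live values; no rows
follow it. `add_status_columns` appends `category` and `verified_status`.

## Known limitations

* Covariates are exogenous; a full co-evolving health-economics model
  would feed back employment, disability and BMI dynamics.
* No survey-design-corrected standard errors, no random effects, no
  time-varying coefficients.
* Verification requires adjacent observed waves; statuses are not bridged
  across interior nonresponse.
* Simulated persons are never "alive with missing score".
* The ordered probit cannot emit score levels absent from its training
  data (by construction of the merged category set).
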