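# ticsim

Dynamic microsimulation of late-life cognitive decline on the 27-point
telephone cognitive screen (TICS27), with the validation framework used to
judge such simulators: k-fold cross-validated estimation, Monte Carlo
replicate-fraction risk scores, and AUROC against held-out outcomes.

## Who this is for

Health-policy and ageing researchers who project cognition for a 53+
survey cohort in two-year steps — the cadence of biennial panels like the
US Health and Retirement Study — and who need the projection *and* an
unbiased way to validate it on the same data.

## The model

Cognition: the next-wave score S ∈ {0,…,27} follows an ordered probit

    P(S = j | x) = Φ(κⱼ − x′β) − Φ(κⱼ₋₁ − x′β),   κ₀ < κ₁ < … < κ₂₆,

with covariates x holding the two- and four-year lagged scores,
demographics (race/ethnicity, education, sex), piecewise-linear age
splines (knots 65, 75), chronic-condition indicators, employment,
widowhood, smoking, a lagged log-BMI spline (knot at BMI 30), the
deviation of the interview gap from two years, and an absorbing
verified-impairment flag.

Mortality: two-year death is a probit P(death | x) = Φ(c + x′γ) with age
spline knots 65, 75, 85 and ADL/IADL limitation dummies.

Scores band into categories — 0–6 dementia (ADOD), 7–11 mild cognitive
impairment, 12–27 normal — and a category becomes a person's *verified*
status only when a second adjacent wave (or death) confirms it; verified
status is absorbing. The engine steps a cohort forward (mortality draw,
then score draw, then status update), repeats over hundreds of Monte Carlo
replicates, and scores each person's risk of an outcome as the fraction of
replicates in which it occurs. The validation suite partitions persons
into k folds, fits the models on k−1 folds, simulates the held-out fold,
and compares pooled simulations to observations: weighted score
percentiles, a 3×5 cognitive/mortality transition matrix, and AUROCs by
predicate, subgroup and horizon. Proxy respondents have the score missing
not-at-random; a sequential-regression multiple-imputation module fills
those cells by predictive mean matching.

Because the survey microdata are access-restricted, the package ships a
first-class synthetic-cohort generator that reproduces the structural
features the models assume (biennial waves, a pre-baseline wave for the
four-year lag, absorbing condition histories, log-normal mean-one weights,
MNAR proxy masking), seeded with the published transition-model
coefficients as the data-generating truth.

## Worked example

```python
import dataclasses
from ticsim import (CohortConfig, SimulationConfig, default_true_models,
                    generate_panel, cross_validated_simulate, evaluate)

cfg = CohortConfig(n_individuals=2000, seed=11)
cfg = dataclasses.replace(cfg, true_models=default_true_models(cfg))
panel = generate_panel(cfg)                      # 6 biennial waves, deaths included

sim = SimulationConfig(horizon_waves=5, replicates=20, base_seed=99)
outcomes, fits = cross_validated_simulate(panel, k=2, sim_config=sim, seed=5)
report = evaluate(panel, outcomes)

a = report.auroc
full = a[(a.subgroup == "full_sample") &
         (a.predicate == "dementia_or_dead_with_dementia")]
print(full[["horizon_wave", "auroc"]])
```

prints (one run of the above):

```
     horizon_wave     auroc
0               1  1.000000
50              2  0.977660
100             3  0.939955
150             4  0.899589
200             5  0.887281
```

i.e. the cross-validated simulator ranks who will be demented-or-dead-with-
dementia almost perfectly two years out (wave 1), and discrimination decays
toward AUROC ≈ 0.89 at the ten-year horizon (wave 5) — the signature
pattern of a well-calibrated cognition simulator. `report.distribution`
holds the weighted score percentiles at baseline and at the horizon
(observed vs simulated), and `report.transition_truth` /
`report.transition_sim` the 3×5 percent-of-population transition matrices.

A CLI mirrors the library: `ticsim generate`, `ticsim fit`,
`ticsim impute`, `ticsim simulate`, `ticsim crossval` (see `--help`).

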