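# exploresim

Simulation and analysis of explore–exploit decision making in developmental
behavioral studies.  The package provides fully generative, seeded models of
two classic paradigms — a Horizon-style two-armed bandit with an unequal
information manipulation, and an Orchard-style patch-foraging task — together
with parameterized choice agents, maximum-likelihood model fitting, synthetic
participant cohorts, and the complete statistical pipeline (regressions,
trial-level logistic mixed models, estimated marginal effects, bootstrap
mediation, optimality tests).  It is aimed at researchers who want to
prototype, power, and validate analyses of information-seeking and foraging
behavior without collecting data first: every stage of a study can be run end
to end on synthetic children whose causal structure is known and planted.

## The tasks and models

**Horizon bandit task.**  Each of 80 games pits two Gaussian bandits
(means anchored at 40 or 60 points, gaps of 4–30 points, payout SD 8,
rounded to integers) against each other.  Four forced trials sample one
bandit three times and the other once, then the participant makes either one
(short horizon) or six (long horizon) free choices.  Choosing the
once-sampled, high-information bandit at the first free choice is
*exploration*.  Free choices follow a logistic choice model

    p(choose 1) = σ( (ΔR + A·ΔI + B·side + K·rep) / σ_noise )

with information bonus `A`, spatial bias `B`, habit (choice-repetition)
bonus `K`, and decision noise `σ_noise`, all in payout points (±1 contrast
coding of the indicators).  The same probability is used for simulation and
for likelihood-based fitting.

**Orchard foraging task.**  Foragers harvest trees whose yield decays by a
mean factor 0.88 per 3-second harvest, and pay a 6-second (rich environment)
or 12-second (poor environment) travel cost to reach a fresh tree, across
four 3.5-minute orchard blocks.  The behavioral *exit threshold* is the mean
of the last two harvests before leaving a tree.  The optimal threshold
follows the Marginal Value Theorem: leave when the expected next harvest
falls below ρ·h, where ρ is the long-run reward rate induced by that same
rule — a fixed point the package solves by Monte Carlo and verifies with a
brute-force policy search (rich ≈ 6.52 apples, poor ≈ 5.31 apples).

**Synthetic cohorts.**  Each synthetic child carries a latent
childhood-unpredictability trait expressed through a 38-item binary
questionnaire (five subscales; totals calibrated to mean ≈ 5.6, SD ≈ 5.1,
right-skewed), covariates (family income, digit span, a distress scalar),
and planted decision parameters.  By default the trait raises the habit
bonus `K`, which lowers exploration — a fully mediated pathway the analysis
stage is able to detect, quantify, and correctly reject when absent.

## Worked example

```python
from exploresim.orchard import rich_config, poor_config, mvt_solve
from exploresim.cohort import generate_cohort, cohort_table, simulate_first_free_study
from exploresim.analysis import exploration_regression, mediate

rich, poor = mvt_solve(rich_config()), mvt_solve(poor_config())
print(f"optimal exit threshold, rich (6 s travel): {rich.threshold:.2f} apples")
print(f"optimal exit threshold, poor (12 s travel): {poor.threshold:.2f} apples")

cohort = generate_cohort(84, seed=1, include_foraging=False)
trials = simulate_first_free_study(cohort, seed=2)
per = (trials.groupby("participant_id")
       .agg(p_explore_overall=("explore", "mean"),
            habitual_rate=("habitual", "mean"))
       .reset_index().merge(cohort_table(cohort), on="participant_id"))
reg = exploration_regression(per).term("quic_total")
med = mediate(per, n_boot=5000, seed=3)
```

prints

```
optimal exit threshold, rich (6 s travel): 6.51 apples
optimal exit threshold, poor (12 s travel): 5.29 apples
```

and the fitted study-level results are

```
unpredictability -> exploration: B = -0.034, t(79) = -5.16, p < 0.001
indirect effect through habitual responding: ab = -0.0356,
    95% CI [-0.0496, -0.0232]; direct c' = 0.0017
```

i.e. on an 84-child synthetic cohort the regression recovers the planted
negative association between questionnaire unpredictability and the rate of
choosing the informative option, and the bootstrap mediation attributes
essentially all of it to habitual responding (the direct path, planted at
zero, is estimated near zero).

The same stages are available from the shell:

```bash
exploresim simulate --n 84 --seed 1 --out run/data
exploresim metrics  --data run/data --out run/metrics.csv
exploresim fit      --data run/data --out run/fits
exploresim analyze  --data run/data --out run/results
exploresim reproduce --n 84 --seed 1 --out run   # all of the above
```

Every command records its seeds in a JSON manifest and re-runs are
byte-identical.

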