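# Methods notes

This note records the modeling assumptions, calibration decisions and known
limitations behind the package, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Horizon bandit task

The schedule is the full factorial of five payout-mean gaps (4, 8, 12, 20,
30 points) × high-mean side (left/right) × horizon (short/long) × placement
of the high-information option (on or off the high-mean side), replicated
twice — once with the high-mean bandit anchored at 40 points and once at 60
— for 80 games, shuffled per seed.  The exact factorization behind the
original 80-game design is not published; this one satisfies the stated
counterbalancing of information, reward amount and side.  The lower bandit
sits `gap` points below its anchor, so generative means range from 10 to 60
points; payouts are Gaussian (SD 8) rounded half-away-from-zero, without
clipping (negative draws are astronomically rare at these means).  The
internal order of each 3:1 forced sequence is uniformly randomized per game,
as the order within forced trials is not analyzed.

Free choices follow the logistic choice model described in the README.  Two
conventions matter for interpreting fitted values:

* Indicators are coded +1/−1 and enter the decision variable unhalved, so a
  bonus `A` moves the decision variable by `2A` between the two options.
  This matches the package's documented worked arithmetic (e.g.
  `p = σ((−5 + 10)/8)` for `A = 10` against a 5-point payout deficit); when
  comparing with conventions that code the contrast as ±1/2, divide by two.
* The "previous option" for the habit term is the choice on the immediately
  preceding trial — at the first free choice, the fourth forced trial.
  Because the forced sequence ends on the thrice-shown bandit three times
  out of four on average, a positive habit bonus mechanically suppresses
  exploration, which is exactly the mediating pathway the synthetic cohorts
  plant.

With zero decision noise the choice is greedy and an exactly tied decision
variable is resolved by a fair coin.

The vectorized first-free-choice simulator (`simulate_first_free`) plays
only trials 1–5.  Exploration, habitual responding, reward–information
conflict and the fitting likelihood are all defined on those trials, so
cohort-scale calibration studies use it; it samples from the same
`horizon_choice_prob` as the trial-by-trial `play_game`, and a test verifies
the two agree in distribution.

## Orchard foraging task and the MVT solver

Within a tree, harvest `k+1` yields `κ · s_k` with `κ` drawn from a Gaussian
truncated to (0, 1].  Naive truncation of N(0.88, sd) would bias the
realized mean ratio below 0.88, so the location parameter is solved (by
Brent root-finding on the truncated-normal mean) to keep the post-truncation
mean exactly at the configured depletion rate; `depletion_sd = 0.07` by
default, with 0 allowed for deterministic tests.

The initial yield of a fresh tree is not published for this task lineage.
It is modeled as a Gaussian truncated at zero with pre-truncation mean 8 and
SD 8 apples — realized mean ≈ 10.3 with a strong right skew, so typical
trees start near 10 apples while some are nearly barren.  These two numbers
were fixed once so that the MVT solver reproduces the task's published
optimal thresholds (6.52 apples at 6 s travel, 5.31 at 12 s); they are the
only calibrated constants in the orchard model.  A narrow initial-yield
distribution cannot reproduce both optima simultaneously: with
near-deterministic trees the ratio of rich to poor optimum is pinned at
≈ 1.256 by the depletion rate and the travel/harvest times alone, whereas
the published optima have ratio 1.228; a wide, zero-truncated distribution
lowers the ratio because the mandatory first harvest at poor trees taxes the
rich environment's higher reward rate relatively more.

The solver iterates the MVT fixed point on a common set of simulated trees
(100,000 by default): given a candidate rate ρ, the rule "leave when the
expected next harvest κ̄·s drops below ρ·h" implies per-tree totals and
harvest counts, which imply a new rate; damped iteration converges in a few
dozen steps to tolerance 1e−6 (the Monte-Carlo map is piecewise constant at
finer scales).  Thresholds are reported on the behavioral scale — the
expected mean of the last two harvests before leaving — so solver output and
participants' measured exit thresholds are directly comparable.  The
brute-force oracle sweeps a grid of leave cutoffs, estimates each one's
long-run rate by simulation, and reports the behavioral threshold of the
rate-maximizing cutoff; solver and oracle agree within Monte-Carlo and grid
resolution across environments (a core correctness test).

Session simulation accounts time exactly: 3 s per harvest, 6/12 s per move,
four 210-second blocks in ABAB/BABA order; an action that does not fit in
the remaining budget is discarded and the block ends.  The first action at
every tree is a harvest.  Exit thresholds computed from logs drop the first
completed exit of each block (participants cannot know the travel time
before their first move) and ignore visits cut short by the block end; a
single-harvest tree contributes that harvest as its threshold, preserving
sample size under the forced first harvest.

## Choice-model fitting

The likelihood covers first free choices only (the later free trials
confound reward and information).  Fitting is multi-start (10 starts)
bounded L-BFGS-B over `A, B, K ∈ [−30, 30]` and `σ ∈ [0.1, 50]`,
deterministic given data and seed.  The default cohort configuration fits
horizon-specific information bonus and decision noise with shared spatial
bias and habit bonus; a pooled four-parameter fit is used for parameter
recovery.  Recovery at 160 games per agent yields true-vs-fitted
correlations around 0.9 for the information bonus and 0.75–0.85 for the
habit bonus (verified in the acceptance tests); an exhaustive grid search
over the four-dimensional box doubles as an optimizer oracle.

## Synthetic cohorts

The latent unpredictability trait is standard normal.  Questionnaire items
are binary indicators `loading·U + ε > τ` with a single loading (0.566) and
threshold (1.200) for all 38 items, solved analytically so that totals have
mean 5.63 and SD 5.05 in the population; the implied latent–total
correlation is ≈ 0.86, and totals are right-skewed with a large mass near
zero, as real unpredictability scores are.  Item-level psychometrics
(per-item difficulties, reverse scoring, response formats) are deliberately
not modeled: the totals and their five subscale groupings (9, 12, 7, 7, 3
items) are the emulation target.  Covariates (income ≈ N(4.29, 1.39) on a
1–7 ordinal scale, digit span ≈ N(10.85, 3.18), a standard-normal distress
scalar, and a parent-report scalar) are drawn independently of the trait,
so they act purely as controls; anxiety and perceived stress are collapsed
into the single distress covariate.

Planted structure: `K = 1 + 4·U + N(0, 1.5)` (habit pathway),
`A_short = 2`, `A_long = 4` plus a shared individual deviate (SD 2) and an
optional direct slope on `U` (zero by default), noise `σ = 8·exp(N(0, 0.2))`,
bias `B ~ N(0, 1.5)`.  The habit slope of 4 points per SD was fixed to
produce an unpredictability–exploration association comparable in size to a
replication-scale study (per-participant correlation ≈ −0.4), which gives
the exploration regression ≥ 80% power at n = 84 while keeping baseline
rates realistic (exploration ≈ 0.53, strategic-exploration difference
≈ 0.03).  Foraging agents get an individual over-exploration trait
N(+1.5, 1.0) apples shared across environments, added to each environment's
optimal behavioral threshold and inverted through the monotone
cutoff-to-threshold map; by default foraging thresholds are unrelated to
unpredictability, mirroring the dissociation the pipeline should preserve.

What the generator does *not* emulate: learning or drift across games,
reaction times, within-questionnaire item structure, demographic effects,
and any correlation between covariates and the trait.  Passing pipeline
tests therefore demonstrate statistical correctness (calibration, power,
recovery of planted structure), not robustness to those real-data features.

## Statistical pipeline

Continuous predictors are z-scored (sample SD).  The exploration regression
is OLS with Wald intervals.  Trial-level models are logistic with a
participant random intercept, estimated by statsmodels' variational-Bayes
binomial mixed GLM; richer condition-specific random intercepts are not
reliably estimable at 80 trials per participant and are deliberately
omitted.  If estimation fails the model falls back to a plain logistic
regression with participant-clustered robust standard errors and flags the
result.  Marginal effects are average derivatives of the predicted
probability with respect to the standardized trait at each moderator level
(random effects at zero, other covariates at observed values), with
delta-method intervals using the variational posterior SDs — an
approximation that ignores posterior correlations between fixed effects.
Mediation is the product-of-coefficients estimator from two linear
regressions with a percentile bootstrap over participants (default 5,000
draws); `total = direct + indirect` holds exactly by OLS algebra.  Outlier
screening removes participants beyond 2 SDs of the sample mean of a metric
in a single pass, separately per task.  p values are reported unadjusted,
matching the reporting style the pipeline mirrors.

## Numerical sizes and determinism

Defaults were chosen so the full test suite runs in a few minutes on one
core: 100,000 trees for the MVT solver (threshold standard error ≈ 0.003
apples), 30,000 for oracle comparisons, 100 agents × 160 games for
recovery, 100 cohorts of n = 84 for error-rate calibration, and 1,000–2,000
bootstrap draws in tests (5,000 in the user-facing default).  Every
stochastic routine takes an explicit seed or Generator; study drivers spawn
per-participant generators from a root seed, so runs are reproducible byte
for byte.

## Known limitations

* The initial-yield distribution is a calibrated stand-in constrained by the
  two published optima, not a published task parameter; alternative shapes
  matching those optima exist.
* The variational mixed-logit underestimates posterior correlations; its SEs
  are mildly optimistic relative to a full-likelihood GLMM.
* The exploration regression treats a proportion as Gaussian; at 80 games
  per participant this is benign, but small-game designs would warrant a
  binomial model.
* The habit term repeats the immediately preceding choice only; richer
  choice kernels (exponentially weighted histories) are out of scope.
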