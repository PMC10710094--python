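"""The statistical pipeline over participant metrics and trial-level logs.

Implements the study's inferential stages: ordinary least squares of the
exploration rate on the (standardized) unpredictability score with
covariates; trial-level logistic mixed models with a participant random
intercept and an unpredictability-by-condition interaction, reported as odds
ratios; estimated marginal effects of unpredictability on the predicted
outcome probability at each condition level (delta-method intervals);
product-of-coefficients mediation with a percentile bootstrap over
participants; one-sample t tests of exit-threshold deviations from the MVT
optimum; and a linear mixed model for the rich-vs-poor environment effect on
exit thresholds.

Mixed logistic models are estimated with statsmodels' variational-Bayes
binomial mixed GLM; when that fails the model falls back to a plain logistic
regression with participant-clustered robust standard errors and the result
carries a warning flag.  Wald intervals are used throughout and p values are
reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
import warnings

DEFAULT_COVARIATES = ("digit_span", "income", "anxiety")

_MODERATORS = {
    # moderator name -> (source column, level-1 meaning)
    "horizon": ("horizon", "long"),
    "conflict": ("conflict", 1),
    "uncertainty": ("prev_uncertainty", "less_info"),
}


def standardize(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns (sample SD, ddof=1); errors on constants."""
    out = df.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant column {col!r}")
        out[col] = (x - x.mean()) / sd
    return out


@dataclass
class RegressionResult:
    """Tidy coefficient table plus bookkeeping for one fitted model."""

    table: pd.DataFrame            # term, estimate, se, stat, df, p, ci_low,
    #                                ci_high[, odds_ratio]
    method: str
    n_participants: int
    n_trials: int | None = None
    warnings: list[str] = field(default_factory=list)
    model: object | None = None    # fitted statsmodels results, when retained

    def term(self, name: str) -> pd.Series:
        match = self.table[self.table["term"] == name]
        if not len(match):
            raise KeyError(f"no term {name!r}; have {list(self.table['term'])}")
        return match.iloc[0]


@dataclass
class MarginalEffect:
    """Average marginal effect of the predictor at one condition level."""

    level: str
    effect: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class MediationResult:
    """Product-of-coefficients mediation with a bootstrap interval."""

    path_a: float
    path_b: float
    indirect: float                 # a * b
    direct: float                   # c'
    total: float                    # c  (= c' + a*b for the linear estimator)
    ci_low: float                   # percentile bootstrap CI of a*b
    ci_high: float
    n_boot: int
    seed: int


def _ols_table(fit, terms=None) -> pd.DataFrame:
    ci = fit.conf_int()
    rows = []
    for name in (terms or fit.params.index):
        rows.append({"term": name, "estimate": fit.params[name],
                     "se": fit.bse[name], "stat": fit.tvalues[name],
                     "df": float(fit.df_resid), "p": fit.pvalues[name],
                     "ci_low": ci.loc[name, 0], "ci_high": ci.loc[name, 1]})
    return pd.DataFrame(rows)


def exploration_regression(metrics: pd.DataFrame,
                           outcome: str = "p_explore_overall",
                           predictor: str = "quic_total",
                           covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """OLS of the exploration rate on standardized unpredictability.

    ``metrics`` must hold one row per participant with the outcome, the
    predictor and the covariates (outlier screening is assumed done).
    Continuous predictors are standardized before fitting.
    """
    cols = [outcome, predictor, *covariates]
    data = metrics[cols].dropna()
    data = standardize(data, [predictor, *covariates])
    X = sm.add_constant(data[[predictor, *covariates]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient "
                         "(collinear covariates)")
    fit = sm.OLS(data[outcome], X).fit()
    return RegressionResult(table=_ols_table(fit), method="ols",
                            n_participants=len(data), model=fit)


def _glmm_design(trial_table: pd.DataFrame, participants: pd.DataFrame,
                 outcome: str, moderator: str,
                 predictor: str, covariates) -> tuple[pd.DataFrame, list[str]]:
    source, level1 = _MODERATORS[moderator]
    df = trial_table.merge(participants, on="participant_id", how="inner")
    df = df.dropna(subset=[outcome, source, predictor, *covariates])
    df["moderator"] = (df[source] == level1).astype(float)
    if df["moderator"].nunique() < 2:
        raise ValueError(f"moderator {moderator!r} is constant; "
                         "interaction not estimable")
    df = standardize(df, [predictor, *covariates])
    df = df.rename(columns={predictor: "u"})
    df["u_x_mod"] = df["u"] * df["moderator"]
    fixed = ["u", "moderator", "u_x_mod", *covariates]
    return df, fixed


def trial_glmm(trial_table: pd.DataFrame, participants: pd.DataFrame,
               outcome: str = "explore", moderator: str = "horizon",
               predictor: str = "quic_total",
               covariates=DEFAULT_COVARIATES) -> RegressionResult:
    """Logistic mixed model of a first-free-choice outcome.

    Fixed effects: standardized unpredictability, a binary condition
    moderator (horizon long, reward-information conflict, or previous-option
    uncertainty), their interaction, and standardized covariates; random
    intercept per participant.  Coefficients are log odds with Wald CIs and
    odds ratios.  On estimation failure the model falls back to plain
    logistic regression with participant-clustered robust SEs (flagged).
    """
    df, fixed = _glmm_design(trial_table, participants, outcome, moderator,
                             predictor, covariates)
    formula = f"{outcome} ~ " + " + ".join(fixed)
    warns: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(
                formula, {"participant": "0 + C(participant_id)"}, df)
            fit = model.fit_vb()
        names = list(fit.model.exog_names)
        est = fit.fe_mean
        se = fit.fe_sd
        method = "binomial_mixed_glm_vb"
    except Exception as exc:                      # pragma: no cover - fallback
        warns.append(f"mixed model failed ({exc}); participant-clustered "
                     "logistic fallback")
        X = sm.add_constant(df[fixed])
        fit = sm.GLM(df[outcome], X, family=sm.families.Binomial()).fit(
            cov_type="cluster",
            cov_kwds={"groups": df["participant_id"].to_numpy()})
        names = list(fit.params.index)
        est = fit.params.to_numpy()
        se = fit.bse.to_numpy()
        method = "cluster_robust_logit"
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "term": names, "estimate": est, "se": se, "stat": z, "df": np.nan,
        "p": p, "ci_low": est - 1.959963984540054 * se,
        "ci_high": est + 1.959963984540054 * se,
    })
    table["odds_ratio"] = np.exp(table["estimate"])
    table["or_ci_low"] = np.exp(table["ci_low"])
    table["or_ci_high"] = np.exp(table["ci_high"])
    result = RegressionResult(table=table, method=method,
                              n_participants=df["participant_id"].nunique(),
                              n_trials=len(df), warnings=warns, model=fit)
    # retained for marginal_effects
    result._design = df
    result._fixed = fixed
    result._outcome = outcome
    return result


def marginal_effects(glmm: RegressionResult, levels=(0.0, 1.0),
                     level_labels=None) -> list[MarginalEffect]:
    """Average marginal effect of unpredictability at each moderator level.

    For every observation the moderator is set to the given level (other
    variables at their observed values, random effects at zero) and the
    derivative of the predicted probability with respect to the standardized
    unpredictability score is averaged; SEs come from the delta method on
    the fixed-effect covariance.
    """
    df = glmm._design
    fixed = glmm._fixed
    beta = glmm.table.set_index("term")["estimate"]
    se = glmm.table.set_index("term")["se"]
    names = ["Intercept" if "Intercept" in beta.index else "const", *fixed]
    b = beta.loc[names].to_numpy()
    cov = np.diag(se.loc[names].to_numpy() ** 2)
    out = []
    for j, level in enumerate(levels):
        X = df.copy()
        X["moderator"] = level
        X["u_x_mod"] = X["u"] * level
        M = np.column_stack([np.ones(len(X)),
                             *[X[f].to_numpy(dtype=float) for f in fixed]])
        eta = M @ b
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = pr * (1 - pr)
        slope_coef = b[names.index("u")] + b[names.index("u_x_mod")] * level
        effect = float(np.mean(slope_coef * w))
        # gradient wrt beta
        grad = np.empty(len(b))
        curv = w * (1 - 2 * pr)
        for k in range(len(b)):
            direct = 0.0
            if names[k] == "u":
                direct = np.mean(w)
            elif names[k] == "u_x_mod":
                direct = np.mean(w) * level
            grad[k] = direct + slope_coef * np.mean(curv * M[:, k])
        eff_se = float(np.sqrt(grad @ cov @ grad))
        label = (level_labels[j] if level_labels is not None else str(level))
        out.append(MarginalEffect(level=label, effect=effect, se=eff_se,
                                  ci_low=effect - 1.959963984540054 * eff_se,
                                  ci_high=effect + 1.959963984540054 * eff_se))
    return out


def mediate(data: pd.DataFrame, exposure: str = "quic_total",
            mediator: str = "habitual_rate", outcome: str = "p_explore_overall",
            covariates=DEFAULT_COVARIATES, n_boot: int = 5000,
            seed: int = 0) -> MediationResult:
    """Product-of-coefficients mediation with a percentile bootstrap.

    Two linear regressions on standardized exposure/covariates —
    mediator ~ exposure + covariates (a-path) and
    outcome ~ exposure + mediator + covariates (b-path and direct c') —
    give the indirect effect a*b; participants are resampled with
    replacement for the bootstrap interval.  The identity c = c' + a*b holds
    exactly for this estimator.
    """
    if n_boot < 1000:
        raise ValueError("use at least 1000 bootstrap draws")
    cols = [exposure, mediator, outcome, *covariates]
    df = standardize(data[cols].dropna().reset_index(drop=True),
                     [exposure, *covariates])
    n = len(df)
    x = df[exposure].to_numpy()
    m = df[mediator].to_numpy()
    y = df[outcome].to_numpy()
    Z = df[list(covariates)].to_numpy() if covariates else np.empty((n, 0))
    ones = np.ones((n, 1))

    def paths(idx):
        Xa = np.column_stack([ones[idx], x[idx], Z[idx]])
        a = np.linalg.lstsq(Xa, m[idx], rcond=None)[0][1]
        Xb = np.column_stack([ones[idx], x[idx], m[idx], Z[idx]])
        coef = np.linalg.lstsq(Xb, y[idx], rcond=None)[0]
        return a, coef[2], coef[1]          # a, b, c'

    idx_all = np.arange(n)
    a, b, cprime = paths(idx_all)
    Xc = np.column_stack([ones, x, Z])
    total = np.linalg.lstsq(Xc, y, rcond=None)[0][1]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab_i = paths(idx)
        boot[i] = ab_i[0] * ab_i[1]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MediationResult(path_a=a, path_b=b, indirect=a * b, direct=cprime,
                           total=total, ci_low=float(lo), ci_high=float(hi),
                           n_boot=n_boot, seed=seed)


def optimality_tests(metrics: pd.DataFrame) -> pd.DataFrame:
    """One-sample t tests of exit-threshold deviations against zero.

    Positive mean deviation means leaving trees earlier than the MVT optimum
    (over-exploration).  One row per environment.
    """
    rows = []
    for env in ("rich", "poor"):
        dev = metrics[f"deviation_{env}"].dropna().to_numpy()
        if len(dev) < 2:
            raise ValueError(f"need >= 2 participants with {env} deviations")
        if np.std(dev, ddof=1) == 0:
            # degenerate sample: all deviations identical
            t = 0.0 if dev.mean() == 0 else np.sign(dev.mean()) * np.inf
            p = 1.0 if dev.mean() == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(dev, 0.0)
        rows.append({"environment": env, "mean_deviation": dev.mean(),
                     "t": float(t), "df": len(dev) - 1, "p": float(p),
                     "n": len(dev)})
    return pd.DataFrame(rows)


def environment_effect(tree_thresholds: pd.DataFrame,
                       participants: pd.DataFrame | None = None,
                       predictor: str = "quic_total") -> RegressionResult:
    """Linear mixed model of per-tree exit thresholds on environment.

    ``tree_thresholds`` is the per-tree table from
    :func:`exploresim.metrics.tree_exit_thresholds`.  Environment is coded
    rich = 1, so a positive estimate reproduces the manipulation check that
    thresholds are higher (earlier leaving) in the short-travel-time
    environment.  When a participant table is given, standardized
    unpredictability and its interaction with environment are added.
    """
    df = tree_thresholds.copy()
    df["rich"] = (df["environment"] == "rich").astype(float)
    fixed = ["rich"]
    if participants is not None:
        df = df.merge(participants[["participant_id", predictor]],
                      on="participant_id", how="inner")
        df = standardize(df, [predictor])
        df = df.rename(columns={predictor: "u"})
        df["u_x_rich"] = df["u"] * df["rich"]
        fixed += ["u", "u_x_rich"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "exit_threshold ~ " + " + ".join(fixed),
            groups="participant_id", data=df)
        fit = model.fit(reml=True)
    names = [n for n in fit.params.index if n != "Group Var"]
    ci = fit.conf_int()
    table = pd.DataFrame({
        "term": names,
        "estimate": [fit.params[n] for n in names],
        "se": [fit.bse[n] for n in names],
        "stat": [fit.tvalues[n] for n in names],
        "df": np.nan,
        "p": [fit.pvalues[n] for n in names],
        "ci_low": [ci.loc[n, 0] for n in names],
        "ci_high": [ci.loc[n, 1] for n in names],
    })
    return RegressionResult(table=table, method="linear_mixed_model",
                            n_participants=df["participant_id"].nunique(),
                            n_trials=len(df), model=fit)
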