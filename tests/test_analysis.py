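"""Statistical pipeline: regressions, mixed models, mediation, optimality."""

import numpy as np
import pandas as pd
import pytest

from exploresim import analysis as an
from exploresim.cohort import (EffectConfig, cohort_table, generate_cohort,
                               simulate_first_free_study)


@pytest.fixture(scope="module")
def planted_cohort():
    cohort = generate_cohort(150, seed=31, include_foraging=False)
    tab = cohort_table(cohort)
    ff = simulate_first_free_study(cohort, seed=32)
    per = (ff.groupby("participant_id")
             .agg(p_explore_overall=("explore", "mean"),
                  habitual_rate=("habitual", "mean"))
             .reset_index().merge(tab, on="participant_id"))
    return tab, ff, per


class TestStandardize:
    def test_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z = an.standardize(df, ["x"])["x"]
        assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            an.standardize(pd.DataFrame({"x": [2.0, 2.0]}), ["x"])

    def test_idempotent(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(3, 2, 50)})
        once = an.standardize(df, ["x"])
        twice = an.standardize(once, ["x"])
        pd.testing.assert_frame_equal(once, twice)


class TestExplorationRegression:
    def test_detects_planted_negative_effect(self, planted_cohort):
        _, _, per = planted_cohort
        res = an.exploration_regression(per)
        term = res.term("quic_total")
        assert term["estimate"] < 0
        assert term["p"] < 0.01
        assert term["ci_low"] <= term["estimate"] <= term["ci_high"]

    def test_collinear_covariate_rejected(self, planted_cohort):
        _, _, per = planted_cohort
        per = per.copy()
        per["income_copy"] = per["income"]
        with pytest.raises(ValueError):
            an.exploration_regression(
                per, covariates=("digit_span", "income", "income_copy",
                                 "anxiety"))


class TestTrialGLMM:
    def test_uncertainty_interaction_shows_habit_signature(self,
                                                           planted_cohort):
        """When the previous option is the familiar (thrice-shown) one,
        unpredictability reduces exploring — the planted habit pathway."""
        tab, ff, _ = planted_cohort
        res = an.trial_glmm(ff, tab, outcome="explore",
                            moderator="uncertainty")
        term = res.term("u_x_mod")
        assert term["odds_ratio"] < 1.0
        assert term["p"] < 0.05
        assert term["odds_ratio"] == pytest.approx(
            np.exp(term["estimate"]))

    def test_constant_moderator_rejected(self, planted_cohort):
        tab, ff, _ = planted_cohort
        short_only = ff[ff["horizon"] == "short"]
        with pytest.raises(ValueError):
            an.trial_glmm(short_only, tab, moderator="horizon")

    def test_matches_plain_logistic_without_heterogeneity(self):
        """With no participant heterogeneity the mixed model's fixed effects
        agree with ordinary logistic regression."""
        rng = np.random.default_rng(33)
        n_part, n_trials = 40, 60
        rows = []
        u_vals = rng.normal(0, 1, n_part)
        for i in range(n_part):
            mod = rng.integers(0, 2, n_trials)
            eta = -0.3 + 0.6 * u_vals[i] - 0.4 * mod
            y = rng.random(n_trials) < 1 / (1 + np.exp(-eta))
            for t in range(n_trials):
                rows.append((f"p{i}", "long" if mod[t] else "short",
                             int(y[t])))
        trials = pd.DataFrame(rows, columns=["participant_id", "horizon",
                                             "explore"])
        participants = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n_part)],
            "quic_total": u_vals,
            "digit_span": rng.normal(10, 3, n_part),
            "income": rng.normal(4, 1.4, n_part),
            "anxiety": rng.normal(0, 1, n_part)})
        res = an.trial_glmm(trials, participants, outcome="explore",
                            moderator="horizon")
        import statsmodels.api as sm
        df, fixed = an._glmm_design(trials, participants, "explore",
                                    "horizon", "quic_total",
                                    an.DEFAULT_COVARIATES)
        X = sm.add_constant(df[fixed])
        glm = sm.GLM(df["explore"], X,
                     family=sm.families.Binomial()).fit()
        for term, name in (("u", "u"), ("moderator", "moderator")):
            assert res.term(term)["estimate"] == pytest.approx(
                glm.params[name], abs=0.1)


class TestMarginalEffects:
    def test_no_interaction_gives_level_invariant_effects(self,
                                                          planted_cohort):
        """The habit pathway is horizon-unspecific, so the marginal effect
        of unpredictability is similar in short- and long-horizon games."""
        tab, ff, _ = planted_cohort
        res = an.trial_glmm(ff, tab, outcome="explore", moderator="horizon")
        short, long_ = an.marginal_effects(res,
                                           level_labels=("short", "long"))
        assert short.effect < 0 and long_.effect < 0
        assert abs(short.effect - long_.effect) < 0.05
        for m in (short, long_):
            assert m.ci_low <= m.effect <= m.ci_high
            assert m.se > 0


class TestMediation:
    def test_algebraic_identity_total_equals_direct_plus_indirect(self):
        rng = np.random.default_rng(34)
        n = 80
        df = pd.DataFrame({
            "quic_total": rng.normal(5, 5, n),
            "habitual_rate": rng.random(n),
            "p_explore_overall": rng.random(n),
            "digit_span": rng.normal(10, 3, n),
            "income": rng.normal(4, 1.4, n),
            "anxiety": rng.normal(0, 1, n)})
        res = an.mediate(df, n_boot=1000, seed=1)
        assert res.total == pytest.approx(res.direct + res.indirect,
                                          abs=1e-8)

    def test_full_mediation_recovered(self, planted_cohort):
        _, _, per = planted_cohort
        res = an.mediate(per, n_boot=1000, seed=2)
        assert res.ci_high < 0          # indirect effect clearly negative
        assert res.indirect < 0

    def test_null_mediation_interval_covers_zero(self):
        effect = EffectConfig(slope_u_repeat=0.0, slope_u_info=0.0)
        cohort = generate_cohort(300, effect, seed=35, include_foraging=False)
        per = (simulate_first_free_study(cohort, seed=36)
               .groupby("participant_id")
               .agg(p_explore_overall=("explore", "mean"),
                    habitual_rate=("habitual", "mean"))
               .reset_index().merge(cohort_table(cohort),
                                    on="participant_id"))
        res = an.mediate(per, n_boot=1000, seed=3)
        assert res.ci_low <= 0 <= res.ci_high

    def test_deterministic_per_seed(self, planted_cohort):
        _, _, per = planted_cohort
        a = an.mediate(per, n_boot=1000, seed=4)
        b = an.mediate(per, n_boot=1000, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_bootstrap_draws_rejected(self, planted_cohort):
        _, _, per = planted_cohort
        with pytest.raises(ValueError):
            an.mediate(per, n_boot=100)


class TestOptimality:
    def test_zero_deviations_give_null_result(self):
        metrics = pd.DataFrame({"deviation_rich": [0.0] * 5,
                                "deviation_poor": [0.0] * 5})
        res = an.optimality_tests(metrics).set_index("environment")
        assert res.loc["rich", "t"] == 0.0
        assert res.loc["rich", "p"] == 1.0

    def test_planted_overexploration_detected(self):
        rng = np.random.default_rng(37)
        metrics = pd.DataFrame({
            "deviation_rich": rng.normal(1.5, 1.0, 76),
            "deviation_poor": rng.normal(1.5, 1.0, 76)})
        res = an.optimality_tests(metrics).set_index("environment")
        for env in ("rich", "poor"):
            assert res.loc[env, "t"] > 2.0
            assert res.loc[env, "p"] < 0.001
            assert res.loc[env, "df"] == 75

    def test_single_participant_rejected(self):
        metrics = pd.DataFrame({"deviation_rich": [1.0],
                                "deviation_poor": [1.0]})
        with pytest.raises(ValueError):
            an.optimality_tests(metrics)


class TestEnvironmentEffect:
    @staticmethod
    def tree_table(rich_mean, poor_mean, n_part=20, n_trees=8, sd=0.5,
                   seed=38):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_part):
            for env, mu in (("rich", rich_mean), ("poor", poor_mean)):
                for t in range(n_trees):
                    rows.append((f"p{i}", env,
                                 rng.normal(mu, sd)))
        return pd.DataFrame(rows, columns=["participant_id", "environment",
                                           "exit_threshold"])

    def test_recovers_rich_poor_difference(self):
        trees = self.tree_table(6.52, 5.31)
        res = an.environment_effect(trees)
        term = res.term("rich")
        assert term["estimate"] == pytest.approx(1.21, abs=0.15)
        assert term["p"] < 0.001

    def test_no_difference_gives_null_effect(self):
        trees = self.tree_table(5.9, 5.9)
        res = an.environment_effect(trees)
        assert abs(res.term("rich")["estimate"]) < 0.15
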