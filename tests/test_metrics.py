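"""Behavioral statistics from trial logs."""

import numpy as np
import pandas as pd
import pytest

from exploresim.agents import HorizonAgentParams
from exploresim.horizon import simulate_first_free
from exploresim.metrics import (classify_conflict, compute_exit_thresholds,
                                compute_exploration,
                                compute_reward_maximization,
                                compute_strategic, exclude_outliers,
                                first_free_choice_table, is_habitual_response,
                                participant_metrics, tree_exit_thresholds)
from conftest import make_horizon_game


def make_foraging_log(trees, environment="rich", orchard_id=1,
                      participant_id="p0", complete_last=True):
    """Build a foraging event log from per-tree harvest-yield lists."""
    rows, t = [], 0.0
    travel = 6.0 if environment == "rich" else 12.0
    for idx, harvests in enumerate(trees, start=1):
        for y in harvests:
            t += 3.0
            rows.append((participant_id, orchard_id, environment, idx,
                         "harvest", y, t))
        if complete_last or idx < len(trees):
            t += travel
            rows.append((participant_id, orchard_id, environment, idx,
                         "leave", np.nan, t))
    return pd.DataFrame(rows, columns=["participant_id", "orchard_id",
                                       "environment", "tree_index", "action",
                                       "yield", "elapsed_s"])


class TestExploration:
    def test_toy_log_proportions(self):
        games = []
        for gid, choice in enumerate(["left", "left", "right", "right"],
                                     start=1):
            games.append(make_horizon_game(game_id=gid, info="left",
                                           free_choices=(choice,)))
        trials = pd.concat(games, ignore_index=True)
        short, long_, overall = compute_exploration(trials)
        assert overall == 0.5
        assert short == 0.5 and np.isnan(long_)

    def test_all_exploring(self):
        trials = make_horizon_game(info="left", free_choices=("left",))
        assert compute_exploration(trials)[2] == 1.0

    def test_greedy_agent_never_explores_in_conflict_games(self, schedule):
        """With no bonuses and no noise, exploration happens only when the
        informative option has the higher observed mean."""
        agent = HorizonAgentParams(decision_noise=0.0)
        rng = np.random.default_rng(8)
        table = simulate_first_free(schedule, agent, rng)
        conflict = table[table["conflict"] == 1]
        assert len(conflict) > 5
        assert conflict["explore"].sum() == 0

    def test_explore_exploit_sum_to_one(self, schedule, noisy_agent, rng):
        table = simulate_first_free(schedule, noisy_agent, rng)
        p_explore = table["explore"].mean()
        p_exploit = 1 - table["explore"].mean()
        assert p_explore + p_exploit == pytest.approx(1.0)


class TestStrategic:
    def test_difference(self):
        assert compute_strategic(0.4, 0.6) == pytest.approx(0.2)
        assert compute_strategic(0.5, 0.5) == 0.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            compute_strategic(-0.1, 0.5)

    def test_long_horizon_bonus_yields_positive_strategic_index(self,
                                                                schedule):
        agent = HorizonAgentParams(
            info_bonus=0.0, decision_noise=8.0,
            horizon_overrides={"long": {"info_bonus": 8.0}})
        rng = np.random.default_rng(9)
        table = simulate_first_free(schedule * 25, agent, rng)
        by_h = table.groupby("horizon")["explore"].mean()
        assert compute_strategic(by_h["short"], by_h["long"]) > 0.05


class TestConflictAndHabit:
    def test_no_conflict_when_info_pays_more(self):
        game = make_horizon_game(info="left", payouts=(50, 42, 44, 40),
                                 forced=("left", "right", "right", "right"))
        assert classify_conflict(game) == "no_conflict"

    def test_conflict_when_info_pays_less(self):
        game = make_horizon_game(info="left", payouts=(40, 50, 52, 48),
                                 forced=("left", "right", "right", "right"))
        assert classify_conflict(game) == "conflict"

    def test_tie_counts_as_no_conflict(self):
        game = make_horizon_game(info="left", payouts=(44, 44, 44, 44),
                                 forced=("left", "right", "right", "right"))
        assert classify_conflict(game) == "no_conflict"

    def test_habitual_repeat_detected(self):
        game = make_horizon_game(forced=("right", "left", "right", "right"),
                                 info="left", free_choices=("right",))
        indicator, label = is_habitual_response(game)
        assert indicator == 1
        assert label == "less_info"   # trial 4 was the thrice-shown bandit

    def test_previous_option_uncertainty_label(self):
        game = make_horizon_game(forced=("right", "right", "right", "left"),
                                 info="left", free_choices=("right",))
        indicator, label = is_habitual_response(game)
        assert indicator == 0
        assert label == "more_info"

    def test_habit_heavy_agent_repeats_almost_always(self, schedule):
        agent = HorizonAgentParams(repeat_bonus=100.0, decision_noise=8.0)
        rng = np.random.default_rng(10)
        table = simulate_first_free(schedule, agent, rng)
        assert table["habitual"].mean() > 0.99


class TestExitThresholds:
    def test_last_two_harvest_mean(self):
        log = make_foraging_log([[9, 8], [10, 8.8, 7.7, 6.8]])
        trees = tree_exit_thresholds(log, drop_first_per_block=False)
        assert trees["exit_threshold"].tolist() == [8.5, pytest.approx(7.25)]

    def test_single_harvest_tree_uses_that_harvest(self):
        log = make_foraging_log([[9, 8], [10.0]])
        trees = tree_exit_thresholds(log, drop_first_per_block=False)
        assert trees["exit_threshold"].iloc[-1] == 10.0

    def test_first_exit_per_block_dropped(self):
        log = make_foraging_log([[9, 8], [10, 8.8, 7.7, 6.8], [7, 6]])
        trees = tree_exit_thresholds(log)
        assert trees["exit_threshold"].tolist() == [pytest.approx(7.25), 6.5]

    def test_incomplete_final_visit_ignored(self):
        complete = make_foraging_log([[9, 8], [8, 7], [10, 9]],
                                     complete_last=False)
        trees = tree_exit_thresholds(complete)
        assert len(trees) == 1          # first dropped, last unfinished
        assert trees["exit_threshold"].iloc[0] == 7.5

    def test_deviation_sign_convention(self):
        log = make_foraging_log([[9, 8], [10, 9], [10, 9]])
        out = compute_exit_thresholds(log, {"rich": 6.52, "poor": 5.31})
        assert out["exit_threshold_rich"] == pytest.approx(9.5)
        assert out["deviation_rich"] == pytest.approx(9.5 - 6.52)
        assert np.isnan(out["exit_threshold_poor"])


class TestRewardMaximization:
    def test_greedy_agent_maximizes(self):
        game = make_horizon_game(horizon="long", info="left",
                                 forced=("left", "right", "right", "right"),
                                 payouts=(50, 42, 44, 40),
                                 free_choices=("left",) * 6,
                                 free_payouts=(55, 52, 58, 54, 56, 53))
        assert compute_reward_maximization(game) == 1.0

    def test_anti_greedy_agent_scores_zero(self):
        game = make_horizon_game(horizon="long", info="left",
                                 forced=("left", "right", "right", "right"),
                                 payouts=(50, 42, 44, 40),
                                 free_choices=("left",) + ("right",) * 5,
                                 free_payouts=(55, 38, 39, 41, 40, 42))
        assert compute_reward_maximization(game) == 0.0

    def test_short_games_have_no_eligible_trials(self):
        game = make_horizon_game()
        assert np.isnan(compute_reward_maximization(game))


class TestOutlierExclusion:
    def test_constructed_outlier_removed(self):
        metrics = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(10)],
            "p_explore_overall": [0.5] * 9 + [0.99]})
        kept, excluded = exclude_outliers(metrics, "p_explore_overall")
        assert excluded == ["p9"]
        assert len(kept) == 9

    def test_identical_values_keep_everyone(self):
        metrics = pd.DataFrame({"participant_id": list("abc"),
                                "p_explore_overall": [0.5] * 3})
        kept, excluded = exclude_outliers(metrics, "p_explore_overall")
        assert excluded == [] and len(kept) == 3

    def test_small_sample_rejected(self):
        metrics = pd.DataFrame({"participant_id": ["a", "b"],
                                "p_explore_overall": [0.4, 0.6]})
        with pytest.raises(ValueError):
            exclude_outliers(metrics, "p_explore_overall")


class TestParticipantTable:
    def test_metrics_assembled_per_participant(self):
        g1 = make_horizon_game(participant_id="a")
        g2 = make_horizon_game(participant_id="b", free_choices=("right",))
        horizon = pd.concat([g1, g2], ignore_index=True)
        foraging = make_foraging_log([[9, 8], [10, 9]], participant_id="a")
        table = participant_metrics(horizon, foraging,
                                    {"rich": 6.52, "poor": 5.31})
        assert set(table["participant_id"]) == {"a", "b"}
        a = table.set_index("participant_id").loc["a"]
        assert a["p_explore_overall"] == 1.0   # chose info bandit
        assert a["exit_threshold_rich"] == pytest.approx(9.5)
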