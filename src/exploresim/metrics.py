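"""Behavioral statistics computed from tidy trial logs.

Horizon task: exploration is choosing the high-information (once-sampled)
bandit at the first free choice (trial 5); strategic exploration is the
long-minus-short-horizon difference in that proportion; a game poses a
reward-information conflict when the high-information option has the lower
observed payout mean after the forced trials; habitual responding is
repeating the trial-4 choice at trial 5; reward maximization is the
proportion of later free choices (trial 6 onward) that pick the bandit with
the higher observed payout mean.

Orchard task: the exit threshold is the mean of the last two harvests before
leaving a tree (a single-harvest tree contributes that one harvest).  The
first exit of every block is dropped, thresholds are averaged per
environment, and the deviation from the MVT-optimal threshold is positive
when the participant leaves trees earlier than optimal (over-exploration).

Participants whose metric lies more than 2 SDs from the sample mean can be
excluded; the rule is applied in one pass per task, and exclusion in one
task does not propagate to the other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_FORCED = 4
FIRST_FREE_TRIAL = 5

METRIC_COLUMNS = ["participant_id", "p_explore_short", "p_explore_long",
                  "p_explore_overall", "strategic_exploration",
                  "habitual_rate", "reward_maximization", "mean_reward",
                  "exit_threshold_rich", "exit_threshold_poor",
                  "deviation_rich", "deviation_poor"]


# ---------------------------------------------------------------------------
# Horizon-task metrics

def _check_game(game: pd.DataFrame) -> pd.DataFrame:
    game = game.sort_values("trial_index")
    if len(game) < FIRST_FREE_TRIAL:
        raise ValueError("each game needs at least 5 trials "
                         f"(game {game['game_id'].iloc[0]} has {len(game)})")
    return game


def classify_conflict(game: pd.DataFrame) -> str:
    """'conflict' iff the high-information option has the strictly lower
    observed mean over the forced trials; ties count as no_conflict."""
    game = _check_game(game)
    forced = game[game["trial_index"] <= N_FORCED]
    info = game["info_bandit"].iloc[0]
    m_info = forced.loc[forced["choice"] == info, "payout"].mean()
    m_other = forced.loc[forced["choice"] != info, "payout"].mean()
    if np.isnan(m_info) or np.isnan(m_other):
        raise ValueError("forced trials must sample both bandits")
    return "conflict" if m_info < m_other else "no_conflict"


def is_habitual_response(game: pd.DataFrame) -> tuple[int, str]:
    """(repeat indicator, uncertainty of the previous option).

    The indicator is 1 iff the trial-5 choice repeats the trial-4 choice.
    The label says whether the previous (trial-4) option is the once-sampled
    high-information option ('more_info') or the thrice-sampled familiar one
    ('less_info').
    """
    game = _check_game(game)
    t4 = game.loc[game["trial_index"] == 4, "choice"].iloc[0]
    t5 = game.loc[game["trial_index"] == FIRST_FREE_TRIAL, "choice"].iloc[0]
    info = game["info_bandit"].iloc[0]
    label = "more_info" if t4 == info else "less_info"
    return int(t4 == t5), label


def first_free_choice_table(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per game with the first-free-choice outcomes and moderators.

    Columns: participant_id, game_id, horizon, explore (0/1), habitual (0/1),
    conflict (0/1), prev_uncertainty ('more_info'/'less_info'),
    obs_mean_diff (info-option observed mean minus the other's).
    """
    rows = []
    for (pid, gid), game in trials.groupby(["participant_id", "game_id"],
                                           sort=False):
        game = _check_game(game)
        info = game["info_bandit"].iloc[0]
        forced = game[game["trial_index"] <= N_FORCED]
        m_info = forced.loc[forced["choice"] == info, "payout"].mean()
        m_other = forced.loc[forced["choice"] != info, "payout"].mean()
        t5_choice = game.loc[game["trial_index"] == FIRST_FREE_TRIAL,
                             "choice"].iloc[0]
        habitual, prev_unc = is_habitual_response(game)
        rows.append((pid, gid, game["horizon"].iloc[0],
                     int(t5_choice == info), habitual,
                     int(m_info < m_other), prev_unc, m_info - m_other))
    return pd.DataFrame(rows, columns=["participant_id", "game_id", "horizon",
                                       "explore", "habitual", "conflict",
                                       "prev_uncertainty", "obs_mean_diff"])


def compute_exploration(trials: pd.DataFrame) -> tuple[float, float, float]:
    """(p_explore_short, p_explore_long, p_explore_overall) for one
    participant's trial log."""
    table = first_free_choice_table(trials)
    by_h = table.groupby("horizon")["explore"].mean()
    return (float(by_h.get("short", np.nan)), float(by_h.get("long", np.nan)),
            float(table["explore"].mean()))


def compute_strategic(p_explore_short: float, p_explore_long: float) -> float:
    """Horizon adaptation of exploration: long minus short proportion."""
    for p in (p_explore_short, p_explore_long):
        if not 0 <= p <= 1:
            raise ValueError("exploration proportions must lie in [0, 1]")
    return p_explore_long - p_explore_short


def compute_reward_maximization(trials: pd.DataFrame) -> float:
    """Proportion of free choices after the first that pick the bandit with
    the higher observed payout mean at choice time; ties are excluded."""
    n_max, n_used = 0, 0
    for _, game in trials.groupby(["participant_id", "game_id"], sort=False):
        game = _check_game(game)
        sums = {"left": 0.0, "right": 0.0}
        counts = {"left": 0, "right": 0}
        for _, row in game.iterrows():
            if row["trial_index"] > FIRST_FREE_TRIAL:
                means = {s: sums[s] / counts[s] for s in ("left", "right")}
                if means["left"] != means["right"]:
                    best = max(means, key=means.get)
                    n_used += 1
                    n_max += int(row["choice"] == best)
            sums[row["choice"]] += row["payout"]
            counts[row["choice"]] += 1
    return n_max / n_used if n_used else np.nan


# ---------------------------------------------------------------------------
# Orchard-task metrics

def tree_exit_thresholds(foraging: pd.DataFrame,
                         drop_first_per_block: bool = True) -> pd.DataFrame:
    """Per-tree exit thresholds from a foraging event log.

    A tree visit counts only when it was completed (followed by a leave
    event); the threshold is the mean of its last two harvests, or the single
    harvest for a one-harvest tree.  The first completed exit of every block
    is dropped by default, mirroring how participants discover the travel
    time of a block only after their first move.
    """
    rows = []
    harvests = foraging[foraging["action"] == "harvest"]
    leaves = foraging[foraging["action"] == "leave"]
    left_trees = set(map(tuple, leaves[["participant_id", "orchard_id",
                                        "tree_index"]].values))
    for (pid, oid, tid), tree in harvests.groupby(
            ["participant_id", "orchard_id", "tree_index"], sort=True):
        if (pid, oid, tid) not in left_trees:
            continue                     # visit cut short by the block end
        y = tree.sort_values("elapsed_s")["yield"].to_numpy()
        threshold = float(y[-2:].mean())
        rows.append((pid, oid, tree["environment"].iloc[0], tid, threshold,
                     len(y)))
    out = pd.DataFrame(rows, columns=["participant_id", "orchard_id",
                                      "environment", "tree_index",
                                      "exit_threshold", "n_harvests"])
    if drop_first_per_block and len(out):
        first = (out.sort_values("tree_index")
                    .groupby(["participant_id", "orchard_id"]).head(1).index)
        out = out.drop(first).reset_index(drop=True)
    return out


def compute_exit_thresholds(foraging: pd.DataFrame,
                            optimal_thresholds: dict[str, float] | None = None
                            ) -> dict[str, float]:
    """Per-environment mean exit threshold (and deviation from optimal) for
    one participant's foraging log.

    ``optimal_thresholds`` maps environment name to the MVT-optimal
    threshold; deviations are participant minus optimal, positive meaning
    earlier leaving than optimal (over-exploration).
    """
    trees = tree_exit_thresholds(foraging)
    by_env = trees.groupby("environment")["exit_threshold"].mean()
    out = {"exit_threshold_rich": float(by_env.get("rich", np.nan)),
           "exit_threshold_poor": float(by_env.get("poor", np.nan))}
    if optimal_thresholds is not None:
        for env in ("rich", "poor"):
            out[f"deviation_{env}"] = (out[f"exit_threshold_{env}"]
                                       - optimal_thresholds[env])
    return out


# ---------------------------------------------------------------------------
# participant-level table and outlier rule

def participant_metrics(horizon_trials: pd.DataFrame | None = None,
                        foraging_trials: pd.DataFrame | None = None,
                        optimal_thresholds: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """One row per participant with every behavioral statistic available
    from the supplied logs (missing task -> NaN columns)."""
    ids: list = []
    for df in (horizon_trials, foraging_trials):
        if df is not None:
            ids.extend(df["participant_id"].unique())
    ids = list(dict.fromkeys(ids))
    rows = []
    for pid in ids:
        row: dict = {"participant_id": pid}
        if horizon_trials is not None:
            t = horizon_trials[horizon_trials["participant_id"] == pid]
            if len(t):
                table = first_free_choice_table(t)
                by_h = table.groupby("horizon")["explore"].mean()
                row["p_explore_short"] = float(by_h.get("short", np.nan))
                row["p_explore_long"] = float(by_h.get("long", np.nan))
                row["p_explore_overall"] = float(table["explore"].mean())
                row["strategic_exploration"] = (row["p_explore_long"]
                                                - row["p_explore_short"])
                row["habitual_rate"] = float(table["habitual"].mean())
                row["reward_maximization"] = compute_reward_maximization(t)
                row["mean_reward"] = float(
                    t.loc[t["phase"] == "free", "payout"].mean())
        if foraging_trials is not None:
            f = foraging_trials[foraging_trials["participant_id"] == pid]
            if len(f):
                row.update(compute_exit_thresholds(f, optimal_thresholds))
        rows.append(row)
    return pd.DataFrame(rows).reindex(columns=METRIC_COLUMNS)


def exclude_outliers(metrics: pd.DataFrame, which: str
                     ) -> tuple[pd.DataFrame, list]:
    """Drop participants whose ``which`` metric is > 2 SDs from the mean.

    Mean and SD come from the full sample in a single pass (the rule is not
    re-applied to the filtered set).  Returns (kept, excluded ids).  With
    zero sample SD nothing is excluded.
    """
    if len(metrics) < 3:
        raise ValueError("outlier screening needs at least 3 participants")
    x = metrics[which].astype(float)
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return metrics.copy(), []
    mask = (x - mu).abs() > 2 * sd
    return (metrics.loc[~mask].copy(),
            metrics.loc[mask, "participant_id"].tolist())
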