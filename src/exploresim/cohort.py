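"""Synthetic developmental cohorts for end-to-end pipeline validation.

Each synthetic child has a latent (standard-normal) childhood-unpredictability
trait, 38 binary questionnaire items generated from that trait through a
thresholded common-factor model (calibrated so cohort totals have mean ~5.6
and SD ~5.1 with a strong right skew — many children near zero), covariates
(family income, digit span, a distress scalar, a parent-report scalar), and
planted decision parameters for both tasks.

The planted causal structure mirrors the hypothesis the pipeline is built to
detect: unpredictability raises the habit (choice-repetition) bonus, which in
turn lowers exploration at the first free choice, with an optional direct
path through the information bonus.  Under the default configuration the
direct path is zero, so the unpredictability-exploration association is fully
mediated by habitual responding.  Foraging thresholds are planted above the
MVT optimum (children over-explore in the orchard) and, by default,
unrelated to unpredictability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .agents import ForagingAgentParams, HorizonAgentParams
from .horizon import generate_schedule, play_game, simulate_first_free, \
    trials_to_frame
from .orchard import (OrchardConfig, _tree_stats, _tree_yield_matrix,
                      mvt_solve, poor_config, rich_config, simulate_session)

#: QUIC subscales (name, number of items); sizes sum to 38
QUIC_SUBSCALES = (("parental_involvement", 9), ("parental_predictability", 12),
                  ("parental_environment", 7), ("physical_environment", 7),
                  ("safety_security", 3))
N_QUIC_ITEMS = 38

#: thresholded common-factor calibration: item endorsed iff
#: loading * latent + N(0,1) > threshold.  Fixed so cohort totals match the
#: questionnaire's published moments (mean 5.63, SD 5.05); implied
#: latent-observed total correlation ~= 0.86.
QUIC_LOADING = 0.566
QUIC_THRESHOLD = 1.200


@dataclass
class EffectConfig:
    """Planted effect structure and population distributions of a cohort.

    Slopes are in decision-model points per SD of the latent trait.  The
    defaults plant the full-mediation structure (habit path only) with an
    effect size in the range of the replication study's association between
    unpredictability and exploration.
    """

    slope_u_repeat: float = 4.0        # a-path: latent trait -> habit bonus
    slope_u_info: float = 0.0          # direct path via the information bonus
    quic_loading: float = QUIC_LOADING
    # Horizon-task population parameters
    base_info_short: float = 2.0
    base_info_long: float = 4.0
    sd_info: float = 2.0
    base_repeat: float = 1.0
    sd_repeat: float = 1.5
    base_noise: float = 8.0
    sd_log_noise: float = 0.2
    sd_bias: float = 1.5
    # Orchard-task population parameters (behavioral-threshold scale, apples)
    overexploration_mean: float = 1.5
    overexploration_sd: float = 1.0
    slope_u_threshold: float = 0.0
    foraging_noise_sd: float = 1.0
    # covariate moments
    income_mean: float = 4.29
    income_sd: float = 1.39
    digit_span_mean: float = 10.85
    digit_span_sd: float = 3.18

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Participant:
    """One synthetic child: latent trait, questionnaire, covariates, and
    planted decision parameters."""

    participant_id: str
    latent_u: float
    quic_items: np.ndarray            # 38 binary responses
    quic_total: int
    quic_subscales: dict[str, int]
    income: float
    digit_span: int
    anxiety: float
    parent_report: float
    horizon_params: HorizonAgentParams
    foraging_params: ForagingAgentParams | None = None


def quic_score(items) -> tuple[int, dict[str, int]]:
    """Total and per-subscale sums of the 38 binary questionnaire items."""
    items = np.asarray(items)
    if items.shape != (N_QUIC_ITEMS,) or set(np.unique(items)) - {0, 1}:
        raise ValueError(f"expected {N_QUIC_ITEMS} binary items")
    subscales = {}
    start = 0
    for name, size in QUIC_SUBSCALES:
        subscales[name] = int(items[start:start + size].sum())
        start += size
    return int(items.sum()), subscales


def _behavioral_to_cutoff_curve(config: OrchardConfig, seed: int = 0,
                                n_trees: int = 20_000):
    """Monotone map from leave cutoff to realized mean exit threshold,
    tabulated once per environment for fast inversion."""
    rng = np.random.default_rng(seed)
    yields = _tree_yield_matrix(config, n_trees, rng, 64)
    cutoffs = np.linspace(0.5, 1.6 * config.initial_yield_mean, 80)
    thresholds = np.array([
        _tree_stats(yields, c, config.depletion_mean)[2].mean()
        for c in cutoffs])
    return cutoffs, thresholds


def generate_cohort(n: int, effect: EffectConfig | None = None, seed: int = 0,
                    include_foraging: bool = True,
                    rich: OrchardConfig | None = None,
                    poor: OrchardConfig | None = None) -> list[Participant]:
    """Draw a cohort of ``n`` synthetic children; deterministic per seed."""
    if n < 2:
        raise ValueError("need at least 2 participants")
    if effect is None:
        effect = EffectConfig()
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    # questionnaire items via the thresholded common-factor model
    propensity = effect.quic_loading * u[:, None] + rng.standard_normal(
        (n, N_QUIC_ITEMS))
    items = (propensity > QUIC_THRESHOLD).astype(int)
    # covariates, independent of the trait (the paper treats them as controls)
    income = np.clip(np.round(rng.normal(effect.income_mean, effect.income_sd,
                                         n)), 1, 7)
    digit = np.clip(np.round(rng.normal(effect.digit_span_mean,
                                        effect.digit_span_sd, n)), 0, None)
    anxiety = rng.standard_normal(n)
    parent_report = rng.standard_normal(n)
    # planted Horizon-task parameters
    info_dev = rng.normal(0.0, effect.sd_info, n)
    info_short = effect.base_info_short + effect.slope_u_info * u + info_dev
    info_long = effect.base_info_long + effect.slope_u_info * u + info_dev
    repeat = effect.base_repeat + effect.slope_u_repeat * u \
        + rng.normal(0.0, effect.sd_repeat, n)
    noise = effect.base_noise * np.exp(rng.normal(0.0, effect.sd_log_noise, n))
    bias = rng.normal(0.0, effect.sd_bias, n)

    foraging: list[ForagingAgentParams | None] = [None] * n
    if include_foraging:
        rich = rich or rich_config()
        poor = poor or poor_config()
        # one individual over-exploration trait, shared across environments
        offset = (effect.overexploration_mean
                  + effect.overexploration_sd * rng.standard_normal(n)
                  + effect.slope_u_threshold * u)
        cutoffs = {}
        for env, cfg in (("rich", rich), ("poor", poor)):
            opt = mvt_solve(cfg, n_trees=50_000).threshold
            grid_c, grid_b = _behavioral_to_cutoff_curve(cfg)
            target = np.clip(opt + offset, grid_b[0] + 1e-6,
                             grid_b[-1] - 1e-6)
            cutoffs[env] = np.interp(target, grid_b, grid_c)
        foraging = [ForagingAgentParams(
            exit_threshold=float(cutoffs["rich"][i]),
            exit_threshold_poor=float(cutoffs["poor"][i]),
            threshold_noise_sd=effect.foraging_noise_sd) for i in range(n)]

    cohort = []
    for i in range(n):
        total, subscales = quic_score(items[i])
        hp = HorizonAgentParams(
            info_bonus=float(info_short[i]), spatial_bias=float(bias[i]),
            decision_noise=float(noise[i]), repeat_bonus=float(repeat[i]),
            horizon_overrides={"long": {"info_bonus": float(info_long[i])}})
        cohort.append(Participant(
            participant_id=f"p{i:04d}", latent_u=float(u[i]),
            quic_items=items[i], quic_total=total, quic_subscales=subscales,
            income=float(income[i]), digit_span=int(digit[i]),
            anxiety=float(anxiety[i]), parent_report=float(parent_report[i]),
            horizon_params=hp, foraging_params=foraging[i]))
    return cohort


def cohort_table(cohort: list[Participant]) -> pd.DataFrame:
    """One row per participant: questionnaire, covariates, true parameters."""
    rows = []
    for p in cohort:
        row = {"participant_id": p.participant_id, "latent_u": p.latent_u,
               "quic_total": p.quic_total, "income": p.income,
               "digit_span": p.digit_span, "anxiety": p.anxiety,
               "parent_report": p.parent_report,
               "true_info_bonus_short": p.horizon_params.info_bonus,
               "true_info_bonus_long":
                   p.horizon_params.for_horizon("long")[0],
               "true_repeat_bonus": p.horizon_params.repeat_bonus,
               "true_decision_noise": p.horizon_params.decision_noise,
               "true_spatial_bias": p.horizon_params.spatial_bias}
        row.update({f"quic_{k}": v for k, v in p.quic_subscales.items()})
        if p.foraging_params is not None:
            row["true_exit_cutoff_rich"] = p.foraging_params.exit_threshold
            row["true_exit_cutoff_poor"] = p.foraging_params.exit_threshold_poor
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_study(cohort: list[Participant], seed: int = 0,
                   rich: OrchardConfig | None = None,
                   poor: OrchardConfig | None = None,
                   tasks=("horizon", "orchard")
                   ) -> dict[str, pd.DataFrame]:
    """Full study: every participant plays the 80-game Horizon schedule and
    a four-orchard foraging session with their planted parameters.

    Returns tidy logs keyed "horizon" and "orchard" in the task modules'
    CSV schemas.  Game schedules and block orders vary across participants
    (seeded); deterministic per (cohort, seed).
    """
    rich = rich or rich_config()
    poor = poor or poor_config()
    root = np.random.default_rng(seed)
    horizon_logs, orchard_logs = [], []
    for i, p in enumerate(cohort):
        rng = np.random.default_rng(root.integers(2**31))
        if "horizon" in tasks:
            specs = generate_schedule(int(rng.integers(2**31)))
            records = []
            for spec in specs:
                records.extend(play_game(spec, p.horizon_params, rng,
                                         participant_id=p.participant_id))
            horizon_logs.append(trials_to_frame(specs, records))
        if "orchard" in tasks and p.foraging_params is not None:
            order = "ABAB" if i % 2 == 0 else "BABA"
            orchard_logs.append(simulate_session(
                p.foraging_params, rich, poor, order, rng,
                participant_id=p.participant_id))
    out = {}
    if horizon_logs:
        out["horizon"] = pd.concat(horizon_logs, ignore_index=True)
    if orchard_logs:
        out["orchard"] = pd.concat(orchard_logs, ignore_index=True)
    return out


def simulate_first_free_study(cohort: list[Participant], seed: int = 0
                              ) -> pd.DataFrame:
    """Fast path for cohort-scale exploration/habit studies.

    Simulates only the forced trials and the first free choice of every game
    (the trials that define exploration, habitual responding and the
    choice-model likelihood), using the same choice-probability code as the
    full simulator.  Returns the per-game first-free-choice table for the
    whole cohort.
    """
    root = np.random.default_rng(seed)
    tables = []
    for p in cohort:
        rng = np.random.default_rng(root.integers(2**31))
        specs = generate_schedule(int(rng.integers(2**31)))
        tables.append(simulate_first_free(specs, p.horizon_params, rng,
                                          participant_id=p.participant_id))
    return pd.concat(tables, ignore_index=True)
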