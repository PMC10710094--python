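"""Generative model of the Horizon two-armed bandit task.

Participants play 80 games against two Gaussian bandits.  The first four
trials of every game are forced: the computer samples one bandit three times
and the other once, creating an unequal-information condition in which the
once-sampled bandit is the high-information option.  The game then continues
with either one (short horizon, 5 trials total) or six (long horizon, 10
trials) free choices.  Payouts are Gaussian with SD 8 points, rounded to the
nearest integer; choosing a bandit reveals only that bandit's payout.

The 80-game schedule is the full factorial of 5 payout-mean gaps x 2 sides of
the high-mean bandit x 2 horizons x 2 placements of the high-information
option (on or off the high-mean side), replicated twice with the high-mean
bandit anchored at 40 on one replicate and 60 on the other, then shuffled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import HorizonAgentParams, act_horizon, horizon_choice_prob

#: payout-mean gaps between the two bandits, in points
MEAN_GAPS = (4, 8, 12, 20, 30)
#: anchors for the high-mean bandit, one per replicate of the factorial
MEAN_ANCHORS = (40, 60)
#: Gaussian payout noise, points
PAYOUT_SD = 8.0
N_FORCED = 4

TRIAL_LOG_COLUMNS = ["participant_id", "game_id", "horizon", "trial_index",
                     "phase", "choice", "payout", "mu_left", "mu_right",
                     "info_bandit"]


@dataclass
class HorizonGameSpec:
    """Design of one Horizon game."""

    game_id: int
    horizon: str                      # "short" | "long"
    total_trials: int                 # 5 | 10
    mu_left: float
    mu_right: float
    info_bandit: str                  # bandit forced only once
    forced_sequence: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if self.horizon not in ("short", "long"):
            raise ValueError("horizon must be 'short' or 'long'")
        expected = 5 if self.horizon == "short" else 10
        if self.total_trials != expected:
            raise ValueError(f"{self.horizon} horizon requires "
                             f"{expected} trials, got {self.total_trials}")
        if self.info_bandit not in ("left", "right"):
            raise ValueError("info_bandit must be 'left' or 'right'")
        seq = tuple(self.forced_sequence)
        if len(seq) != N_FORCED or set(seq) - {"left", "right"}:
            raise ValueError("forced_sequence must be four of 'left'/'right'")
        if seq.count(self.info_bandit) != 1:
            raise ValueError("info_bandit must appear exactly once in "
                             "forced_sequence")
        self.forced_sequence = seq

    @property
    def mean_gap(self) -> float:
        return abs(self.mu_left - self.mu_right)

    @property
    def high_mean_side(self) -> str:
        return "left" if self.mu_left >= self.mu_right else "right"

    def mu(self, side: str) -> float:
        return self.mu_left if side == "left" else self.mu_right


@dataclass
class TrialRecord:
    """One trial of one game: what was chosen and what it paid."""

    game_id: int
    trial_index: int                  # 1-based
    phase: str                        # "forced" | "free"
    choice: str                       # "left" | "right"
    payout: int
    participant_id: str = ""


def generate_schedule(seed: int) -> list[HorizonGameSpec]:
    """Build the counterbalanced, shuffled 80-game schedule.

    Every cell of {gap x high-mean side x horizon x info placement} appears
    exactly twice (once per mean anchor); game order and the internal order
    of each forced sequence are randomized by ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs = []
    cells = product(MEAN_ANCHORS, MEAN_GAPS, ("left", "right"),
                    ("short", "long"), ("high", "low"))
    for anchor, gap, high_side, horizon, info_rel in cells:
        low_side = "right" if high_side == "left" else "left"
        mu = {high_side: float(anchor), low_side: float(anchor - gap)}
        info_bandit = high_side if info_rel == "high" else low_side
        other = low_side if info_bandit == high_side else high_side
        forced = [info_bandit] + [other] * 3
        rng.shuffle(forced)
        specs.append(dict(horizon=horizon,
                          total_trials=5 if horizon == "short" else 10,
                          mu_left=mu["left"], mu_right=mu["right"],
                          info_bandit=info_bandit,
                          forced_sequence=tuple(forced)))
    rng.shuffle(specs)
    return [HorizonGameSpec(game_id=i + 1, **s) for i, s in enumerate(specs)]


def sample_payout(mu, sd: float = PAYOUT_SD, rng=None, size=None,
                  integer: bool = True):
    """Sample bandit payouts ~ N(mu, sd), rounded to the nearest integer.

    Rounding is half-away-from-zero.  ``integer=False`` returns the raw
    Gaussian draws (useful for checking the generator's moments).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    draws = rng.normal(loc=mu, scale=sd, size=size)
    if not integer:
        return draws
    rounded = np.copysign(np.floor(np.abs(draws) + 0.5), draws)
    if np.isscalar(draws) or np.ndim(draws) == 0:
        return int(rounded)
    return rounded.astype(int)


def play_game(spec: HorizonGameSpec, agent: HorizonAgentParams, rng,
              participant_id: str = "") -> list[TrialRecord]:
    """Play one game: four forced trials, then free choices by the agent.

    The agent sees only the payouts of bandits it (or the computer) chose;
    the unchosen bandit's payout is never drawn, so it cannot leak.
    """
    records: list[TrialRecord] = []
    history: list[tuple[str, int]] = []
    for t in range(1, spec.total_trials + 1):
        if t <= N_FORCED:
            choice = spec.forced_sequence[t - 1]
            phase = "forced"
        else:
            choice = act_horizon(agent, history, rng, horizon=spec.horizon)
            if choice not in ("left", "right"):
                raise ValueError(f"agent returned invalid choice {choice!r}")
            phase = "free"
        payout = sample_payout(spec.mu(choice), PAYOUT_SD, rng)
        history.append((choice, payout))
        records.append(TrialRecord(game_id=spec.game_id, trial_index=t,
                                   phase=phase, choice=choice, payout=payout,
                                   participant_id=participant_id))
    return records


def simulate_first_free(specs: Sequence[HorizonGameSpec],
                        agent: HorizonAgentParams, rng,
                        participant_id: str = "") -> pd.DataFrame:
    """Vectorized simulation of the forced trials and the first free choice.

    Exploration, habitual responding, and the choice-model likelihood all
    depend only on trials 1-5, so cohort-scale studies of those measures can
    skip the later free choices.  Choice probabilities come from
    :func:`exploresim.agents.horizon_choice_prob`, the same code path
    :func:`play_game` samples from.

    Returns one row per game with left/right-coded model inputs
    (``dr_left`` = observed mean difference left minus right, ``info_left``,
    ``rep_left`` = +1/-1 indicators) and outcomes ``choice_left``,
    ``explore``, ``habitual``, ``conflict``.
    """
    n = len(specs)
    mu_info = np.array([s.mu(s.info_bandit) for s in specs])
    mu_other = np.array([s.mu("left" if s.info_bandit == "right" else "right")
                         for s in specs])
    info_left = np.array([1.0 if s.info_bandit == "left" else -1.0
                          for s in specs])
    rep_left = np.array([1.0 if s.forced_sequence[3] == "left" else -1.0
                         for s in specs])
    horizons = np.array([s.horizon for s in specs])

    m_info = sample_payout(mu_info, PAYOUT_SD, rng, size=n).astype(float)
    m_other = sample_payout(np.repeat(mu_other[:, None], 3, axis=1),
                            PAYOUT_SD, rng, size=(n, 3)).mean(axis=1)
    dr_left = (m_info - m_other) * info_left

    p_left = np.empty(n)
    for h in ("short", "long"):
        mask = horizons == h
        if mask.any():
            p_left[mask] = horizon_choice_prob(
                agent, dr_left[mask], info_left[mask], rep_left[mask],
                side_indicator=1.0, horizon=h)
    choice_left = rng.random(n) < p_left
    explore = choice_left == (info_left > 0)
    habitual = choice_left == (rep_left > 0)
    return pd.DataFrame({
        "participant_id": participant_id,
        "game_id": [s.game_id for s in specs],
        "horizon": horizons,
        "dr_left": dr_left,
        "info_left": info_left,
        "rep_left": rep_left,
        "obs_mean_info": m_info,
        "obs_mean_other": m_other,
        "choice_left": choice_left.astype(int),
        "explore": explore.astype(int),
        "habitual": habitual.astype(int),
        "conflict": (m_info < m_other).astype(int),
        "prev_uncertainty": np.where(rep_left == info_left, "more_info",
                                     "less_info"),
    })


def trials_to_frame(specs: Sequence[HorizonGameSpec],
                    records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy trial log joining per-trial records with their game designs."""
    by_id = {s.game_id: s for s in specs}
    rows = []
    for r in records:
        s = by_id[r.game_id]
        rows.append((r.participant_id, r.game_id, s.horizon, r.trial_index,
                     r.phase, r.choice, r.payout, s.mu_left, s.mu_right,
                     s.info_bandit))
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def schedule_to_json(specs: Sequence[HorizonGameSpec], path=None) -> str:
    """Serialize a schedule for reproducibility; returns the JSON text."""
    payload = json.dumps([asdict(s) for s in specs], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def schedule_from_json(source) -> list[HorizonGameSpec]:
    """Inverse of :func:`schedule_to_json`; accepts a path or JSON text."""
    text = source
    if not str(source).lstrip().startswith("["):
        with open(source) as fh:
            text = fh.read()
    return [HorizonGameSpec(**{**d, "forced_sequence": tuple(d["forced_sequence"])})
            for d in json.loads(text)]
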