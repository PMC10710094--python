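"""Parameterized decision policies for the bandit and foraging tasks.

The central object is the logistic information-bonus choice model used for the
Horizon bandit task.  The probability of choosing option 1 over option 2 is

    p = logistic( (dR + A * dI + B * side + K * rep) / sigma )

where ``dR`` is the difference in observed payout means (option 1 minus
option 2), ``A`` the information bonus in points attached to the
high-information (once-sampled) option, ``B`` a spatial bias, ``K`` a
choice-repetition ("habit") bonus, and ``sigma`` the decision noise in
points.  The indicators ``dI``, ``side`` and ``rep`` are coded +1/-1: +1 when
option 1 is, respectively, the high-information option, the left option, or
the previously chosen option.  Exactly this probability is used both to
simulate choices and to evaluate the likelihood during fitting, so simulated
and fitted behaviour share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy.special import expit


@dataclass
class HorizonAgentParams:
    """Parameters of a Horizon-task decision maker.

    Parameters
    ----------
    info_bonus : float
        A, in points; positive values favour the once-sampled option.
    spatial_bias : float
        B, in points; positive values favour the left option.
    decision_noise : float
        sigma, in points; must be >= 0.  With sigma = 0 the agent is greedy
        on the decision variable and ties are broken by a fair coin.
    repeat_bonus : float
        K, in points; positive values favour repeating the previous choice.
    horizon_overrides : mapping, optional
        Per-horizon overrides, e.g. ``{"long": {"info_bonus": 8.0}}``.  Any of
        the four scalar parameters may be overridden for a given horizon
        ("short" or "long").
    """

    info_bonus: float = 0.0
    spatial_bias: float = 0.0
    decision_noise: float = 8.0
    repeat_bonus: float = 0.0
    horizon_overrides: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.decision_noise < 0:
            raise ValueError("decision_noise must be >= 0")
        for name in ("info_bonus", "spatial_bias", "decision_noise", "repeat_bonus"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def for_horizon(self, horizon: str | None) -> tuple[float, float, float, float]:
        """Effective (A, B, sigma, K) for a horizon condition."""
        a, b, s, k = (self.info_bonus, self.spatial_bias,
                      self.decision_noise, self.repeat_bonus)
        if horizon is not None and self.horizon_overrides:
            ov = self.horizon_overrides.get(horizon, {})
            a = ov.get("info_bonus", a)
            b = ov.get("spatial_bias", b)
            s = ov.get("decision_noise", s)
            k = ov.get("repeat_bonus", k)
        return a, b, s, k

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ForagingAgentParams:
    """Threshold policy for the patch-foraging task.

    ``exit_threshold`` is a cutoff on the *expected next harvest* (apples):
    the agent leaves the current tree as soon as the expected yield of one
    more harvest falls below the cutoff (plus trial-level Gaussian noise with
    SD ``threshold_noise_sd``).  ``exit_threshold_poor``, when given, is used
    in the long-travel-time ("poor") environment instead, letting an agent
    adapt its leaving rule to the environment's reward rate as the Marginal
    Value Theorem prescribes.
    """

    exit_threshold: float
    threshold_noise_sd: float = 0.0
    exit_threshold_poor: float | None = None

    def __post_init__(self) -> None:
        if self.exit_threshold <= 0:
            raise ValueError("exit_threshold must be > 0")
        if self.threshold_noise_sd < 0:
            raise ValueError("threshold_noise_sd must be >= 0")

    def cutoff(self, environment: str = "rich") -> float:
        if environment == "poor" and self.exit_threshold_poor is not None:
            return self.exit_threshold_poor
        return self.exit_threshold


def horizon_choice_prob(params: HorizonAgentParams,
                        observed_mean_diff,
                        info_indicator,
                        repeat_indicator,
                        side_indicator=1.0,
                        horizon: str | None = None):
    """Probability of choosing option 1 in a Horizon-task free choice.

    All decision inputs may be scalars or numpy arrays (broadcast together).

    Parameters
    ----------
    observed_mean_diff : array-like
        Observed payout-mean difference, option 1 minus option 2, in points.
    info_indicator, repeat_indicator, side_indicator : array-like
        +1 if option 1 is the high-information / previously chosen / left
        option, -1 otherwise.
    horizon : str, optional
        Horizon condition used to resolve per-horizon parameter overrides.

    Returns
    -------
    Probability (same shape as the broadcast inputs) of choosing option 1,
    strictly inside (0, 1) for sigma > 0.  With sigma = 0 the choice is
    greedy and an exactly tied decision variable yields probability 0.5.
    """
    a, b, sigma, k = params.for_horizon(horizon)
    dv = (np.asarray(observed_mean_diff, dtype=float)
          + a * np.asarray(info_indicator, dtype=float)
          + b * np.asarray(side_indicator, dtype=float)
          + k * np.asarray(repeat_indicator, dtype=float))
    if sigma == 0:
        return np.where(dv > 0, 1.0, np.where(dv < 0, 0.0, 0.5))[()]
    return expit(dv / sigma)[()]


def act_horizon(params: HorizonAgentParams, game_history, rng,
                horizon: str | None = None) -> str:
    """Sample the next free choice given the history of observed payouts.

    ``game_history`` is a sequence of (choice, payout) pairs for the trials
    played so far in the current game — forced and free alike.  Only payouts
    of chosen bandits appear in the history, so the agent can never condition
    on unobserved outcomes.  The previous option for the repeat bonus is the
    choice on the immediately preceding trial.
    """
    if len(game_history) < 4:
        raise ValueError("history must contain at least the four forced trials")
    payouts = {"left": [], "right": []}
    for choice, payout in game_history:
        if choice not in payouts:
            raise ValueError(f"invalid choice in history: {choice!r}")
        payouts[choice].append(payout)
    n_left, n_right = len(payouts["left"]), len(payouts["right"])
    if min(n_left, n_right) == 0:
        raise ValueError("both bandits must have been sampled during forced trials")
    mean_left = float(np.mean(payouts["left"]))
    mean_right = float(np.mean(payouts["right"]))
    # the high-information option is the one sampled fewer times
    info_ind = 1.0 if n_left < n_right else (-1.0 if n_right < n_left else 0.0)
    prev = game_history[-1][0]
    rep_ind = 1.0 if prev == "left" else -1.0
    p_left = horizon_choice_prob(params, mean_left - mean_right, info_ind,
                                 rep_ind, side_indicator=1.0, horizon=horizon)
    return "left" if rng.random() < p_left else "right"


def act_foraging(params: ForagingAgentParams, expected_next_yield: float,
                 rng, environment: str = "rich") -> str:
    """Harvest-or-leave decision given the expected yield of one more harvest.

    Returns ``"leave"`` iff the expected next yield falls below the agent's
    cutoff plus a Gaussian noise draw; otherwise ``"harvest"``.
    """
    cutoff = params.cutoff(environment)
    if params.threshold_noise_sd > 0:
        cutoff = cutoff + params.threshold_noise_sd * rng.standard_normal()
    return "leave" if expected_next_yield < cutoff else "harvest"
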