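import numpy as np
import pandas as pd
import pytest

from exploresim.agents import HorizonAgentParams
from exploresim.horizon import generate_schedule


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def greedy_agent():
    """Deterministic value-maximizer: no bonuses, no noise."""
    return HorizonAgentParams(info_bonus=0.0, spatial_bias=0.0,
                              decision_noise=0.0, repeat_bonus=0.0)


@pytest.fixture
def noisy_agent():
    return HorizonAgentParams(info_bonus=4.0, spatial_bias=0.0,
                              decision_noise=8.0, repeat_bonus=1.0)


def make_horizon_game(game_id=1, horizon="short", info="left",
                      forced=("right", "left", "right", "right"),
                      payouts=(50, 42, 44, 40), free_choices=("left",),
                      free_payouts=(55,), participant_id="p0",
                      mu_left=60.0, mu_right=40.0):
    """Hand-built tidy trial log for one game."""
    rows = []
    for i, (c, p) in enumerate(zip(forced, payouts), start=1):
        rows.append((participant_id, game_id, horizon, i, "forced", c, p,
                     mu_left, mu_right, info))
    for j, (c, p) in enumerate(zip(free_choices, free_payouts), start=5):
        rows.append((participant_id, game_id, horizon, j, "free", c, p,
                     mu_left, mu_right, info))
    return pd.DataFrame(rows, columns=[
        "participant_id", "game_id", "horizon", "trial_index", "phase",
        "choice", "payout", "mu_left", "mu_right", "info_bandit"])
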