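import numpy as np
import pandas as pd
import pytest

from striatd import rl_agents
from striatd.task_env import CONDITIONS


def toy_trials(rows):
    """Build a minimal trial table from (cue_location, cue_frequency, choice, correct)."""
    df = pd.DataFrame(rows, columns=["cue_location", "cue_frequency", "choice", "correct"])
    df["r"] = np.where(df["correct"], 1.0, -1.0)
    return df


@pytest.fixture(scope="session")
def location_protocol():
    """5 SARSA partial-reset agents trained on the location rule."""
    params = rl_agents.AgentParams(algorithm="sarsa", reset_mode="partial")
    return rl_agents.run_protocol(params, rule_sequence=("location",), n_agents=5,
                                  max_sessions=30, seed=101)


@pytest.fixture(scope="session")
def two_rule_protocol():
    """One SARSA partial-reset agent through location then frequency."""
    params = rl_agents.AgentParams(algorithm="sarsa", reset_mode="partial")
    return rl_agents.run_protocol(params, rule_sequence=("location", "frequency"),
                                  n_agents=1, max_sessions=40, seed=7)
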