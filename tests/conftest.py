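import numpy as np
import pandas as pd
import pytest

from neurodisc import (
    BehaviorParams,
    UnitParams,
    simulate_fra_protocol,
    simulate_session,
)


@pytest.fixture(scope="session")
def task_session():
    """Mid-size task session with planted behavior and a choice signal."""
    bp = BehaviorParams(n_trials=400, d_easy=1.0, d_hard=1.0, c_bias=-0.5)
    up = UnitParams(n_units=4, choice_gain=25.0, choice_onset=0.15)
    session, truth = simulate_session(bp, up, seed=42)
    return session, truth


@pytest.fixture(scope="session")
def fra_session():
    """Passive pure-tone session with a unit tuned near 10 kHz."""
    up = UnitParams(
        n_units=3, evoked_gain=30.0, bf_log2=np.log2(10.0), tuning_sd_oct=0.3
    )
    return simulate_fra_protocol(up, seed=7)


def make_trials(outcomes, tasks=None, onset_gap=7.0, freq=7070.0):
    """Minimal classified trial table from a list of outcome labels."""
    n = len(outcomes)
    tasks = tasks or ["easy"] * n
    cats = {"hit": "go", "miss": "go", "fa": "nogo", "cr": "nogo", "probe": "probe"}
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "t_onset": 5.0 + onset_gap * np.arange(n),
            "freq": freq,
            "level": 72.0,
            "category": [cats[o] for o in outcomes],
            "task": tasks,
            "tone_dur": 0.1,
            "outcome": outcomes,
            "lick_count": [5 if o in ("hit", "fa") else 0 for o in outcomes],
            "first_lick_latency": np.nan,
        }
    )
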