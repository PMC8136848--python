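"""Shared fixtures.

The closed-loop behavioral checks share two trained agents (head-roll
std 0 and 30 deg) under the scaled-down profile: 64-unit GASSOMs, 1000
training episodes (20000 closed-loop iterations) per condition, one
fixed training seed.  Training them once per session keeps the whole
battery affordable; the behavioral comparisons then take medians over
independent evaluation seeds.
"""

import pytest

TRAIN_EPISODES = 1000
FIXTURE_SEED = 0
SIGMA_CONDITIONS = (0.0, 30.0)


@pytest.fixture(scope="session")
def trained_conditions():
    """Agents trained under sigma_roll = 0 and 30 deg (scaled profile)."""
    from echoroll import experiment

    states = {}
    for sigma in SIGMA_CONDITIONS:
        state = experiment.init_agent(
            "ci", seed=FIXTURE_SEED, total_steps=TRAIN_EPISODES * 20
        )
        state, _ = experiment.train(
            TRAIN_EPISODES, sigma, seed=FIXTURE_SEED, state=state
        )
        states[sigma] = state
    return states
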