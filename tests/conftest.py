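import numpy as np
import pytest

from watermaze import (
    LearningParams,
    SwimParams,
    make_default_arena,
)
from watermaze.learning import run_training


@pytest.fixture(scope="session")
def arena():
    return make_default_arena()


@pytest.fixture(scope="session")
def swim():
    return SwimParams()


@pytest.fixture(scope="session")
def learning_params():
    return LearningParams()


@pytest.fixture(scope="session")
def trained_state(arena, learning_params):
    """Final state after the standard 40-trial protocol, equal cues."""
    return run_training(arena, learning_params, arena.n_trials())[-1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
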