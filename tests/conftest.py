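import numpy as np
import pytest

from cyberslug.arena import ArenaConfig, init_arena
from cyberslug.constants import DEFAULT_CONSTANTS


@pytest.fixture
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arena():
    """A small mixed arena for fast world-level tests."""
    return ArenaConfig(width=30, height=30, n_flab=4, n_hermi=2, seed=7)


@pytest.fixture
def empty_arena():
    return ArenaConfig(width=30, height=30, n_flab=0, n_hermi=0, seed=7)


@pytest.fixture
def world(small_arena):
    return init_arena(small_arena)
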