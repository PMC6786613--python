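import sys
from pathlib import Path

import pytest

from herdnet import SimParams

# make the naive reference engine importable from any test module
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def defaults() -> SimParams:
    return SimParams()


@pytest.fixture
def small() -> SimParams:
    """A small, fast configuration for engine unit tests."""
    return SimParams(
        n_households=20,
        carrying_capacity=5_000.0,
        disaster_prob=0.10,
        n_steps=50,
    )
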