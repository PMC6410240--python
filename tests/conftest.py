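import numpy as np
import pytest

from mtna import simulate


@pytest.fixture(scope="session")
def refs():
    """Standard 49/41-flank, 49-bp indel reference pair."""
    return simulate.make_references(49, 41, 49, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def fast_config():
    """Small, single-end read-simulation settings for quick cohort tests."""
    return simulate.SimConfig(
        seed=5, coverage=20, error_rate=0.0, p_del=0.3, paired=False
    )
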