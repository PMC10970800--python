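import numpy as np
import pytest

from rirsr import DegradationSpec, ModelConfig, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_192():
    """One 192x192 phantom shared across read-only tests."""
    return generate_phantom(PhantomSpec(height=192, width=192, seed=7))


@pytest.fixture(scope="session")
def phantom_128():
    return generate_phantom(PhantomSpec(height=128, width=128, seed=11))


@pytest.fixture
def tiny_cfg():
    """Smallest architecture that still exercises every component."""
    return ModelConfig(n_groups=2, n_blocks_per_group=2, n_filters=16,
                       scale=4, seed=3)


@pytest.fixture
def spec_x4():
    return DegradationSpec(scale=4)
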