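import numpy as np
import pytest

from glomil.experiments import desk_config
from glomil.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Small-network configuration used by model-level tests."""
    return desk_config(seed=0, epochs=2, tta_count=2)


@pytest.fixture
def phantom_sample(rng):
    return generate_phantom(PhantomSpec(), rng, force_counts=(1, 1))


@pytest.fixture
def default_spec():
    return PhantomSpec()
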