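import numpy as np
import pytest

from quadbird import GeneratorConfig, generate_community


@pytest.fixture(scope="session")
def community():
    """One default synthetic community shared across read-only tests."""
    return generate_community(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def null_community():
    """A site-equivalent (unfiltered) world."""
    return generate_community(GeneratorConfig(seed=123, filtering_strength=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
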