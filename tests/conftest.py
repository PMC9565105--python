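import numpy as np
import pytest

from vegdyn import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """One default 25x20x21 scenario shared by read-only tests."""
    return generate_scenario(ScenarioConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
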