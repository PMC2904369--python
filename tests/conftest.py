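import numpy as np
import pytest

from iqtlmap.simulate import SimulationScenario, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """A modest Scenario-I cross reused by fit- and scan-level tests."""
    sc = SimulationScenario.reference("I", n_per_family=150, h2=0.4)
    return simulate_cross(sc, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
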