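import numpy as np
import pytest
from hypothesis import settings

import activesim as asim

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def metabolic():
    return asim.MetabolicParams()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario: 2,000 agents, 1 year, 2 replicates."""
    return asim.ScenarioConfig(
        population=asim.PopulationSpec(n_agents=2000, seed=11),
        horizon_years=1,
        replicates=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return asim.build_world(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
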