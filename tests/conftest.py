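import numpy as np
import pytest

from rdfselect import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=60,
        n_planted=8,
        n_decoy=4,
        n_cases_per_group=15,
        n_controls_per_group=15,
        effect_size=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
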