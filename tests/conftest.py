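import numpy as np
import pytest

from smartscan.data_model import disease_progress
from smartscan.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down study: 16 pairs, 24 variables, 5-variable panel."""
    return GeneratorConfig(
        n_pairs=16, n_variables=24, panel_size=5, effect_size=2.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    table, truth = generate_cohort(small_config)
    return table, truth


@pytest.fixture(scope="session")
def small_cohort(small_table):
    table, truth = small_table
    return disease_progress(table), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
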