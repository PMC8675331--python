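import numpy as np
import pytest

import methylink as ml


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config for fast unit tests."""
    return ml.SimulationConfig(
        seed=11,
        chromosomes={"chr1": 120_000, "chr2": 120_000, "chrW": 120_000},
        n_genes=30,
        n_planted_dmrs=10,
        module_sizes=(10, 10),
        trait_coupling=(0.9, -0.45),
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return ml.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_methylomes(small_config, small_annotation):
    return {
        g: ml.simulate_methylome(small_config, small_annotation, g)
        for g in small_config.groups
    }


@pytest.fixture(scope="session")
def small_expression(small_config, small_annotation):
    return ml.simulate_expression(small_config, small_annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
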