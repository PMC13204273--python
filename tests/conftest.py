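import numpy as np
import pandas as pd
import pytest

from convergene.synthetic import GeneratorConfig, generate_bulk, make_truth


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale study: 300 genes, 40/group, clear planted signal."""
    return GeneratorConfig(
        n_genes=300, n_samples_per_group=40, n_de_genes=60,
        n_sc_de_genes=40, n_cells_per_donor=400, seed=101,
    )


@pytest.fixture(scope="session")
def small_bulk(small_config):
    return generate_bulk(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_samples():
    """Eight-sample covariate table with both groups and two batches."""
    return pd.DataFrame(
        {
            "group": ["case"] * 4 + ["control"] * 4,
            "age": [70.0, 75.0, 80.0, 68.0, 72.0, 74.0, 78.0, 81.0],
            "sex": [0, 1, 1, 0, 1, 0, 0, 1],
            "apoe4": [1, 1, 0, 1, 0, 0, 1, 0],
            "batch": ["B1", "B2", "B1", "B2", "B1", "B2", "B1", "B2"],
        },
        index=[f"S{i}" for i in range(1, 9)],
    )
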