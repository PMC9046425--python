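import numpy as np
import pandas as pd
import pytest

from coexnet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort: 200 genes, 3 planted modules, quick to generate."""
    return SimulationConfig(
        n_genes=200,
        n_cases=20,
        n_controls=40,
        module_sizes=(40, 30, 30),
        eigengene_trait_cor=(0.5, 0.0, 0.0),
        n_outliers=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition cohort (~880 genes, 22 vs 44 samples, 2 outliers)."""
    return simulate_dataset(SimulationConfig(seed=5))


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric adjacency in [0, 1] with unit diagonal."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
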