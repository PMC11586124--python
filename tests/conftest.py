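import numpy as np
import pytest

from spatialcci import generate_tissue, standardize


@pytest.fixture(scope="session")
def small_tissue():
    """Tiny tissue for structural tests (fast)."""
    return generate_tissue(n_cells=30, n_genes=8, n_communities=2,
                           n_neighbors=3, seed=11)


@pytest.fixture(scope="session")
def benchmark_tissue():
    """The default 200-cell / 50-gene / 4-community benchmark fixture."""
    return generate_tissue(seed=0)


@pytest.fixture(scope="session")
def benchmark_features(benchmark_tissue):
    return standardize(benchmark_tissue.expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
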