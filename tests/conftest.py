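import numpy as np
import pytest

from pathdens import build_graph, run_mca, simulate_scrnaseq


@pytest.fixture(scope="session")
def small_dataset():
    """Shared planted-marker dataset: 3 types x 120 cells, 400 genes, 65% zeros."""
    return simulate_scrnaseq(
        n_types=3,
        cells_per_type=120,
        n_genes=400,
        markers_per_type=25,
        target_sparsity=0.65,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_embedding(small_dataset):
    return run_mca(small_dataset.expression, n_dims=20)


@pytest.fixture(scope="session")
def small_graph(small_embedding):
    return build_graph(small_embedding, k=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
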