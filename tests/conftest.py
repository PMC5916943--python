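import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meiodecay.io import CountMatrix
from meiodecay.synthetic import SimulationConfig, _model_for, generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One default synthetic dataset, shared across the session."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def default_model(default_config):
    return _model_for(default_config)


@pytest.fixture(scope="session")
def marker_panel_symbols(default_model):
    return tuple(default_model.marker_table().symbols())


@pytest.fixture(scope="session")
def seeded_datasets():
    """Datasets for seeds 0..9, generated lazily and cached."""
    cache = {}

    def get(seed):
        if seed not in cache:
            cache[seed] = generate_dataset(SimulationConfig(seed=seed))
        return cache[seed]

    return get


def make_matrix(counts, chromosomes=None, symbols=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if chromosomes is None:
        chromosomes = [str(j % 19 + 1) for j in range(n_genes)]
    if symbols is None:
        symbols = [f"G{j}" for j in range(n_genes)]
    genes = pd.DataFrame({
        "gene_id": [f"ID{j}" for j in range(n_genes)],
        "symbol": symbols,
        "chromosome": chromosomes,
    })
    return CountMatrix(
        barcodes=[f"BC{i}" for i in range(n_cells)],
        genes=genes,
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def tiny_matrix():
    """6 cells x 4 genes with a Y gene and an X gene."""
    counts = np.array([
        [5, 0, 2, 1],
        [3, 1, 0, 2],
        [4, 2, 1, 0],
        [6, 0, 3, 1],
        [2, 1, 1, 1],
        [5, 3, 0, 2],
    ])
    return make_matrix(counts, chromosomes=["1", "X", "Y", "2"])
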