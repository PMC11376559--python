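import numpy as np
import pytest
import scipy.sparse as sp

import mvst
from mvst.types import ViewGraph


@pytest.fixture(scope="session")
def tiny_section():
    """12x12-grid, 3-domain section small enough for fast unit tests."""
    spec = mvst.SyntheticSpec(n_rows=12, n_cols=12, n_genes=80,
                              n_marker_genes_per_domain=20, seed=7)
    section, truth = mvst.generate_section(spec)
    return section, truth


@pytest.fixture(scope="session")
def tiny_features(tiny_section):
    section, _ = tiny_section
    return mvst.preprocess(section, n_hvg=60, n_pcs=30, seed=0)


def graph_from_dense(adj: np.ndarray, view_name: str = "spatial",
                     k: int = 1) -> ViewGraph:
    return ViewGraph(sp.csr_matrix(np.asarray(adj, dtype=float)), view_name, k)


@pytest.fixture
def path_graph_2():
    """Two nodes joined by one edge."""
    return graph_from_dense([[0, 1], [1, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
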