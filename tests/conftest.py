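import numpy as np
import pytest

from netimpute import ExpressionMatrix, GeneModel, RegulatoryNetwork


def make_matrix(values, scale="log2", prefix=("g", "c")) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix[0]}{i}" for i in range(values.shape[0])]
    cells = [f"{prefix[1]}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, scale)


def random_sparse_matrix(rng, n_genes=25, n_cells=30, zero_fraction=0.3,
                         scale="log2") -> ExpressionMatrix:
    """Non-negative matrix with a controlled share of exact zeros."""
    values = rng.uniform(0.5, 8.0, size=(n_genes, n_cells))
    values[rng.random((n_genes, n_cells)) < zero_fraction] = 0.0
    return make_matrix(values, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def chain_network() -> RegulatoryNetwork:
    """g1 <- 0.5*g3, g2 <- 0.5*g1; g3 is a source gene without a model."""
    return RegulatoryNetwork(
        {
            "g1": GeneModel("g1", {"g3": 0.5}),
            "g2": GeneModel("g2", {"g1": 0.5}),
            "g3": GeneModel("g3"),
        },
        ["g1", "g2", "g3"],
    )
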