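import numpy as np
import pytest

from pgagp import (
    AssociationTable,
    HeterogeneousNetwork,
    LayerGraph,
    NodeIndex,
    default_fixture,
)


@pytest.fixture(scope="session")
def fixture_network():
    """The seeded 140-node planted-structure network used across the suite."""
    return default_fixture()


@pytest.fixture
def toy_network():
    """Tiny hand-checkable heterogeneous network: 2 diseases, 3 genes.

    Disease layer: d0-d1 edge.  Gene layer: g0-g1, g1-g2 edges.
    Associations: d0-g0, d0-g1, d1-g2.
    """
    d_idx = NodeIndex(["d0", "d1"])
    g_idx = NodeIndex(["g0", "g1", "g2"])
    A_D = np.array([[0.0, 1.0], [1.0, 0.0]])
    A_G = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    R = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return HeterogeneousNetwork(
        LayerGraph(A_D, d_idx),
        LayerGraph(A_G, g_idx),
        AssociationTable(R, d_idx, g_idx),
    )


def random_symmetric_graph(rng: np.random.Generator, n: int, density: float = 0.3,
                           weighted: bool = False) -> np.ndarray:
    """Random symmetric non-negative adjacency with zero diagonal."""
    upper = np.triu(rng.random((n, n)) < density, k=1).astype(float)
    if weighted:
        upper *= rng.uniform(0.1, 2.0, size=(n, n))
    return upper + upper.T
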