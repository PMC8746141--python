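import numpy as np
import pytest

from braidkit import (
    Connectome,
    RegionPartition,
    WeightMatrix,
    build_laplacian,
    build_weight_matrix,
    four_node_example,
)


@pytest.fixture(scope="session")
def four_node():
    """(connectome, DW weights, singleton partition, dynamics params)."""
    return four_node_example()


@pytest.fixture(scope="session")
def four_node_laplacian(four_node):
    return build_laplacian(four_node[1])


@pytest.fixture
def p3_weights():
    """Path graph on 3 nodes with unit weights: degrees (1, 2, 1)."""
    conn = Connectome(["a", "b", "c"], {(0, 1): (1.0, 20.0), (1, 2): (1.0, 20.0)})
    return build_weight_matrix(conn, "LW")


@pytest.fixture
def star4():
    """K_{1,4} star with one dominant spoke (hub = node 0)."""
    edges = {(0, k): (1.0, 20.0) for k in range(1, 5)}
    edges[(0, 1)] = (100.0, 20.0)
    return Connectome([f"n{k}" for k in range(5)], edges)


def chunk_partition(n_nodes: int, n_regions: int) -> RegionPartition:
    """Contiguous near-equal chunks of 0..n_nodes-1 as staging regions."""
    bounds = np.linspace(0, n_nodes, n_regions + 1).astype(int)
    return RegionPartition.from_node_sets(
        [range(bounds[k], bounds[k + 1]) for k in range(n_regions)]
    )


def weight_matrix_from_dense(values) -> WeightMatrix:
    return WeightMatrix(np.asarray(values, dtype=float), "LW")
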