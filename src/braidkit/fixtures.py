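"""Deterministic fixtures: the four-node worked example and synthetic graphs.

The four-node example is the smallest network on which braid diagrams show
nontrivial staging.  Its DW weight matrix is (row/column order 1..4):

    W = [[0,        3.125e-7, 5e-6,   0      ],
         [3.125e-7, 0,        0,      1e-5   ],
         [5e-6,     0,        0,      1.5e-4 ],
         [0,        1e-5,     1.5e-4, 0      ]]

with edge lengths l_12 = 40 and all others 20.  Fiber counts are
back-computed from W under the diffusive scheme (n = W * l**2) so the same
fixture also has well-defined LW and BW variants.  The dynamics use
ln(beta) = 3.897, total seed mass 0.005 placed at node 1 (region I), and
singleton staging regions I..IV.  Everything here is deterministic or fully
determined by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import Connectome, WeightMatrix, build_weight_matrix
from .dynamics import DynamicsParams
from .regions import RegionPartition

__all__ = [
    "FOUR_NODE_LN_BETA",
    "FixtureSpec",
    "four_node_example",
    "random_connectome",
]

FOUR_NODE_LN_BETA = 3.897

# (i, j, W_ij under DW, length); fiber counts follow as n = W * l**2
_FOUR_NODE_EDGES = (
    (0, 1, 3.125e-7, 40.0),
    (0, 2, 5.0e-6, 20.0),
    (1, 3, 1.0e-5, 20.0),
    (2, 3, 1.5e-4, 20.0),
)


def four_node_example() -> tuple[Connectome, WeightMatrix, RegionPartition, DynamicsParams]:
    """The four-node worked example (connectome, DW weights, regions, params)."""
    edges = {
        (i, j): (w * l**2, l) for i, j, w, l in _FOUR_NODE_EDGES
    }
    connectome = Connectome([f"node{k + 1}" for k in range(4)], edges)
    weights = build_weight_matrix(connectome, "DW")
    partition = RegionPartition.singletons(4)
    params = DynamicsParams.from_ln_beta(FOUR_NODE_LN_BETA, delta=1.0, seed_mass=0.005, seed_region=0)
    return connectome, weights, partition, params


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic connectome; the seed fully determines output.

    ``kind`` is one of ``four_node``, ``random_geometric``, ``regular_ring``
    or ``star``.  ``degree`` applies to the regular ring (must be even);
    ``radius`` to the geometric graph (grown automatically until connected).
    """

    kind: str = "random_geometric"
    size: int = 20
    degree: int = 4
    radius: float = 0.35
    seed: int = 0


def _attach_edge_data(g: nx.Graph, rng: np.random.Generator, random_weights: bool) -> Connectome:
    nodes = sorted(g.nodes)
    index = {v: k for k, v in enumerate(nodes)}
    edges = {}
    for u, v in sorted(g.edges()):
        i, j = sorted((index[u], index[v]))
        if random_weights:
            n = float(rng.lognormal(mean=3.0, sigma=1.0))
            l = float(rng.uniform(10.0, 120.0))
        else:
            n, l = 1.0, 20.0
        edges[(i, j)] = (n, l)
    return Connectome([f"node{k}" for k in range(len(nodes))], edges)


def random_connectome(spec: FixtureSpec) -> Connectome:
    """Generate a connected synthetic connectome from a fixture spec.

    Fiber counts are lognormal (heavy-tailed, like tractography counts) and
    lengths uniform on 10-120 mm, except for the regular ring, which uses
    constant unit counts and equal lengths so its weighted degrees are
    exactly equal (the case where every Laplacian in the family is
    admissible).
    """
    if spec.kind == "four_node":
        return four_node_example()[0]
    if spec.size < 2:
        raise ValueError("size must be >= 2")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "regular_ring":
        if spec.degree % 2 or spec.degree <= 0 or spec.degree >= spec.size:
            raise ValueError("regular_ring needs an even degree in (0, size)")
        g = nx.circulant_graph(spec.size, list(range(1, spec.degree // 2 + 1)))
        return _attach_edge_data(g, rng, random_weights=False)
    if spec.kind == "star":
        g = nx.star_graph(spec.size - 1)
        return _attach_edge_data(g, rng, random_weights=True)
    if spec.kind == "random_geometric":
        radius = spec.radius
        for _ in range(60):
            g = nx.random_geometric_graph(
                spec.size, radius, seed=int(rng.integers(0, 2**31 - 1))
            )
            if nx.is_connected(g):
                return _attach_edge_data(g, rng, random_weights=True)
            radius = min(1.5, radius * 1.15)
        raise RuntimeError(f"could not generate a connected geometric graph for {spec}")
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
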