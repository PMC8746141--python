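"""Weighted structural connectomes and the parametrized graph-Laplacian family.

A connectome is an undirected graph whose nodes are anatomical regions of
interest and whose edges carry two tractography-derived quantities: the fiber
count ``n_ij`` (dimensionless) and the mean fiber length ``l_ij`` (mm).  From
these, three edge-weighting schemes in common use are built:

========  =================  =========================================
scheme    W_ij               interpretation
========  =================  =========================================
LW        n_ij               length-free (pure count)
BW        n_ij / l_ij        ballistic (signal travels at fixed speed)
DW        n_ij / l_ij**2     diffusive (Fickian transport along fibers)
========  =================  =========================================

The graph Laplacian acting on node concentrations is drawn from the
two-parameter family

    L_{a,b} = D**(1-a-b) - D**(-a) W D**(-b),    a, b in [0, 1], a + b <= 1,

where ``D`` is the diagonal strength matrix ``D_ii = sum_j W_ij``.  The choice
(0, 0) is the standard Laplacian ``D - W``; (1/2, 1/2) is the symmetric
normalized Laplacian.  Two physical transport axioms single out (0, 0) on any
graph with heterogeneous degrees:

* mass conservation — transport neither creates nor destroys material,
  equivalently the left null-vector condition ``1 . L = 0`` (zero column sums);
* Fick's condition — equal concentrations drive no flux, equivalently the
  right null-vector condition ``L . 1 = 0`` (zero row sums).

On a d-regular (equal-strength) graph every member of the family satisfies
both conditions, so regularity is the degenerate case in which normalization
is harmless.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Connectome",
    "WeightMatrix",
    "Laplacian",
    "ConditionReport",
    "InvalidInputError",
    "DegenerateDegreeError",
    "WEIGHT_SCHEMES",
    "build_weight_matrix",
    "build_laplacian",
    "check_mass_conservation",
    "check_ficks_condition",
    "laplacian_condition_scan",
    "threshold_naive",
    "threshold_disparity",
    "register_backbone_filter",
    "apply_backbone_filter",
    "BACKBONE_FILTERS",
]

logger = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("LW", "BW", "DW")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateDegreeError(InvalidInputError):
    """Raised when a Laplacian requires a negative power of a zero degree."""


@dataclass
class Connectome:
    """Undirected weighted connectome.

    Parameters
    ----------
    node_labels
        Anatomical label per node; the node index (0-based position) is the
        internal identifier used everywhere else.
    edges
        Mapping ``(i, j) -> (n, l)`` with ``i < j``; ``n`` is the fiber count
        (>= 0) and ``l`` the fiber length in mm (> 0).
    """

    node_labels: list[str]
    edges: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_nodes = len(self.node_labels)
        canon: dict[tuple[int, int], tuple[float, float]] = {}
        for (i, j), (n, l) in self.edges.items():
            if i == j:
                raise InvalidInputError(f"self-loop on node {i} is not allowed")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise InvalidInputError(f"edge ({i},{j}) references unknown node")
            key = (min(i, j), max(i, j))
            if key in canon:
                raise InvalidInputError(f"duplicate edge {key}")
            if n < 0:
                raise InvalidInputError(f"edge {key}: fiber count {n} < 0")
            if l <= 0:
                raise InvalidInputError(f"edge {key}: fiber length {l} <= 0")
            canon[key] = (float(n), float(l))
        self.edges = canon

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Unweighted degree of each node."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edge_records(
        cls,
        node_labels: Sequence[str],
        records: Iterable[tuple[int, int, float, float]],
    ) -> "Connectome":
        """Build from possibly directed/duplicated ``(i, j, n, l)`` records.

        Asymmetric pairs are symmetrized as the arithmetic mean of the two
        directions (the model assumes an undirected network); self-loops are
        dropped.  Both events are logged.
        """
        seen: dict[tuple[int, int], list[tuple[float, float]]] = {}
        n_loops = 0
        for i, j, n, l in records:
            i, j = int(i), int(j)
            if i == j:
                n_loops += 1
                continue
            seen.setdefault((min(i, j), max(i, j)), []).append((float(n), float(l)))
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop(s) from input", stacklevel=2)
        edges = {}
        n_asym = 0
        for key, vals in seen.items():
            if len(vals) > 2:
                raise InvalidInputError(f"edge {key} appears {len(vals)} times")
            if len(vals) == 2 and vals[0] != vals[1]:
                n_asym += 1
            n = float(np.mean([v[0] for v in vals]))
            l = float(np.mean([v[1] for v in vals]))
            edges[key] = (n, l)
        if n_asym:
            logger.info("symmetrized %d asymmetric edge pair(s) by averaging", n_asym)
        return cls(list(node_labels), edges)

    def with_edges(self, edges: dict[tuple[int, int], tuple[float, float]]) -> "Connectome":
        """Copy with a different edge set (same nodes)."""
        return Connectome(list(self.node_labels), dict(edges))

    # -- interchange -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, label in enumerate(self.node_labels):
            g.add_node(idx, label=label)
        for (i, j), (n, l) in self.edges.items():
            g.add_edge(i, j, n=n, l=l)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Connectome":
        nodes = sorted(g.nodes)
        index = {v: k for k, v in enumerate(nodes)}
        labels = [str(g.nodes[v].get("label", v)) for v in nodes]
        records = [
            (index[u], index[v], float(d["n"]), float(d["l"]))
            for u, v, d in g.edges(data=True)
        ]
        return cls.from_edge_records(labels, records)

    def write_csv(self, edge_path, node_path=None) -> None:
        """Write the standard edge list (header ``i,j,n,l``) and node table."""
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["i", "j", "n", "l"])
            for (i, j), (n, l) in sorted(self.edges.items()):
                w.writerow([i, j, repr(n), repr(l)])
        if node_path is not None:
            with open(node_path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["id", "label"])
                for idx, label in enumerate(self.node_labels):
                    w.writerow([idx, label])

    @classmethod
    def read_csv(cls, edge_path, node_path=None) -> "Connectome":
        records = []
        max_idx = -1
        with open(edge_path, newline="") as fh:
            for row in csv.DictReader(fh):
                i, j = int(row["i"]), int(row["j"])
                records.append((i, j, float(row["n"]), float(row["l"])))
                max_idx = max(max_idx, i, j)
        if node_path is not None:
            labels_by_id = {}
            with open(node_path, newline="") as fh:
                for row in csv.DictReader(fh):
                    labels_by_id[int(row["id"])] = row["label"]
            n_nodes = max(max(labels_by_id, default=-1), max_idx) + 1
            labels = [labels_by_id.get(k, str(k)) for k in range(n_nodes)]
        else:
            labels = [str(k) for k in range(max_idx + 1)]
        return cls.from_edge_records(labels, records)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "Connectome":
        return cls.from_networkx(nx.read_graphml(path))


@dataclass
class WeightMatrix:
    """Symmetric nonnegative adjacency weights for one scheme (LW/BW/DW)."""

    values: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def strengths(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def write_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


@dataclass
class Laplacian:
    """A member L_{a,b} of the parametrized graph-Laplacian family."""

    values: np.ndarray
    a: float
    b: float
    degree: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def params(self) -> tuple[float, float]:
        return (self.a, self.b)

    def write_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


class ConditionReport(NamedTuple):
    """Outcome of a transport-axiom check on a Laplacian."""

    ok: bool
    max_violation: float


def build_weight_matrix(connectome: Connectome, scheme: str) -> WeightMatrix:
    """Assemble the N x N weight matrix for one of the LW/BW/DW schemes.

    LW uses the raw fiber count, BW divides by fiber length, DW by its square.
    Raises :class:`InvalidInputError` if a length-dependent scheme meets a
    nonpositive length (cannot happen for a validated :class:`Connectome`,
    but the check names the offending edge for raw matrices).
    """
    if scheme not in WEIGHT_SCHEMES:
        raise InvalidInputError(f"unknown weighting scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")
    n_nodes = connectome.n_nodes
    w = np.zeros((n_nodes, n_nodes), dtype=float)
    for (i, j), (n, l) in connectome.edges.items():
        if scheme in ("BW", "DW") and l <= 0:
            raise InvalidInputError(f"edge ({i},{j}): length {l} <= 0 invalid for scheme {scheme}")
        if scheme == "LW":
            wij = n
        elif scheme == "BW":
            wij = n / l
        else:
            wij = n / l**2
        w[i, j] = w[j, i] = wij
    return WeightMatrix(w, scheme)


def _degree_power(degree: np.ndarray, exponent: float) -> np.ndarray:
    if exponent == 0:
        return np.ones_like(degree)
    if exponent < 0 and np.any(degree <= 0):
        bad = int(np.argmin(degree))
        raise DegenerateDegreeError(
            f"node {bad} has degree {degree[bad]}: cannot raise to power {exponent}"
        )
    return degree**exponent


def build_laplacian(weights: WeightMatrix, a: float = 0.0, b: float = 0.0) -> Laplacian:
    """Build L_{a,b} = D^(1-a-b) - D^(-a) W D^(-b).

    The parameters must satisfy ``a, b in [0, 1]`` and ``a + b <= 1``.  For
    (0, 0) this is the standard Laplacian ``D - W`` and isolated nodes are
    allowed; any other member requires strictly positive strengths.
    """
    if not (0 <= a <= 1 and 0 <= b <= 1 and a + b <= 1 + 1e-12):
        raise InvalidInputError(f"(a, b) = ({a}, {b}) outside the admissible region")
    w = weights.values
    if not np.allclose(w, w.T, atol=1e-12):
        raise InvalidInputError("weight matrix must be symmetric")
    degree = w.sum(axis=1)
    if a == 0 and b == 0:
        values = np.diag(degree) - w
    else:
        diag = _degree_power(degree, 1.0 - a - b)
        da = _degree_power(degree, -a)
        db = _degree_power(degree, -b)
        values = np.diag(diag) - da[:, None] * w * db[None, :]
    return Laplacian(values, float(a), float(b), degree)


def _scaled_violation(sums: np.ndarray, values: np.ndarray) -> float:
    scale = np.max(np.abs(values))
    if scale == 0:
        return float(np.max(np.abs(sums))) if sums.size else 0.0
    return float(np.max(np.abs(sums)) / scale)


def check_mass_conservation(laplacian: Laplacian, tol: float = 1e-10) -> ConditionReport:
    """Check the left null-vector condition 1 . L = 0 (zero column sums).

    The violation is the largest absolute column sum scaled by max|L|, so the
    verdict is invariant under rescaling the weights.
    """
    viol = _scaled_violation(laplacian.values.sum(axis=0), laplacian.values)
    return ConditionReport(viol <= tol, viol)


def check_ficks_condition(laplacian: Laplacian, tol: float = 1e-10) -> ConditionReport:
    """Check the right null-vector condition L . 1 = 0 (zero row sums)."""
    viol = _scaled_violation(laplacian.values.sum(axis=1), laplacian.values)
    return ConditionReport(viol <= tol, viol)


def laplacian_condition_scan(
    weights: WeightMatrix,
    grid: Iterable[tuple[float, float]],
    tol: float = 1e-10,
) -> list[tuple[float, float]]:
    """Return the grid points (a, b) whose L_{a,b} passes both transport axioms.

    Grid points outside the admissible region ``a + b <= 1`` are skipped; a
    degenerate degree (isolated node with a normalized member) counts as a
    failure.  On a degree-heterogeneous graph the surviving set is {(0, 0)}
    whenever the grid contains it; on an equal-strength (regular) graph every
    admissible point survives.
    """
    passing = []
    for a, b in grid:
        if a + b > 1 + 1e-12:
            continue
        try:
            lap = build_laplacian(weights, a, b)
        except DegenerateDegreeError:
            continue
        if check_mass_conservation(lap, tol).ok and check_ficks_condition(lap, tol).ok:
            passing.append((float(a), float(b)))
    return passing


# -- backbone thresholding -------------------------------------------------

def threshold_naive(connectome: Connectome, cutoff: float) -> Connectome:
    """Remove every edge whose fiber count falls below ``cutoff``.

    Nodes are retained even if isolated.  If the surviving graph is
    disconnected, a warning reporting the component count is emitted.
    """
    if cutoff < 0:
        raise InvalidInputError(f"cutoff must be >= 0, got {cutoff}")
    kept = {key: nl for key, nl in connectome.edges.items() if nl[0] >= cutoff}
    result = connectome.with_edges(kept)
    _warn_if_disconnected(result, "naive cutoff")
    return result


def threshold_disparity(
    connectome: Connectome, alpha: float, scheme: str = "LW"
) -> Connectome:
    """Disparity-filter backbone: keep edges that are statistically dominant.

    For node i with degree k_i and strength s_i = sum_j w_ij, the edge (i, j)
    has the closed-form p-value  alpha_ij = (1 - w_ij / s_i) ** (k_i - 1)
    under the null of uniformly random weight partition.  An edge is kept if
    alpha_ij < ``alpha`` at *either* endpoint; edges at a degree-1 endpoint
    are always kept (the null is undefined there).  Weights come from the
    chosen scheme (default LW, i.e. raw fiber counts).
    """
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    w = build_weight_matrix(connectome, scheme).values
    strength = w.sum(axis=1)
    degree = connectome.degrees()
    kept = {}
    for (i, j), nl in connectome.edges.items():
        keep = False
        for u, v in ((i, j), (j, i)):
            if degree[u] == 1:
                keep = True
                break
            p_val = (1.0 - w[u, v] / strength[u]) ** (degree[u] - 1)
            if p_val < alpha:
                keep = True
                break
        if keep:
            kept[(i, j)] = nl
    result = connectome.with_edges(kept)
    _warn_if_disconnected(result, "disparity filter")
    return result


def _warn_if_disconnected(connectome: Connectome, method: str) -> None:
    n_comp = nx.number_connected_components(connectome.to_networkx())
    if n_comp > 1:
        warnings.warn(
            f"{method} left the connectome disconnected ({n_comp} components)",
            stacklevel=3,
        )


# Pluggable registry so externally published backbones (doubly stochastic,
# high-salience skeleton, noise-corrected) can be attached without modifying
# this module; only the naive cutoff and the disparity filter ship built in.
BACKBONE_FILTERS: dict[str, Callable[..., Connectome]] = {
    "naive": threshold_naive,
    "disparity": threshold_disparity,
}


def register_backbone_filter(name: str, fn: Callable[..., Connectome]) -> None:
    """Register a custom backbone filter under ``name``."""
    BACKBONE_FILTERS[name] = fn


def apply_backbone_filter(name: str, connectome: Connectome, **kwargs) -> Connectome:
    """Apply a registered backbone filter by name."""
    try:
        fn = BACKBONE_FILTERS[name]
    except KeyError:
        raise InvalidInputError(
            f"no backbone filter named {name!r}; registered: {sorted(BACKBONE_FILTERS)}"
        ) from None
    return fn(connectome, **kwargs)
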