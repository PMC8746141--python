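"""Braid diagrams and braid surfaces.

A *braid diagram* answers "in what order do the regions reach a biomarker
threshold T?" for every T in a grid, at fixed model parameters: one
simulation, one crossing-time table, one staging pattern per threshold.

A *braid surface* sweeps one model parameter (canonically ln β) and records
the observed pattern at every (parameter, threshold) cell.  Patterns are
registered in discovery order — scanning ascending parameter, then ascending
threshold — so pattern ids (and hence colors) are stable across reruns of
the same sweep specification.  Per-parameter simulations are independent and
may run in parallel; ids are assigned only after all cells are collected, so
parallel and serial execution produce identical surfaces.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import Connectome, Laplacian, build_laplacian, build_weight_matrix
from .dynamics import (
    DynamicsParams,
    Trajectory,
    initial_state,
    regional_series,
    simulate_adaptive,
)
from .regions import RegionPartition
from .staging import CrossingTimeTable, StagingPattern, crossing_times, staging_order

__all__ = [
    "BraidDiagram",
    "PatternRegistry",
    "BraidSurface",
    "default_thresholds",
    "build_braid_diagram",
    "build_braid_surface",
    "surface_summary",
    "export_surface",
    "load_surface",
    "render_surface",
]


def default_thresholds() -> np.ndarray:
    """The default biomarker threshold grid: 1%..100% in 1% steps."""
    return np.round(np.arange(1, 101) / 100.0, 10)


@dataclass
class BraidDiagram:
    """Per-threshold staging patterns at fixed model parameters."""

    thresholds: np.ndarray
    patterns: list[StagingPattern]
    table: CrossingTimeTable
    trajectory: Trajectory | None = None

    def pattern_at(self, threshold: float) -> StagingPattern:
        k = int(np.argmin(np.abs(self.thresholds - threshold)))
        if not np.isclose(self.thresholds[k], threshold):
            raise KeyError(f"threshold {threshold} not in diagram grid")
        return self.patterns[k]


class PatternRegistry:
    """Distinct canonical pattern strings, id = discovery order."""

    def __init__(self, patterns: Sequence[str] = ()):
        self._patterns: list[str] = []
        self._ids: dict[str, int] = {}
        for p in patterns:
            self.get_id(p)

    def get_id(self, canonical: str) -> int:
        """Id of a pattern, registering it if unseen."""
        if canonical not in self._ids:
            self._ids[canonical] = len(self._patterns)
            self._patterns.append(canonical)
        return self._ids[canonical]

    @property
    def patterns(self) -> tuple[str, ...]:
        return tuple(self._patterns)

    def __len__(self) -> int:
        return len(self._patterns)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._ids

    def __eq__(self, other) -> bool:
        return isinstance(other, PatternRegistry) and self.patterns == other.patterns

    def color(self, pattern_id: int) -> tuple[float, float, float, float]:
        """Deterministic discovery-order palette (tab20)."""
        from matplotlib import colormaps

        return tuple(colormaps["tab20"](pattern_id % 20))


@dataclass
class BraidSurface:
    """Pattern-id field over a (swept parameter) x (threshold) grid."""

    param_name: str
    param_values: np.ndarray
    thresholds: np.ndarray
    ids: np.ndarray  # (n_params, n_thresholds) int; -1 marks a failed cell
    registry: PatternRegistry
    failures: dict[int, str] = field(default_factory=dict)  # param index -> message

    def __post_init__(self) -> None:
        self.param_values = np.asarray(self.param_values, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)
        used = set(np.unique(self.ids)) - {-1}
        if used - set(range(len(self.registry))):
            raise ValueError("surface uses pattern ids missing from the registry")


def _max_threshold_reached(partition: RegionPartition, t_top: float, marker: str):
    """Stop criterion for the adaptive horizon: every region past ``t_top``."""
    node_lists = [sorted(s) for s in partition.node_sets]

    def finished(traj: Trajectory) -> bool:
        x = traj.p if marker == "p" else traj.q
        final = np.clip(x[-1], 0.0, 1.0)
        return all(final[nl].mean() >= t_top for nl in node_lists)

    return finished


def build_braid_diagram(
    laplacian: Laplacian,
    partition: RegionPartition,
    params: DynamicsParams,
    thresholds: Sequence[float] | None = None,
    marker: str = "p",
    tie_tol: float = 1e-9,
) -> BraidDiagram:
    """Simulate once and derive the staging pattern at every threshold.

    All thresholds are evaluated from the same solve, so there is no
    re-integration drift between rows of the diagram.  The horizon doubles
    adaptively until every region crosses the largest threshold (or the
    hard cap is hit, leaving the slow regions at infinity).
    """
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    p0, q0 = initial_state(partition, laplacian.n_nodes, params)
    # the capacity threshold T=1 is never attained in finite time, so the
    # horizon only needs to cover the largest sub-capacity threshold
    attainable = thresholds[thresholds < 1.0]
    top = float(attainable.max()) if attainable.size else 0.0
    finished = _max_threshold_reached(partition, top, marker)
    traj = simulate_adaptive(laplacian, params, p0, q0, finished)
    series = regional_series(traj, partition)
    table = crossing_times(series, thresholds, marker=marker)
    patterns = [
        staging_order(table.column(k), partition.names, tie_tol=tie_tol)
        for k in range(thresholds.size)
    ]
    return BraidDiagram(thresholds=thresholds, patterns=patterns, table=table, trajectory=traj)


def _resolve_laplacian(network, scheme: str) -> Laplacian:
    if isinstance(network, Laplacian):
        return network
    if isinstance(network, Connectome):
        return build_laplacian(build_weight_matrix(network, scheme))
    raise TypeError("network must be a Connectome or a Laplacian")


def _sweep_cell(laplacian, partition, params, thresholds, marker, tie_tol):
    try:
        diagram = build_braid_diagram(
            laplacian, partition, params, thresholds, marker=marker, tie_tol=tie_tol
        )
        return [p.canonical for p in diagram.patterns], None
    except Exception as exc:  # cell failure must not sink the sweep
        return None, f"{type(exc).__name__}: {exc}"


def build_braid_surface(
    network,
    partition: RegionPartition,
    param_values: Sequence[float],
    thresholds: Sequence[float] | None = None,
    params: DynamicsParams | None = None,
    sweep: str = "ln_beta",
    scheme: str = "DW",
    marker: str = "p",
    tie_tol: float = 1e-9,
    n_jobs: int = 1,
) -> BraidSurface:
    """Sweep one parameter and classify the staging pattern of every cell.

    ``sweep`` selects the swept axis: ``"ln_beta"`` (canonical), ``"beta"``
    or ``"delta"`` (with beta fixed from ``params``).  Each parameter value
    is one simulation whose trajectory serves every threshold.  Ids are
    assigned by scanning cells in ascending parameter then ascending
    threshold, independent of execution order.
    """
    if sweep not in ("ln_beta", "beta", "delta"):
        raise ValueError(f"unknown sweep axis {sweep!r}")
    param_values = np.asarray(param_values, dtype=float)
    if param_values.size == 0:
        raise ValueError("parameter grid must be nonempty")
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    laplacian = _resolve_laplacian(network, scheme)
    if params is None:
        params = DynamicsParams(beta=1.0)

    def cell_params(value: float) -> DynamicsParams:
        if sweep == "ln_beta":
            return params.with_(beta=float(np.exp(value)))
        if sweep == "beta":
            return params.with_(beta=float(value))
        return params.with_(delta=float(value))

    jobs = [
        (laplacian, partition, cell_params(v), thresholds, marker, tie_tol)
        for v in param_values
    ]
    if n_jobs == 1:
        results = [_sweep_cell(*j) for j in jobs]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_sweep_cell)(*j) for j in jobs)

    registry = PatternRegistry()
    ids = np.full((param_values.size, thresholds.size), -1, dtype=int)
    failures: dict[int, str] = {}
    for pi, (canonicals, error) in enumerate(results):  # canonical discovery order
        if canonicals is None:
            failures[pi] = error
            continue
        for ti, canonical in enumerate(canonicals):
            ids[pi, ti] = registry.get_id(canonical)
    return BraidSurface(
        param_name=sweep,
        param_values=param_values,
        thresholds=thresholds,
        ids=ids,
        registry=registry,
        failures=failures,
    )


def surface_summary(surface: BraidSurface, catalog: dict[str, str] | None = None) -> dict:
    """Cell counts and fractional areas per pattern, with catalog labels."""
    from .staging import classify_pattern

    total = surface.ids.size
    entries = []
    for pid, canonical in enumerate(surface.registry.patterns):
        count = int(np.sum(surface.ids == pid))
        entries.append(
            {
                "id": pid,
                "pattern": canonical,
                "count": count,
                "area": count / total,
                "label": classify_pattern(canonical, catalog),
            }
        )
    return {
        "n_cells": total,
        "n_failed": int(np.sum(surface.ids == -1)),
        "patterns": entries,
    }


def export_surface(surface: BraidSurface, directory) -> None:
    """Write ``surface.tsv`` (param, threshold, pattern_id) and ``registry.json``."""
    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    n_p, n_t = surface.ids.shape
    frame = pd.DataFrame(
        {
            surface.param_name: np.repeat(surface.param_values, n_t),
            "threshold": np.tile(surface.thresholds, n_p),
            "pattern_id": surface.ids.ravel(),
        }
    )
    frame.to_csv(os.path.join(directory, "surface.tsv"), sep="\t", index=False)
    registry = {
        "param_name": surface.param_name,
        "patterns": [
            {"id": i, "pattern": p} for i, p in enumerate(surface.registry.patterns)
        ],
        "failures": {str(k): v for k, v in surface.failures.items()},
    }
    with open(os.path.join(directory, "registry.json"), "w") as fh:
        json.dump(registry, fh, indent=2, ensure_ascii=False)


def load_surface(directory) -> BraidSurface:
    """Reload a surface exported by :func:`export_surface`."""
    import pandas as pd

    frame = pd.read_csv(os.path.join(directory, "surface.tsv"), sep="\t")
    with open(os.path.join(directory, "registry.json")) as fh:
        registry_doc = json.load(fh)
    param_name = registry_doc["param_name"]
    param_values = np.unique(frame[param_name].to_numpy())
    thresholds = np.unique(frame["threshold"].to_numpy())
    ids = (
        frame.pivot(index=param_name, columns="threshold", values="pattern_id")
        .sort_index()
        .to_numpy()
        .astype(int)
    )
    registry = PatternRegistry([e["pattern"] for e in registry_doc["patterns"]])
    failures = {int(k): v for k, v in registry_doc.get("failures", {}).items()}
    return BraidSurface(param_name, param_values, thresholds, ids, registry, failures)


def render_surface(surface: BraidSurface, path, title: str | None = None) -> None:
    """Raster of the surface with the discovery-order palette (PNG/SVG)."""
    from matplotlib import colormaps
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.figure import Figure
    from matplotlib.patches import Patch

    n_patterns = max(len(surface.registry), 1)
    palette = [colormaps["tab20"](i % 20) for i in range(n_patterns)]
    cmap = ListedColormap([(0.85, 0.85, 0.85, 1.0)] + palette)
    norm = BoundaryNorm(np.arange(-1.5, n_patterns + 0.5), cmap.N)
    fig = Figure(figsize=(8, 5))
    ax = fig.add_subplot(111)
    mesh = ax.pcolormesh(
        surface.param_values,
        surface.thresholds * 100.0,
        surface.ids.T,
        cmap=cmap,
        norm=norm,
        shading="nearest",
    )
    del mesh
    ax.set_xlabel({"ln_beta": r"$\ln\beta$", "beta": r"$\beta$", "delta": r"$\delta$"}[surface.param_name])
    ax.set_ylabel("threshold T (%)")
    if title:
        ax.set_title(title)
    handles = [
        Patch(facecolor=palette[i], label=p)
        for i, p in enumerate(surface.registry.patterns)
    ]
    if handles:
        ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.02, 1.0), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
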