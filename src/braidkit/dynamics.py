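"""Network reaction-diffusion dynamics of seed-competent protein and tangles.

The model couples a Fisher-KPP equation for the seed-competent protein
concentration ``p_i`` on the connectome with a saturating accumulation law
for the tangle (NFT) marker ``q_i``:

    dp_i/dt = -beta * sum_j L_ij p_j + p_i (1 - p_i)
    dq_i/dt = delta * p_i (1 - q_i)

Time is nondimensional (the logistic growth rate is scaled to one), ``beta``
is the transmission-to-growth ratio and ``delta`` the tangle accumulation
rate.  The system is growth dominated for beta << 1 and diffusion dominated
for beta >> 1.  The initial condition places a small total seed mass
(default 0.005) split evenly over the nodes of the seed region — the
bilateral entorhinal cortex in the disease application — with q identically
zero.

Because q solves a linear ODE given p, it admits the closed form
``q_i(t) = 1 - exp(-delta * int_0^t p_i ds)``; :func:`nft_closed_form_oracle`
evaluates it by quadrature as an independent check on the coupled solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .connectome import Laplacian
from .regions import InvalidPartitionError, RegionPartition

__all__ = [
    "DynamicsParams",
    "Trajectory",
    "RegionalSeries",
    "IntegrationError",
    "initial_state",
    "simulate",
    "simulate_adaptive",
    "regional_series",
    "nft_closed_form_oracle",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last accepted time in ``last_time``."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class DynamicsParams:
    """Model and solver parameters.

    Attributes
    ----------
    beta
        Transmission/growth ratio (> 0, dimensionless).
    delta
        NFT accumulation rate per unit nondimensional time (>= 0).
    seed_mass
        Total initial seed concentration, split evenly over the seed region.
    seed_region
        Index of the seeded region in the partition (default 0, region I).
    t_max
        Fixed integration horizon; ``None`` selects the adaptive horizon.
    t_cap
        Hard cap for the adaptive horizon; thresholds not reached by then
        report an infinite crossing time.
    rtol, atol
        Solver tolerances.  Deliberately tight: staging is decided by races
        between near-identical crossing times, which must not be resolved by
        integration error.
    """

    beta: float
    delta: float = 1.0
    seed_mass: float = 0.005
    seed_region: int = 0
    t_max: float | None = None
    t_cap: float = 1e6
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not (0 < self.seed_mass < 1):
            raise ValueError(f"seed_mass must lie in (0, 1), got {self.seed_mass}")

    @property
    def ln_beta(self) -> float:
        return float(np.log(self.beta))

    @classmethod
    def from_ln_beta(cls, ln_beta: float, **kwargs) -> "DynamicsParams":
        return cls(beta=float(np.exp(ln_beta)), **kwargs)

    def with_(self, **kwargs) -> "DynamicsParams":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """Solution of the coupled system at the solver's accepted steps.

    ``p`` and ``q`` are (n_times, n_nodes) arrays of raw solver state (no
    clamping).  ``evaluate`` interpolates both fields at arbitrary times via
    the solver's dense output, which is what crossing-time localization uses.
    """

    times: np.ndarray
    p: np.ndarray
    q: np.ndarray
    _dense: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def n_nodes(self) -> int:
        return self.p.shape[1]

    def evaluate(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Dense-output (p, q) at scalar or vector time ``t``."""
        if self._dense is None:
            raise ValueError("trajectory carries no dense output")
        y = self._dense(np.asarray(t, dtype=float))
        n = self.n_nodes
        return y[:n], y[n:]

    def to_frame(self):
        """Tidy table (time, node, p, q) for TSV export."""
        import pandas as pd

        n_t, n = self.p.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "node": np.tile(np.arange(n), n_t),
                "p": self.p.ravel(),
                "q": self.q.ravel(),
            }
        )


@dataclass
class RegionalSeries:
    """Regional averages P_j(t), Q_j(t) of a trajectory.

    Values are clamped to [0, 1] (solver undershoots below zero are a
    reporting artifact, never fed back into the state).  When the source
    trajectory has dense output, ``evaluate`` exposes the regional averages
    at arbitrary times for crossing-time bisection.
    """

    times: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    region_names: tuple[str, ...]
    _traj: Trajectory | None = None
    _partition: RegionPartition | None = None

    @property
    def n_regions(self) -> int:
        return self.P.shape[1]

    @property
    def has_dense(self) -> bool:
        return self._traj is not None and self._traj._dense is not None

    def evaluate(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Dense-output (P, Q) per region at scalar time ``t``."""
        if not self.has_dense:
            raise ValueError("series carries no dense output")
        p, q = self._traj.evaluate(t)
        P = np.array([np.clip(p[list(s)], 0.0, 1.0).mean(axis=0) for s in self._partition.node_sets])
        Q = np.array([np.clip(q[list(s)], 0.0, 1.0).mean(axis=0) for s in self._partition.node_sets])
        return P, Q

    def to_frame(self):
        """Tidy table (time, region, p, q) for TSV export."""
        import pandas as pd

        n_t, J = self.P.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, J),
                "region": np.tile(self.region_names, n_t),
                "p": self.P.ravel(),
                "q": self.Q.ravel(),
            }
        )


def initial_state(
    partition: RegionPartition, n_nodes: int, params: DynamicsParams
) -> tuple[np.ndarray, np.ndarray]:
    """Seed-region initial condition: p0_i = seed_mass / N_seed, q0 = 0.

    The total seed mass is split evenly over the nodes of the seeded region;
    all other nodes start clean.
    """
    if not (0 <= params.seed_region < partition.n_regions):
        raise InvalidPartitionError(
            f"seed region index {params.seed_region} outside partition of {partition.n_regions}"
        )
    seed_nodes = sorted(partition.node_sets[params.seed_region])
    if not seed_nodes:
        raise InvalidPartitionError("seed region is empty")
    if max(seed_nodes) >= n_nodes:
        raise InvalidPartitionError("seed region references nodes beyond the connectome")
    p0 = np.zeros(n_nodes)
    p0[seed_nodes] = params.seed_mass / len(seed_nodes)
    q0 = np.zeros(n_nodes)
    return p0, q0


def _laplacian_matrix(laplacian) -> np.ndarray:
    if isinstance(laplacian, Laplacian):
        if laplacian.params != (0.0, 0.0):
            warnings.warn(
                f"Laplacian params {laplacian.params} violate the transport axioms; "
                "the standard (0, 0) Laplacian is recommended",
                stacklevel=3,
            )
        return laplacian.values
    return np.asarray(laplacian, dtype=float)


def simulate(
    laplacian,
    params: DynamicsParams,
    p0: np.ndarray,
    q0: np.ndarray,
    *,
    t_max: float | None = None,
    growth: bool = True,
) -> Trajectory:
    """Integrate the coupled seed/NFT system to ``t_max`` with dense output.

    Uses an adaptive stiff-capable method (LSODA by default) with an
    analytic Jacobian.  ``growth=False`` disables the logistic reaction term
    (pure transport), which conserves total seed mass under the standard
    Laplacian — a verification hook, not a disease model.
    """
    lap = _laplacian_matrix(laplacian)
    n = lap.shape[0]
    if lap.shape != (n, n):
        raise ValueError("Laplacian must be square")
    p0 = np.asarray(p0, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    if p0.shape != (n,) or q0.shape != (n,):
        raise ValueError("state length does not match the Laplacian")
    if t_max is None:
        t_max = params.t_max if params.t_max is not None else 10.0
    beta, delta = params.beta, params.delta
    blap = beta * lap

    def rhs(_t, y):
        p, q = y[:n], y[n:]
        dp = -blap @ p
        if growth:
            dp += p * (1.0 - p)
        dq = delta * p * (1.0 - q)
        return np.concatenate([dp, dq])

    def jac(_t, y):
        p, q = y[:n], y[n:]
        j = np.zeros((2 * n, 2 * n))
        j[:n, :n] = -blap
        if growth:
            j[:n, :n] += np.diag(1.0 - 2.0 * p)
        j[n:, :n] = np.diag(delta * (1.0 - q))
        j[n:, n:] = np.diag(-delta * p)
        return j

    sol = solve_ivp(
        rhs,
        (0.0, float(t_max)),
        np.concatenate([p0, q0]),
        method=params.method,
        jac=jac,
        rtol=params.rtol,
        atol=params.atol,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}", last_time=float(sol.t[-1])
        )
    return Trajectory(times=sol.t, p=sol.y[:n].T, q=sol.y[n:].T, _dense=sol.sol)


def simulate_adaptive(
    laplacian,
    params: DynamicsParams,
    p0: np.ndarray,
    q0: np.ndarray,
    finished: Callable[[Trajectory], bool],
    *,
    t_start: float = 10.0,
    growth: bool = True,
) -> Trajectory:
    """Double the horizon from ``t_start`` until ``finished`` or the hard cap.

    ``finished(traj)`` inspects the trajectory's end state (e.g. "every
    region has crossed the largest threshold").  Thresholds still uncrossed
    at the cap are reported as infinite by the staging layer.
    """
    t_max = t_start
    while True:
        traj = simulate(laplacian, params, p0, q0, t_max=t_max, growth=growth)
        if finished(traj) or t_max >= params.t_cap:
            return traj
        t_max = min(2.0 * t_max, params.t_cap)


def regional_series(traj: Trajectory, partition: RegionPartition) -> RegionalSeries:
    """Average node trajectories over each region (divisor: region size)."""
    n = traj.n_nodes
    if max(partition.covered_nodes()) >= n:
        raise InvalidPartitionError("partition references nodes beyond the trajectory")
    p = np.clip(traj.p, 0.0, 1.0)
    q = np.clip(traj.q, 0.0, 1.0)
    P = np.column_stack([p[:, sorted(s)].mean(axis=1) for s in partition.node_sets])
    Q = np.column_stack([q[:, sorted(s)].mean(axis=1) for s in partition.node_sets])
    return RegionalSeries(
        times=traj.times,
        P=P,
        Q=Q,
        region_names=partition.names,
        _traj=traj,
        _partition=partition,
    )


def nft_closed_form_oracle(
    traj: Trajectory, delta: float, n_grid: int = 4001
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature evaluation of q_i(t) = 1 - exp(-delta * int_0^t p_i ds).

    Samples the dense seed trajectory on a uniform grid and integrates by
    the trapezoid rule; independent of the coupled q solve it validates.
    Returns ``(t_grid, q_hat)`` with q_hat of shape (n_grid, n_nodes).
    """
    t_grid = np.linspace(traj.times[0], traj.times[-1], n_grid)
    p, _ = traj.evaluate(t_grid)
    integral = cumulative_trapezoid(p, t_grid, axis=1, initial=0.0)
    return t_grid, 1.0 - np.exp(-delta * integral.T)
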