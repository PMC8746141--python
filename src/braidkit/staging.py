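"""Threshold-crossing times, observed staging patterns, and dispersion.

Given regional biomarker time series and a fixed threshold T in (0, 1], the
crossing time of region j is the earliest time its average first reaches T
(infinity if it never does within the horizon).  Sorting regions by
ascending crossing time yields the *observed staging pattern* — the model's
analogue of a Braak-style anatomical progression — written in the compact
arrow notation, e.g. ``I → III → II → IV``.

The spread of the crossing times at one threshold (their population standard
deviation) diagnoses *race conditions*: where the times are nearly identical
the observed ordering flips under tiny parameter perturbations, so a
near-zero standard deviation marks the staging as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .connectome import InvalidInputError
from .dynamics import RegionalSeries
from .regions import InvalidPartitionError, RegionPartition, roman  # noqa: F401  (re-export)

__all__ = [
    "RegionPartition",
    "CrossingTimeTable",
    "StagingPattern",
    "DEFAULT_PATTERN_CATALOG",
    "crossing_times",
    "staging_order",
    "classify_pattern",
    "staging_time_std",
]

ARROW = " → "

#: Named late-stage patterns of clinical interest for the five Braak-style
#: regions: the canonical progressive sequence, the variant suggested by
#: tau-PET SUVR data (III before II), and the two uncertain-terminal
#: variants (V before IV).
DEFAULT_PATTERN_CATALOG: dict[str, str] = {
    "I → II → III → IV → V": "progressive",
    "I → III → II → IV → V": "suvr-suggested",
    "I → II → III → V → IV": "progressive-late-swap",
    "I → III → II → V → IV": "suvr-late-swap",
}


@dataclass
class CrossingTimeTable:
    """Matrix t[j, k]: first time region j reaches threshold k (inf if never)."""

    region_names: tuple[str, ...]
    thresholds: np.ndarray
    times: np.ndarray  # (J, K), entries in [0, inf]
    marker: str = "p"

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.region_names), self.thresholds.size):
            raise ValueError("times must be (n_regions, n_thresholds)")
        if np.any(self.times < 0):
            raise ValueError("crossing times must be nonnegative")

    def column(self, k: int) -> np.ndarray:
        return self.times[:, k]

    def to_frame(self):
        """Tidy table (region, threshold, time); inf serialized as 'inf'."""
        import pandas as pd

        J, K = self.times.shape
        return pd.DataFrame(
            {
                "region": np.repeat(self.region_names, K),
                "threshold": np.tile(self.thresholds, J),
                "time": self.times.ravel(),
            }
        )


@dataclass(frozen=True)
class StagingPattern:
    """An observed staging pattern: reached regions in crossing order.

    ``order`` holds indices of regions that reached the threshold, ascending
    in crossing time; ``unreached`` the regions whose time is infinite
    (ascending index).  Two patterns are equal iff their canonical strings
    are equal — a pattern with unreached regions is a distinct observation
    from any completed one.  ``ties`` records adjacent pairs whose times
    agree within the tie tolerance (broken by ascending region index).
    """

    order: tuple[int, ...]
    unreached: tuple[int, ...]
    region_names: tuple[str, ...]
    ties: tuple[tuple[int, int], ...] = ()
    canonical: str = field(init=False)

    def __post_init__(self) -> None:
        if set(self.order) | set(self.unreached) != set(range(len(self.region_names))):
            raise ValueError("order and unreached must partition the regions")
        head = ARROW.join(self.region_names[i] for i in self.order)
        if self.unreached:
            tail = ", ".join(self.region_names[i] for i in self.unreached)
            head = f"{head} [unreached: {tail}]" if head else f"[unreached: {tail}]"
        object.__setattr__(self, "canonical", head)

    def __eq__(self, other) -> bool:
        return isinstance(other, StagingPattern) and self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __str__(self) -> str:
        return self.canonical


def crossing_times(
    series: RegionalSeries,
    thresholds: Sequence[float],
    marker: str = "p",
    rel_tol: float = 1e-8,
) -> CrossingTimeTable:
    """First-passage times of each regional average over each threshold.

    Thresholds must be strictly increasing values in (0, 1].  The crossing is
    closed (>=): a region whose initial average already meets T crosses at
    time zero.  Between stored solver points the crossing is localized by
    bisection on the dense output (relative time tolerance ``rel_tol``),
    falling back to monotone linear interpolation when no dense output is
    attached.  A threshold not reached within the horizon yields infinity.

    The capacity threshold T = 1 is the asymptotic limit of the saturating
    dynamics: trajectories approach it strictly from below, so it is only
    met by a region whose initial average is already saturated.  Treating a
    numerical overshoot as attainment would rank regions by solver noise.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or thresholds.size == 0:
        raise InvalidInputError("thresholds must be a nonempty 1-D sequence")
    if np.any(thresholds <= 0) or np.any(thresholds > 1):
        raise InvalidInputError("thresholds must lie in (0, 1]")
    if np.any(np.diff(thresholds) <= 0):
        raise InvalidInputError("thresholds must be strictly increasing")
    values = series.P if marker == "p" else series.Q
    t_pts = series.times
    J = series.n_regions
    out = np.full((J, thresholds.size), np.inf)
    for j in range(J):
        col = values[:, j]
        for k, thr in enumerate(thresholds):
            if thr >= 1.0:
                if col[0] >= thr:  # saturated from the start
                    out[j, k] = t_pts[0]
                continue
            hits = np.nonzero(col >= thr)[0]
            if hits.size == 0:
                continue
            idx = int(hits[0])
            if idx == 0:
                out[j, k] = t_pts[0]
                continue
            lo, hi = t_pts[idx - 1], t_pts[idx]
            if series.has_dense:

                def gap(t, _j=j, _thr=thr):
                    P, Q = series.evaluate(t)
                    v = P if marker == "p" else Q
                    return v[_j] - _thr

                g_lo, g_hi = gap(lo), gap(hi)
                if g_lo >= 0:  # dense output crosses earlier than the stored grid
                    out[j, k] = lo
                elif g_hi < 0:
                    out[j, k] = hi
                else:
                    out[j, k] = brentq(gap, lo, hi, rtol=max(rel_tol, 4e-16))
            else:
                frac = (thr - col[idx - 1]) / (col[idx] - col[idx - 1])
                out[j, k] = lo + frac * (hi - lo)
    return CrossingTimeTable(series.region_names, thresholds, out, marker=marker)


def staging_order(
    times: np.ndarray,
    region_names: Sequence[str],
    tie_tol: float = 1e-9,
) -> StagingPattern:
    """Order regions by ascending crossing time into a staging pattern.

    Infinite entries go to ``unreached`` (ascending region index).  Finite
    times equal within ``tie_tol`` are flagged as ties and broken by
    ascending region index — a race this close is a warning sign, never
    silently resolved.
    """
    times = np.asarray(times, dtype=float)
    region_names = tuple(region_names)
    finite = [j for j in range(times.size) if np.isfinite(times[j])]
    unreached = tuple(j for j in range(times.size) if not np.isfinite(times[j]))
    order = tuple(sorted(finite, key=lambda j: (times[j], j)))
    ties = tuple(
        (order[m], order[m + 1])
        for m in range(len(order) - 1)
        if abs(times[order[m + 1]] - times[order[m]]) <= tie_tol
    )
    return StagingPattern(order=order, unreached=unreached, region_names=region_names, ties=ties)


def classify_pattern(
    pattern: StagingPattern | str, catalog: dict[str, str] | None = None
) -> str:
    """Label a pattern by exact canonical-string match; unmatched -> 'other'."""
    if catalog is None:
        catalog = DEFAULT_PATTERN_CATALOG
    canonical = pattern.canonical if isinstance(pattern, StagingPattern) else pattern
    return catalog.get(canonical, "other")


def staging_time_std(table: CrossingTimeTable, column: int) -> float | None:
    """Population standard deviation of one threshold's crossing times.

    Returns ``None`` (undefined) if any region never crossed: an infinite
    entry has no meaningful dispersion.  Low values flag race conditions.
    """
    col = table.column(column)
    if not np.all(np.isfinite(col)):
        return None
    return float(np.std(col))
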