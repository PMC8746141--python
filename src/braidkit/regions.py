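"""Staging regions: ordered, disjoint node sets with Roman-numeral names.

The staging vocabulary follows the Braak-style five-region adaptation used
for tau pathology on Lausanne-parcellated connectomes: I entorhinal cortex,
II hippocampus, III parahippocampal gyrus, IV anterior cingulate (rostral +
caudal), V occipital terminal stage (cuneus, pericalcarine, lateral
occipital, lingual).  The packaged JSON config encodes that mapping; any
other partition can be supplied the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "RegionPartition",
    "InvalidPartitionError",
    "roman",
    "load_region_config",
    "partition_from_labels",
]

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(number: int) -> str:
    """Roman numeral for a positive integer (region display names)."""
    if number < 1:
        raise ValueError(f"no Roman numeral for {number}")
    out = []
    for value, sym in _ROMAN:
        while number >= value:
            out.append(sym)
            number -= value
    return "".join(out)


class InvalidPartitionError(ValueError):
    """Raised when a region partition violates its invariants."""


@dataclass(frozen=True)
class RegionPartition:
    """Ordered list of named, pairwise-disjoint, nonempty node sets."""

    names: tuple[str, ...]
    node_sets: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.node_sets):
            raise InvalidPartitionError("names and node sets differ in length")
        seen: set[int] = set()
        for name, nodes in zip(self.names, self.node_sets):
            if not nodes:
                raise InvalidPartitionError(f"region {name} is empty")
            if seen & nodes:
                raise InvalidPartitionError(f"region {name} overlaps an earlier region")
            seen |= nodes

    @classmethod
    def from_node_sets(cls, node_sets: Sequence[Iterable[int]], names=None) -> "RegionPartition":
        sets = tuple(frozenset(int(i) for i in s) for s in node_sets)
        if names is None:
            names = tuple(roman(k + 1) for k in range(len(sets)))
        return cls(tuple(names), sets)

    @classmethod
    def singletons(cls, n_regions: int) -> "RegionPartition":
        """One region per node, named I, II, ... (the worked-example layout)."""
        return cls.from_node_sets([[k] for k in range(n_regions)])

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.node_sets)

    def covered_nodes(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self.node_sets:
            out |= s
        return frozenset(out)


def load_region_config(path=None) -> list[dict]:
    """Load a region config: ``[{"name": ..., "labels": [...]}, ...]``.

    With no path, the packaged Braak-style five-region mapping is returned.
    """
    if path is None:
        text = resources.files("braidkit.data").joinpath("staging_regions.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = json.loads(text)
    regions = config["regions"] if isinstance(config, dict) else config
    for entry in regions:
        if "name" not in entry or "labels" not in entry:
            raise InvalidPartitionError("each region entry needs 'name' and 'labels'")
    return regions


def partition_from_labels(
    config: list[dict], node_labels: Sequence[str]
) -> RegionPartition:
    """Assign nodes to regions by case-insensitive substring match on labels.

    Anatomical node labels usually carry hemisphere prefixes
    (``lh.entorhinal_1``); a node joins a region when any of the region's
    label patterns occurs in its label.  A node matching several regions is
    an error (regions must be disjoint).
    """
    names, sets = [], []
    owner: dict[int, str] = {}
    for entry in config:
        members = set()
        for idx, label in enumerate(node_labels):
            lowered = label.lower()
            if any(pat.lower() in lowered for pat in entry["labels"]):
                if idx in owner:
                    raise InvalidPartitionError(
                        f"node {idx} ({label}) matches both {owner[idx]} and {entry['name']}"
                    )
                owner[idx] = entry["name"]
                members.add(idx)
        if not members:
            raise InvalidPartitionError(f"region {entry['name']} matched no node label")
        names.append(entry["name"])
        sets.append(frozenset(members))
    return RegionPartition(tuple(names), tuple(sets))
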