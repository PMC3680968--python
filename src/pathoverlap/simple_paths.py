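"""Enumeration of simple paths: minimal, non-overlapping reaction chains.

A *simple path* between an ordered species pair (u, v) is a directed walk over
the spliced edges whose reaction-id chain has no repeated id
("non-overlapping"), whose length — counted in reactions, not species hops —
is at most N, and which is *minimal*: no shorter valid chain connects the same
ordered pair.  All distinct chains of the minimal length are kept, and a path
may start and end at the same species (a cycle competes only against other
cycles on that species).  Interior species may repeat as long as reaction ids
do not; interiors are recorded because the matching stage rejects pairs with
equivalent intermediate species.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from .errors import ParameterError
from .sbml_graph import PathwayGraph

__all__ = ["SimplePath", "enumerate_simple_paths"]


@dataclasses.dataclass(frozen=True, order=True)
class SimplePath:
    """A minimal reaction chain from ``start`` to ``end``.

    ``orientation[i]`` is True when step i traverses a reversible reaction
    against its declared direction; ``interior`` lists the intermediate species
    in traversal order (length ``len(chain) - 1``).
    """

    start: str
    end: str
    chain: tuple[str, ...]
    orientation: tuple[bool, ...]
    interior: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.orientation) != len(self.chain):
            raise ValueError("orientation must align with chain")
        if len(self.interior) != len(self.chain) - 1:
            raise ValueError("interior must have len(chain) - 1 species")

    @property
    def length(self) -> int:
        return len(self.chain)

    @property
    def is_cycle(self) -> bool:
        return self.start == self.end


def enumerate_simple_paths(graph: PathwayGraph, n_max: int) -> list[SimplePath]:
    """All simple paths of length <= ``n_max`` of one pathway graph.

    Breadth-first layered expansion per source species: walks grow one reaction
    at a time, pruning any extension that reuses a reaction id already in the
    chain.  The first layer at which a target is reached fixes the minimal
    length for that ordered pair; every distinct (chain, interior) realization
    at that layer is returned, nothing longer.

    The result is sorted, so identical graphs yield identical path lists.
    """
    if n_max < 1:
        raise ParameterError(f"maximum path length must be >= 1, got {n_max}")
    found: set[SimplePath] = set()
    for source in sorted(graph.vertex_ids):
        # walk = (current species, chain, orientation, full node sequence)
        frontier: list[tuple[str, tuple[str, ...], tuple[bool, ...], tuple[str, ...]]]
        frontier = [(source, (), (), (source,))]
        minimal_length: dict[str, int] = {}
        for length in range(1, n_max + 1):
            next_frontier = []
            for current, chain, orientation, nodes in frontier:
                for target, rid, rev in graph.out_edges(current):
                    if rid in chain:
                        continue
                    walk = (target, chain + (rid,), orientation + (rev,), nodes + (target,))
                    next_frontier.append(walk)
                    if minimal_length.setdefault(target, length) == length:
                        found.add(
                            SimplePath(
                                start=source,
                                end=target,
                                chain=walk[1],
                                orientation=walk[2],
                                interior=walk[3][1:-1],
                            )
                        )
            frontier = next_frontier
    return sorted(found)


def paths_by_pair(
    paths: Iterable[SimplePath],
) -> dict[tuple[str, str], list[SimplePath]]:
    """Group a path collection by its ordered (start, end) species pair."""
    grouped: dict[tuple[str, str], list[SimplePath]] = {}
    for path in paths:
        grouped.setdefault((path.start, path.end), []).append(path)
    return grouped
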