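"""Compatibility graph, Bron-Kerbosch clique enumeration and the staged solver.

A set of matched path pairs is *consistent* when it induces one-to-one
mappings between species, between compartments and between reaction chains,
and no reaction id belongs to two distinct matched chains (a chain and its
reversed chain count as one).  Pairwise consistency defines the undirected
*compatibility graph* over path pairs; maximal consistent sets are exactly its
maximal cliques, enumerated here with the pivoting (version 2) variant of the
Bron-Kerbosch algorithm.

Because clique enumeration is exponential in the worst case, the solver is
staged: at stage i = 1..N only path pairs of maximum chain length i that are
compatible with everything already accepted are considered, the cliques of the
subgraph they induce are enumerated, and the best clique — highest summed
overlap score, then largest, then lexicographically first — is folded into the
accepted set.  Shorter chains are the safest similarities, so they are locked
in first.  Optional bounds on the number of enumerated cliques and on solver
time make large queries practical; the time budget is split evenly across
stages and a stage that exhausts it keeps its best result so far.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Iterable, NamedTuple, Sequence

from . import scoring
from .errors import ParameterError
from .path_matching import EquivalenceSpec, PathPair, match_paths
from .sbml_graph import PathwayGraph
from .simple_paths import enumerate_simple_paths

__all__ = [
    "SolverLimits",
    "UNBOUNDED",
    "ChainMatch",
    "MatchSolution",
    "compatible",
    "CompatibilityGraph",
    "build_compatibility_graph",
    "bron_kerbosch_v2",
    "iterative_overlap",
]

Chain = tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class SolverLimits:
    """Bounds on clique enumeration; ``None`` means unbounded."""

    max_solutions: int | None = None
    max_time: float | None = None

    def __post_init__(self) -> None:
        if self.max_solutions is not None and self.max_solutions < 1:
            raise ParameterError("max_solutions must be >= 1 or None")
        if self.max_time is not None and self.max_time < 0:
            raise ParameterError("max_time must be >= 0 or None")


UNBOUNDED = SolverLimits()


class ChainMatch(NamedTuple):
    """One matched pair of reaction chains; reversed2 marks opposite traversal."""

    chain1: Chain
    chain2: Chain
    reversed2: bool


@dataclasses.dataclass(frozen=True)
class MatchSolution:
    """A consistent set E of path pairs with its induced mappings.

    ``species_map`` maps doc1 species ids to doc2 ids (endpoints plus mapped
    modifiers), injectively in both directions; likewise ``compartment_map``.
    ``modifier_map`` is the subset of ``species_map`` contributed by modifier
    mapping.  ``truncated`` flags that a solver limit was reached.
    """

    pairs: tuple[PathPair, ...]
    species_map: dict[str, str]
    compartment_map: dict[str, str]
    chain_map: tuple[ChainMatch, ...]
    modifier_map: dict[str, str]
    truncated: bool = False

    @property
    def is_empty(self) -> bool:
        return not self.pairs


def canonical_chain(chain: Chain) -> Chain:
    """A chain and its reversed chain count as one; pick the smaller tuple."""
    reverse = chain[::-1]
    return chain if chain <= reverse else reverse


def _merge_one_to_one(
    pairs_a: Iterable[tuple[str, str]], pairs_b: Iterable[tuple[str, str]]
) -> bool:
    fwd: dict[str, str] = {}
    bwd: dict[str, str] = {}
    for a, b in (*pairs_a, *pairs_b):
        if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
            return False
    return True


def compatible(p: PathPair, q: PathPair) -> bool:
    """True iff the union of the two pairs' induced mappings stays one-to-one.

    Checks species and compartment injectivity, chain-to-chain uniqueness
    (up to reversal) and single ownership of every reaction id per side.
    """
    if p == q:
        return False
    if not _merge_one_to_one(p.species_pairs, q.species_pairs):
        return False
    if not _merge_one_to_one(p.compartment_pairs, q.compartment_pairs):
        return False
    c1p, c1q = canonical_chain(p.chain1), canonical_chain(q.chain1)
    c2p, c2q = canonical_chain(p.chain2), canonical_chain(q.chain2)
    if (c1p == c1q) != (c2p == c2q):
        return False
    if c1p != c1q:
        if set(p.chain1) & set(q.chain1):
            return False
        if set(p.chain2) & set(q.chain2):
            return False
    return True


@dataclasses.dataclass(frozen=True)
class CompatibilityGraph:
    """Undirected graph (no self loops) over indexed path pairs."""

    pairs: tuple[PathPair, ...]
    adjacency: tuple[frozenset[int], ...]

    @property
    def n_vertices(self) -> int:
        return len(self.adjacency)

    @classmethod
    def from_adjacency(cls, n_vertices: int, edges: Iterable[tuple[int, int]]) -> "CompatibilityGraph":
        """Build from an explicit edge list (used by tests and tools)."""
        adj: list[set[int]] = [set() for _ in range(n_vertices)]
        for u, v in edges:
            if u == v:
                continue
            adj[u].add(v)
            adj[v].add(u)
        return cls(pairs=(), adjacency=tuple(frozenset(a) for a in adj))


def build_compatibility_graph(pairs: Sequence[PathPair]) -> CompatibilityGraph:
    """Vertex per path pair (deterministically indexed), edge iff compatible."""
    ordered = tuple(sorted(set(pairs)))
    n = len(ordered)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if compatible(ordered[i], ordered[j]):
                adj[i].add(j)
                adj[j].add(i)
    return CompatibilityGraph(pairs=ordered, adjacency=tuple(frozenset(a) for a in adj))


def bron_kerbosch_v2(
    graph: CompatibilityGraph, limits: SolverLimits = UNBOUNDED
) -> tuple[list[tuple[int, ...]], bool]:
    """Enumerate maximal cliques with pivoting.

    The pivot is the vertex of P union X with the most neighbours in P
    (smallest index on ties) and candidates are expanded in index order, so the
    enumeration order is deterministic.  Returns the cliques found and a flag
    marking that a limit cut the enumeration short; every returned clique is
    maximal regardless.
    """
    adjacency = graph.adjacency
    deadline = None if limits.max_time is None else time.monotonic() + limits.max_time
    cliques: list[tuple[int, ...]] = []
    stop = False

    def expand(r: frozenset[int], p: frozenset[int], x: frozenset[int]) -> None:
        nonlocal stop
        if stop:
            return
        if deadline is not None and time.monotonic() > deadline:
            stop = True
            return
        if not p and not x:
            cliques.append(tuple(sorted(r)))
            if limits.max_solutions is not None and len(cliques) >= limits.max_solutions:
                stop = True
            return
        pivot = max(sorted(p | x), key=lambda u: len(adjacency[u] & p))
        for v in sorted(p - adjacency[pivot]):
            expand(r | {v}, p & adjacency[v], x & adjacency[v])
            if stop:
                return
            p = p - {v}
            x = x | {v}

    expand(frozenset(), frozenset(range(graph.n_vertices)), frozenset())
    return cliques, stop


def _build_solution(
    pairs: Iterable[PathPair],
    g1: PathwayGraph,
    g2: PathwayGraph,
    spec: EquivalenceSpec | None,
    truncated: bool = False,
) -> MatchSolution:
    ordered = tuple(sorted(set(pairs)))
    species_map: dict[str, str] = {}
    compartment_map: dict[str, str] = {}
    chain_matches: dict[tuple[Chain, Chain], ChainMatch] = {}
    for pp in ordered:
        species_map.update(pp.species_pairs)
        compartment_map.update(pp.compartment_pairs)
        key = (canonical_chain(pp.chain1), canonical_chain(pp.chain2))
        chain_matches.setdefault(key, ChainMatch(pp.chain1, pp.chain2, pp.reversed2))
    solution = MatchSolution(
        pairs=ordered,
        species_map=species_map,
        compartment_map=compartment_map,
        chain_map=tuple(sorted(chain_matches.values())),
        modifier_map={},
        truncated=truncated,
    )
    return scoring.map_modifiers(solution, g1, g2, spec)


def iterative_overlap(
    g1: PathwayGraph,
    g2: PathwayGraph,
    n_max: int = 3,
    spec: EquivalenceSpec | None = None,
    limits: SolverLimits = UNBOUNDED,
) -> MatchSolution:
    """Run the full staged overlap computation between two pathway graphs.

    Enumerates simple paths on both graphs, matches them, then accumulates one
    best clique per stage i = 1..N over the pairs of maximum length i that are
    compatible with everything accepted so far.  The returned solution carries
    the induced species/compartment/chain mappings, the modifier mapping, and
    a truncation flag when limits were hit.  An empty solution is valid when
    nothing matches.
    """
    if n_max < 1:
        raise ParameterError(f"maximum path length must be >= 1, got {n_max}")
    paths1 = enumerate_simple_paths(g1, n_max)
    paths2 = enumerate_simple_paths(g2, n_max)
    all_pairs = match_paths(paths1, paths2, g1, g2, spec)

    stage_limits = SolverLimits(
        max_solutions=limits.max_solutions,
        max_time=None if limits.max_time is None else limits.max_time / n_max,
    )
    accepted: list[PathPair] = []
    truncated = False
    for stage in range(1, n_max + 1):
        candidates = [
            pp
            for pp in all_pairs
            if pp.max_length == stage and all(compatible(pp, a) for a in accepted)
        ]
        if not candidates:
            continue
        cgraph = build_compatibility_graph(candidates)
        cliques, cut = bron_kerbosch_v2(cgraph, stage_limits)
        truncated = truncated or cut
        best_key: tuple[float, int, tuple[int, ...]] | None = None
        best_pairs: list[PathPair] = []
        for clique in cliques:
            trial_pairs = accepted + [cgraph.pairs[v] for v in clique]
            trial = _build_solution(trial_pairs, g1, g2, spec)
            score = scoring.score_solution(g1, g2, trial)
            # negated clique tuple: on score/size ties prefer the
            # lexicographically smallest vertex set
            key = (score.s1 + score.s2, len(clique), tuple(-v for v in clique))
            if best_key is None or key > best_key:
                best_key = key
                best_pairs = trial_pairs
        if best_pairs:
            accepted = best_pairs
    return _build_solution(accepted, g1, g2, spec, truncated=truncated)
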