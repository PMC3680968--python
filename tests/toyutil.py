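"""Shared builders and independent brute-force oracles for the test suite.

The oracles deliberately use different strategies than the library code:
depth-first enumeration of all reaction-id-distinct walks followed by a
minimality filter (vs the library's layered breadth-first search), exhaustive
subset checking for maximal cliques (vs pivoted Bron-Kerbosch), and pairwise
concordance counting for AUC (vs the ROC integral).
"""

from __future__ import annotations

import itertools
import random

from pathoverlap.clique_solver import CompatibilityGraph
from pathoverlap.sbml_graph import PathwayGraph, Reaction, Species, build_graph
from pathoverlap.simple_paths import SimplePath


def S(sid: str, name: str | None = "", comp: str = "c") -> Species:
    """Species shortcut; name defaults to the id itself."""
    return Species(id=sid, compartment=comp, name=sid if name == "" else name)


def R(rid, reactants, products, modifiers=(), reversible=False, name=None) -> Reaction:
    return Reaction(
        id=rid,
        reactants=frozenset(reactants),
        products=frozenset(products),
        modifiers=frozenset(modifiers),
        reversible=reversible,
        name=name,
    )


def G(species, reactions) -> PathwayGraph:
    return build_graph(species, reactions)


def linear_graph(n_reactions: int = 3, reversible: bool = False) -> PathwayGraph:
    species = [S(f"A{i}") for i in range(n_reactions + 1)]
    reactions = [
        R(f"r{i}", {f"A{i}"}, {f"A{i+1}"}, reversible=reversible) for i in range(n_reactions)
    ]
    return G(species, reactions)


def brute_simple_paths(graph: PathwayGraph, n_max: int) -> set[SimplePath]:
    """DFS over all distinct-reaction-id walks up to n_max, then keep the
    minimal length per ordered (start, end) pair."""
    walks: list[SimplePath] = []

    def dfs(node, chain, orient, nodes):
        if chain:
            walks.append(
                SimplePath(
                    start=nodes[0], end=node, chain=chain, orientation=orient,
                    interior=nodes[1:-1],
                )
            )
        if len(chain) == n_max:
            return
        for tgt, rid, rev in graph.out_edges(node):
            if rid in chain:
                continue
            dfs(tgt, chain + (rid,), orient + (rev,), nodes + (tgt,))

    for u in graph.vertex_ids:
        dfs(u, (), (), (u,))
    minimal: dict[tuple[str, str], int] = {}
    for w in walks:
        key = (w.start, w.end)
        minimal[key] = min(minimal.get(key, w.length), w.length)
    return {w for w in walks if w.length == minimal[(w.start, w.end)]}


def random_multidigraph(rng: random.Random, max_species: int = 8, max_reactions: int = 10) -> PathwayGraph:
    """A random pathway graph; names equal ids, single compartment."""
    n_species = rng.randint(2, max_species)
    n_reactions = rng.randint(1, max_reactions)
    species = [S(f"s{i}") for i in range(n_species)]
    reactions = []
    for j in range(n_reactions):
        reactants = frozenset(rng.sample(range(n_species), rng.choice((1, 2))))
        products = frozenset(rng.sample(range(n_species), rng.choice((1, 2))))
        reactions.append(
            R(
                f"r{j}",
                {f"s{i}" for i in reactants},
                {f"s{i}" for i in products},
                reversible=rng.random() < 0.3,
            )
        )
    return G(species, reactions)


def brute_maximal_cliques(graph: CompatibilityGraph) -> set[tuple[int, ...]]:
    """All maximal cliques by exhaustive subset enumeration (n <= ~14)."""
    n = graph.n_vertices
    adj = graph.adjacency
    cliques = [
        subset
        for r in range(1, n + 1)
        for subset in itertools.combinations(range(n), r)
        if all(v in adj[u] for u, v in itertools.combinations(subset, 2))
    ]
    if n == 0:
        return set()
    clique_sets = [set(c) for c in cliques]
    maximal = set()
    for c, cs in zip(cliques, clique_sets):
        if not any(cs < other for other in clique_sets):
            maximal.add(c)
    return maximal


def random_compat_graph(rng: random.Random, max_vertices: int = 12) -> CompatibilityGraph:
    n = rng.randint(1, max_vertices)
    edges = [
        (u, v)
        for u, v in itertools.combinations(range(n), 2)
        if rng.random() < rng.choice((0.2, 0.5, 0.8))
    ]
    return CompatibilityGraph.from_adjacency(n, edges)


def auc_by_concordance(labels, values) -> float:
    """AUC as the pairwise concordance probability (ties count 1/2)."""
    positives = [v for v, y in zip(values, labels) if y]
    negatives = [v for v, y in zip(values, labels) if not y]
    total = 0.0
    for p in positives:
        for q in negatives:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(positives) * len(negatives))
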