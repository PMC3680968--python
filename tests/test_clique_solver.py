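"""Compatibility, Bron-Kerbosch enumeration and the staged overlap solver."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from pathoverlap.clique_solver import (
    CompatibilityGraph,
    SolverLimits,
    bron_kerbosch_v2,
    build_compatibility_graph,
    compatible,
    iterative_overlap,
)
from pathoverlap.errors import ParameterError
from pathoverlap.path_matching import match_paths
from pathoverlap.sbml_graph import load_pathway
from pathoverlap.scoring import score_solution
from pathoverlap.simple_paths import enumerate_simple_paths
from toyutil import G, R, S, brute_maximal_cliques, random_compat_graph


def all_pairs(g1, g2, n_max=3, spec=None):
    return match_paths(
        enumerate_simple_paths(g1, n_max), enumerate_simple_paths(g2, n_max), g1, g2, spec
    )


def pair_by_chains(pairs, chain1, chain2):
    return next(pp for pp in pairs if pp.chain1 == chain1 and pp.chain2 == chain2)


class TestCompatibility:
    def setup_method(self):
        # two disjoint matched edges plus one conflicting alternative:
        # doc1 has A -r1-> B, C -r2-> D; doc2 has the same names twice so the
        # A-path can map to either copy.
        self.g1 = G(
            [S("a", "A"), S("b", "B"), S("c", "C"), S("d", "D")],
            [R("r1", {"a"}, {"b"}), R("r2", {"c"}, {"d"})],
        )
        self.g2 = G(
            [S("a2", "A"), S("b2", "B"), S("a3", "A"), S("b3", "B"),
             S("c2", "C"), S("d2", "D")],
            [R("s1", {"a2"}, {"b2"}), R("s1b", {"a3"}, {"b3"}), R("s2", {"c2"}, {"d2"})],
        )
        self.pairs = all_pairs(self.g1, self.g2)

    def test_conflicting_species_mappings_are_incompatible(self):
        p = pair_by_chains(self.pairs, ("r1",), ("s1",))
        q = pair_by_chains(self.pairs, ("r1",), ("s1b",))
        assert not compatible(p, q)  # a -> b2 vs a -> b3

    def test_disjoint_pairs_are_compatible(self):
        p = pair_by_chains(self.pairs, ("r1",), ("s1",))
        q = pair_by_chains(self.pairs, ("r2",), ("s2",))
        assert compatible(p, q)

    def test_reaction_id_claimed_by_two_chains_is_incompatible(self):
        # doc1: A -r1-> B -r2-> C -r3-> D (names shared with doc2 in a way that
        # lets chain [r1,r2] and chain [r2,r3] both match distinct partners)
        g1 = G(
            [S("a", "A"), S("b", "Bq"), S("c", "C"), S("d", "D")],
            [R("r1", {"a"}, {"b"}), R("r2", {"b"}, {"c"}), R("r3", {"c"}, {"d"})],
        )
        g2 = G(
            [S("a2", "A"), S("c2", "C"), S("bb2", "Bq"), S("d2", "D")],
            [R("s1", {"a2"}, {"c2"}), R("s2", {"bb2"}, {"d2"})],
        )
        pairs = all_pairs(g1, g2)
        p = pair_by_chains(pairs, ("r1", "r2"), ("s1",))
        q = pair_by_chains(pairs, ("r2", "r3"), ("s2",))
        assert not compatible(p, q)  # r2 would belong to two distinct chains

    def test_no_self_compatibility(self):
        p = self.pairs[0]
        assert not compatible(p, p)

    def test_build_graph_examples(self):
        assert build_compatibility_graph([]).n_vertices == 0
        p = pair_by_chains(self.pairs, ("r1",), ("s1",))
        p_alt = pair_by_chains(self.pairs, ("r1",), ("s1b",))
        q = pair_by_chains(self.pairs, ("r2",), ("s2",))
        cg = build_compatibility_graph([p, p_alt, q])
        edges = {
            (i, j) for i in range(3) for j in cg.adjacency[i] if i < j
        }
        conflict = frozenset({cg.pairs.index(p), cg.pairs.index(p_alt)})
        assert len(edges) == 2 and conflict not in {frozenset(e) for e in edges}


class TestBronKerbosch:
    def test_triangle_has_one_maximal_clique(self):
        cg = CompatibilityGraph.from_adjacency(3, [(0, 1), (1, 2), (0, 2)])
        cliques, truncated = bron_kerbosch_v2(cg)
        assert cliques == [(0, 1, 2)] and not truncated

    def test_path_graph_cliques(self):
        cg = CompatibilityGraph.from_adjacency(3, [(0, 1), (1, 2)])
        cliques, _ = bron_kerbosch_v2(cg)
        assert sorted(cliques) == [(0, 1), (1, 2)]

    def test_isolated_vertices_are_maximal_singletons(self):
        cg = CompatibilityGraph.from_adjacency(2, [])
        cliques, _ = bron_kerbosch_v2(cg)
        assert sorted(cliques) == [(0,), (1,)]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_subset_oracle(self, seed):
        cg = random_compat_graph(random.Random(seed))
        cliques, truncated = bron_kerbosch_v2(cg)
        assert not truncated
        assert set(cliques) == brute_maximal_cliques(cg)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_networkx(self, seed):
        cg = random_compat_graph(random.Random(seed))
        nxg = nx.Graph()
        nxg.add_nodes_from(range(cg.n_vertices))
        nxg.add_edges_from((u, v) for u in range(cg.n_vertices) for v in cg.adjacency[u])
        expected = {tuple(sorted(c)) for c in nx.find_cliques(nxg)}
        assert set(bron_kerbosch_v2(cg)[0]) == expected

    def test_max_solutions_truncates_enumeration(self):
        cg = CompatibilityGraph.from_adjacency(6, [])  # six singleton cliques
        cliques, truncated = bron_kerbosch_v2(cg, SolverLimits(max_solutions=2))
        assert len(cliques) == 2 and truncated
        assert all(set(c) <= set(range(6)) for c in cliques)

    def test_zero_time_budget_returns_flagged_empty_result(self):
        cg = CompatibilityGraph.from_adjacency(4, [(0, 1), (2, 3)])
        cliques, truncated = bron_kerbosch_v2(cg, SolverLimits(max_time=0.0))
        assert truncated and cliques == []

    def test_invalid_limits_rejected(self):
        with pytest.raises(ParameterError):
            SolverLimits(max_solutions=0)
        with pytest.raises(ParameterError):
            SolverLimits(max_time=-1)


def solution_invariants(solution):
    """Pairwise compatibility and two-sided injectivity of all induced maps."""
    pairs = solution.pairs
    for i, p in enumerate(pairs):
        for q in pairs[i + 1 :]:
            assert compatible(p, q)
    for mapping in (solution.species_map, solution.compartment_map):
        assert len(set(mapping.values())) == len(mapping)
    chains1 = [cm.chain1 for cm in solution.chain_map]
    chains2 = [cm.chain2 for cm in solution.chain_map]
    assert len(set(chains1)) == len(chains1)
    assert len(set(chains2)) == len(chains2)
    claimed1 = [rid for c in chains1 for rid in c]
    claimed2 = [rid for c in chains2 for rid in c]
    assert len(set(claimed1)) == len(claimed1)
    assert len(set(claimed2)) == len(claimed2)


class TestIterativeOverlap:
    def test_identical_maps_score_one_with_identity_mapping(self, identical_pair):
        g1, g2 = load_pathway(identical_pair.doc1), load_pathway(identical_pair.doc2)
        solution = iterative_overlap(g1, g2, 3)
        scores = score_solution(g1, g2, solution)
        assert scores.s1 == scores.s2 == 1.0
        for sid1, sid2 in solution.species_map.items():
            assert g1.species(sid1).name == g2.species(sid2).name
        solution_invariants(solution)

    def test_extra_unmatched_reaction_forces_asymmetry(self):
        g1 = G([S(x) for x in "ABCD"],
               [R("r1", {"A"}, {"B"}), R("r2", {"B"}, {"C"}), R("r3", {"C"}, {"D"})])
        g2 = G([S(x + "2", x) for x in "ABCD"] + [S("E2", "E")],
               [R("s1", {"A2"}, {"B2"}), R("s2", {"B2"}, {"C2"}),
                R("s3", {"C2"}, {"D2"}), R("s4", {"D2"}, {"E2"})])
        solution = iterative_overlap(g1, g2, 3)
        scores = score_solution(g1, g2, solution)
        assert scores.s1 == 1.0
        assert scores.s2 == pytest.approx(0.75)

    def test_no_shared_names_yields_empty_solution(self):
        g1 = G([S("a", "A"), S("b", "B")], [R("r1", {"a"}, {"b"})])
        g2 = G([S("x", "X"), S("y", "Y")], [R("s1", {"x"}, {"y"})])
        solution = iterative_overlap(g1, g2, 3)
        assert solution.is_empty
        scores = score_solution(g1, g2, solution)
        assert scores.s1 == scores.s2 == 0.0

    def test_deterministic_under_fixed_inputs(self, identical_pair):
        g1, g2 = load_pathway(identical_pair.doc1), load_pathway(identical_pair.doc2)
        a = iterative_overlap(g1, g2, 3)
        b = iterative_overlap(g1, g2, 3)
        assert a == b

    def test_staged_score_bounded_by_exhaustive_clique_optimum(self, gap_pair):
        """The staged heuristic never beats the global optimum over all
        maximal cliques of the full compatibility graph, and attains it when
        the optimum uses only shortest-length pairs (as planted here)."""
        from pathoverlap.clique_solver import _build_solution

        g1, g2 = load_pathway(gap_pair.doc1), load_pathway(gap_pair.doc2)
        staged = iterative_overlap(g1, g2, 3)
        staged_total = sum(
            (lambda s: (s.s1, s.s2))(score_solution(g1, g2, staged))
        )
        cg = build_compatibility_graph(all_pairs(g1, g2))
        cliques, truncated = bron_kerbosch_v2(cg)
        assert not truncated
        best = max(
            sum(
                (lambda s: (s.s1, s.s2))(
                    score_solution(
                        g1, g2, _build_solution([cg.pairs[v] for v in c], g1, g2, None)
                    )
                )
            )
            for c in cliques
        )
        assert staged_total <= best + 1e-12
        assert staged_total == pytest.approx(best)
        solution_invariants(staged)
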