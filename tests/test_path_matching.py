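"""Species equivalence and path-matching rules (a), (b), (c)."""

import pytest

from pathoverlap.errors import ParameterError
from pathoverlap.path_matching import EquivalenceSpec, match_paths, species_equivalent
from pathoverlap.simple_paths import enumerate_simple_paths
from toyutil import G, R, S


def make_spec(**kwargs):
    frozen = {k: frozenset(v) for k, v in kwargs.items()}
    return EquivalenceSpec(**frozen)


class TestSpeciesEquivalence:
    def test_same_name_matches_by_default(self):
        assert species_equivalent(S("a1", "ATP"), S("b1", "ATP"))

    def test_whitespace_around_names_is_trimmed(self):
        assert species_equivalent(S("a1", " ATP "), S("b1", "ATP"))

    def test_allowed_pair_overrides_different_names(self):
        spec = make_spec(allowed_species={("g1", "p1")})
        assert species_equivalent(S("g1", "GeneX"), S("p1", "ProtX"), spec)

    def test_forbidden_pair_overrides_equal_names(self):
        spec = make_spec(forbidden_species={("a1", "b1")})
        assert not species_equivalent(S("a1", "ATP"), S("b1", "ATP"), spec)

    def test_nameless_species_only_match_via_allowed_list(self):
        nameless1, nameless2 = S("a1", None), S("b1", None)
        assert not species_equivalent(nameless1, nameless2)
        spec = make_spec(allowed_species={("a1", "b1")})
        assert species_equivalent(nameless1, nameless2, spec)

    def test_default_equivalence_is_symmetric(self):
        s1, s2 = S("a1", "ATP"), S("b1", "ATP")
        assert species_equivalent(s1, s2) == species_equivalent(s2, s1)

    def test_contradictory_spec_rejected(self):
        with pytest.raises(ParameterError):
            make_spec(allowed_species={("a", "b")}, forbidden_species={("a", "b")})

    def test_spec_round_trips_through_tsv(self, tmp_path):
        path = tmp_path / "rules.tsv"
        path.write_text(
            "# comment\n"
            "species\tallow\tg1\tp1\n"
            "species\tforbid\ta1\tb1\n"
            "chain\tforbid\tr1,r2\ts9\n"
        )
        spec = EquivalenceSpec.from_tsv(path)
        assert ("g1", "p1") in spec.allowed_species
        assert ("a1", "b1") in spec.forbidden_species
        assert (("r1", "r2"), ("s9",)) in spec.forbidden_chains


def _paths_and_graphs(g1, g2, n_max=3):
    return enumerate_simple_paths(g1, n_max), enumerate_simple_paths(g2, n_max), g1, g2


def matched_chain_pairs(pairs):
    return {(pp.chain1, pp.chain2) for pp in pairs}


class TestMatchRules:
    def setup_method(self):
        # doc1: A -r1-> B -r2-> C;  doc2: A' -s1-> X -s2-> Y -s3-> C'
        self.g1 = G([S("a", "A"), S("b", "B"), S("c", "C")],
                    [R("r1", {"a"}, {"b"}), R("r2", {"b"}, {"c"})])

    def g2(self, x_name="X"):
        return G(
            [S("a2", "A"), S("x2", x_name), S("y2", "Y"), S("c2", "C")],
            [R("s1", {"a2"}, {"x2"}), R("s2", {"x2"}, {"y2"}), R("s3", {"y2"}, {"c2"})],
        )

    def test_gap_mismatch_match_accepted_when_interiors_differ(self):
        pairs = match_paths(*_paths_and_graphs(self.g1, self.g2()))
        assert (("r1", "r2"), ("s1", "s2", "s3")) in matched_chain_pairs(pairs)

    def test_equivalent_intermediates_reject_the_long_match(self):
        pairs = match_paths(*_paths_and_graphs(self.g1, self.g2(x_name="B")))
        chains = matched_chain_pairs(pairs)
        assert (("r1", "r2"), ("s1", "s2", "s3")) not in chains
        # the two shorter subpath pairs are matched at their own lengths
        assert (("r1",), ("s1",)) in chains
        assert (("r2",), ("s2", "s3")) in chains

    def test_user_forbidden_chain_pair_suppressed(self):
        spec = make_spec(forbidden_chains={(("r1", "r2"), ("s1", "s2", "s3"))})
        pairs = match_paths(*_paths_and_graphs(self.g1, self.g2()), spec=spec)
        assert (("r1", "r2"), ("s1", "s2", "s3")) not in matched_chain_pairs(pairs)

    def test_allowed_chain_pair_exempts_rule_b(self):
        spec = make_spec(allowed_chains={(("r1", "r2"), ("s1", "s2", "s3"))})
        pairs = match_paths(*_paths_and_graphs(self.g1, self.g2(x_name="B")), spec=spec)
        assert (("r1", "r2"), ("s1", "s2", "s3")) in matched_chain_pairs(pairs)

    def test_cycle_only_matches_cycle(self):
        g1 = G([S("a", "A")], [R("r1", {"a"}, {"a"})])
        g2 = G([S("a2", "A"), S("c2", "A")], [R("s1", {"a2"}, {"c2"})])
        assert match_paths(*_paths_and_graphs(g1, g2)) == []

    def test_compartment_class_mismatch_rejected(self):
        # same-compartment path vs cross-compartment path with equal names
        g1 = G([S("a", "A", "cyto"), S("b", "B", "cyto")], [R("r1", {"a"}, {"b"})])
        g2 = G([S("a2", "A", "cyto"), S("b2", "B", "nucleus")], [R("s1", {"a2"}, {"b2"})])
        assert match_paths(*_paths_and_graphs(g1, g2)) == []

    def test_output_invariant_to_input_ordering(self):
        p1, p2, g1, g2 = _paths_and_graphs(self.g1, self.g2())
        assert match_paths(p1, p2, g1, g2) == match_paths(p1[::-1], p2[::-1], g1, g2)

    def test_matches_cartesian_product_filter_oracle(self):
        """Every returned pair passes the written rules; every passing
        combination is returned (endpoint equivalence, no equivalent
        interiors, cycle and compartment class consistency)."""
        p1, p2, g1, g2 = _paths_and_graphs(self.g1, self.g2(x_name="B"))
        got = {(pp.chain1, pp.chain2) for pp in match_paths(p1, p2, g1, g2)}
        expected = set()
        for p in p1:
            for q in p2:
                if g1.species(p.start).name != g2.species(q.start).name:
                    continue
                if g1.species(p.end).name != g2.species(q.end).name:
                    continue
                if (p.start == p.end) != (q.start == q.end):
                    continue
                interiors1 = {g1.species(x).name for x in p.interior}
                interiors2 = {g2.species(y).name for y in q.interior}
                if interiors1 & interiors2:
                    continue
                expected.add((p.chain, q.chain))
        assert got == expected
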