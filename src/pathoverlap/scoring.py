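"""Modifier mapping and the normalized overlap score.

Given a consistent solution E (a set of compatible matched path pairs), the
score of graph G1 is

    S(G1, E) = sum_{r in R1} w(r) / |R1|

where R1 is the set of retained reaction ids of G1 and the per-reaction weight

    w(r) = (|R_E(r)| + |P_E(r)| + |M_E(r)|) / (|R(r)| + |P(r)| + |M(r)|)

counts the fraction of r's reactants, products and modifiers whose species are
contained in E, i.e. appear in the species mapping E induces.  w(r) = 0 when
r's id belongs to no matched chain, 1 when every participant is mapped.  The
score lies in [0, 1], roughly measures how much of G1 is contained in G2, and
is in general asymmetric: S(G1, E) != S(G2, E).

Interior species of a gap-match that were never themselves mapped do not count
toward w(r): only species in the induced mapping are "contained in E".
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

from .errors import DegenerateGraphError
from .path_matching import EquivalenceSpec, species_equivalent
from .sbml_graph import PathwayGraph, Reaction

if TYPE_CHECKING:  # pragma: no cover
    from .clique_solver import MatchSolution

__all__ = [
    "OverlapScore",
    "map_modifiers",
    "reaction_weight",
    "overlap_score",
    "score_solution",
]


@dataclasses.dataclass(frozen=True)
class OverlapScore:
    """The two directed overlap scores of one solution."""

    s1: float
    s2: float

    def __post_init__(self) -> None:
        for value in (self.s1, self.s2):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"overlap score outside [0, 1]: {value}")


def matched_reaction_ids(solution: "MatchSolution", side: int) -> frozenset[str]:
    """Reaction ids claimed by any matched chain on one side (1 or 2)."""
    chains = (cm.chain1 if side == 1 else cm.chain2 for cm in solution.chain_map)
    return frozenset(rid for chain in chains for rid in chain)


def map_modifiers(
    solution: "MatchSolution",
    g1: PathwayGraph,
    g2: PathwayGraph,
    spec: EquivalenceSpec | None = None,
) -> "MatchSolution":
    """Extend a solution with a one-to-one mapping of modifiers.

    For every matched chain pair, equivalent modifiers of the two chains'
    reactions are paired greedily in sorted order, skipping any species already
    mapped (injectivity of the species map is never violated) and any pair
    whose compartments would break the one-to-one compartment mapping.
    Modifiers with no equivalent partner stay unmapped; that is not an error.
    """
    species_map = dict(solution.species_map)
    reverse_species = {v: k for k, v in species_map.items()}
    compartment_map = dict(solution.compartment_map)
    reverse_compartment = {v: k for k, v in compartment_map.items()}
    modifier_map = dict(solution.modifier_map)

    for cm in solution.chain_map:
        mods1 = sorted({m for rid in cm.chain1 for m in g1.reactions[rid].modifiers})
        mods2 = sorted({m for rid in cm.chain2 for m in g2.reactions[rid].modifiers})
        for m1 in mods1:
            if m1 in species_map:
                continue
            for m2 in mods2:
                if m2 in reverse_species:
                    continue
                if not species_equivalent(g1.species(m1), g2.species(m2), spec):
                    continue
                c1, c2 = g1.compartment(m1), g2.compartment(m2)
                if compartment_map.get(c1, c2) != c2 or reverse_compartment.get(c2, c1) != c1:
                    continue
                species_map[m1] = m2
                reverse_species[m2] = m1
                modifier_map[m1] = m2
                compartment_map[c1] = c2
                reverse_compartment[c2] = c1
                break
    return dataclasses.replace(
        solution,
        species_map=species_map,
        compartment_map=compartment_map,
        modifier_map=modifier_map,
    )


def reaction_weight(reaction: Reaction, solution: "MatchSolution", side: int = 1) -> float:
    """Matched-participant fraction w(r) of one reaction.

    Zero when the reaction's id is in no matched chain of its side; otherwise
    the fraction of its reactant/product/modifier species present in the
    induced species mapping.  The denominator is at least 2 because incomplete
    reactions never enter the graph.
    """
    if reaction.id not in matched_reaction_ids(solution, side):
        return 0.0
    mapped = (
        set(solution.species_map)
        if side == 1
        else set(solution.species_map.values())
    )
    numerator = sum(
        1
        for group in (reaction.reactants, reaction.products, reaction.modifiers)
        for sid in group
        if sid in mapped
    )
    denominator = len(reaction.reactants) + len(reaction.products) + len(reaction.modifiers)
    return numerator / denominator


def overlap_score(graph: PathwayGraph, solution: "MatchSolution", side: int = 1) -> float:
    """S(G, E): mean reaction weight over all retained reactions of ``graph``."""
    if not graph.reactions:
        raise DegenerateGraphError("overlap score is undefined on a graph with no reactions")
    weights = [reaction_weight(r, solution, side) for r in graph.reactions.values()]
    return sum(weights) / len(weights)


def score_solution(
    g1: PathwayGraph, g2: PathwayGraph, solution: "MatchSolution"
) -> OverlapScore:
    """Both directed scores of one solution."""
    return OverlapScore(
        s1=overlap_score(g1, solution, side=1),
        s2=overlap_score(g2, solution, side=2),
    )
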