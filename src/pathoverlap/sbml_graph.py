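"""SBML reading and the labeled-multidigraph model of an interaction map.

An SBML document declares *species* (entities with a unique ``id``, an optional
``name`` and a mandatory ``compartment``) and *reactions* (sets of reactants,
products and modifiers plus a reversibility flag).  The comparison algorithm
operates on a labeled multidigraph: every reaction is spliced into one directed
edge per (reactant, product) combination, labeled with the reaction id;
reversible reactions additionally contribute the reversed edges, carried with a
``reversed`` flag so chain-orientation constraints can be enforced later.
Modifiers are edge attributes (kept on the :class:`Reaction` record), never
traversal vertices; compartments are vertex attributes.

*Incomplete* reactions (empty reactant or product set) and *isolated* species
(participating in no retained reaction as reactant or product) are dropped from
the graph.  Only the SBML core components named above are read; kinetic laws,
rules, events and SBML packages are ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
from lxml import etree

from .errors import ConsistencyError, SBMLFormatError

__all__ = [
    "Species",
    "Reaction",
    "PathwayGraph",
    "parse_sbml",
    "build_graph",
    "load_pathway",
]


@dataclasses.dataclass(frozen=True, order=True)
class Species:
    """An SBML species: unique id, mandatory compartment, optional name.

    Distinct species may share a name (e.g. a gene and its protein); the name
    is the default equivalence key between two documents, the id never is.
    """

    id: str
    compartment: str
    name: str | None = None


@dataclasses.dataclass(frozen=True)
class Reaction:
    """An SBML reaction: reactant/product/modifier species-id sets.

    Set semantics: a species listed twice in one role counts once.  A reaction
    is *incomplete* iff it has no reactants or no products.
    """

    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    modifiers: frozenset[str] = frozenset()
    reversible: bool = False
    name: str | None = None

    @property
    def incomplete(self) -> bool:
        return not self.reactants or not self.products

    @property
    def participants(self) -> frozenset[str]:
        return self.reactants | self.products | self.modifiers


@dataclasses.dataclass
class PathwayGraph:
    """The spliced multidigraph of one SBML document.

    ``catalog`` holds every declared species (modifier-only species included,
    so they can be looked up for modifier mapping); ``reactions`` holds only
    complete reactions; ``graph`` holds only non-isolated species as nodes.
    """

    catalog: dict[str, Species]
    reactions: dict[str, Reaction]
    graph: nx.MultiDiGraph

    @property
    def vertex_ids(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def reaction_ids(self) -> frozenset[str]:
        """|R| of the normalized score: ids of all retained reactions."""
        return frozenset(self.reactions)

    def species(self, species_id: str) -> Species:
        return self.catalog[species_id]

    def compartment(self, species_id: str) -> str:
        return self.catalog[species_id].compartment

    def out_edges(self, species_id: str) -> Iterator[tuple[str, str, bool]]:
        """Yield (target species id, reaction id, reversed flag)."""
        for _, tgt, (rid, rev) in self.graph.out_edges(species_id, keys=True):
            yield tgt, rid, rev


def _localname(element) -> str:
    return etree.QName(element).localname


def _children(element, localname: str) -> list:
    return [
        child
        for child in element
        if isinstance(child.tag, str) and _localname(child) == localname
    ]


def _species_refs(reaction_el, list_name: str, ref_name: str) -> frozenset[str]:
    ids: set[str] = set()
    for lst in _children(reaction_el, list_name):
        for ref in _children(lst, ref_name):
            sid = ref.get("species")
            if sid is None:
                raise SBMLFormatError(
                    f"<{ref_name}> in reaction {reaction_el.get('id')!r} "
                    "lacks the mandatory species attribute"
                )
            ids.add(sid)
    return frozenset(ids)


def parse_sbml(document_path: str | Path) -> tuple[list[Species], list[Reaction]]:
    """Read one SBML (Level 2 / Level 3) document.

    Returns every declared species and reaction, unfiltered: incomplete
    reactions and isolated species are legal SBML and are only dropped by
    :func:`build_graph`.

    Raises
    ------
    OSError
        If the file cannot be read.
    SBMLFormatError
        On malformed XML or a missing mandatory attribute, naming the
        offending element.
    ConsistencyError
        If a species or reaction id is declared twice.
    """
    try:
        tree = etree.parse(str(document_path))
    except etree.XMLSyntaxError as exc:
        raise SBMLFormatError(f"{document_path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    if _localname(root) != "sbml":
        raise SBMLFormatError(
            f"{document_path}: root element is <{_localname(root)}>, expected <sbml>"
        )
    models = _children(root, "model")
    if not models:
        raise SBMLFormatError(f"{document_path}: <sbml> contains no <model> element")
    model = models[0]

    species: list[Species] = []
    seen_sids: set[str] = set()
    for lst in _children(model, "listOfSpecies"):
        for el in _children(lst, "species"):
            sid = el.get("id")
            if sid is None:
                raise SBMLFormatError("<species> element lacks the mandatory id attribute")
            compartment = el.get("compartment")
            if not compartment:
                raise SBMLFormatError(
                    f"<species id={sid!r}> lacks the mandatory compartment attribute"
                )
            if sid in seen_sids:
                raise ConsistencyError(f"species id {sid!r} declared twice")
            seen_sids.add(sid)
            species.append(Species(id=sid, compartment=compartment, name=el.get("name")))

    reactions: list[Reaction] = []
    seen_rids: set[str] = set()
    for lst in _children(model, "listOfReactions"):
        for el in _children(lst, "reaction"):
            rid = el.get("id")
            if rid is None:
                raise SBMLFormatError("<reaction> element lacks the mandatory id attribute")
            if rid in seen_rids:
                raise ConsistencyError(f"reaction id {rid!r} declared twice")
            seen_rids.add(rid)
            # SBML Level 2 core default for a missing reversible attribute is true.
            reversible = el.get("reversible", "true").lower() in ("true", "1")
            reactions.append(
                Reaction(
                    id=rid,
                    reactants=_species_refs(el, "listOfReactants", "speciesReference"),
                    products=_species_refs(el, "listOfProducts", "speciesReference"),
                    modifiers=_species_refs(
                        el, "listOfModifiers", "modifierSpeciesReference"
                    ),
                    reversible=reversible,
                    name=el.get("name"),
                )
            )
    return species, reactions


def build_graph(
    species: Iterable[Species], reactions: Iterable[Reaction]
) -> PathwayGraph:
    """Splice reactions into the labeled multidigraph.

    Every complete reaction ``r`` contributes exactly ``|R(r)|*|P(r)|`` forward
    edges (one per reactant-product combination) and the same number of
    reversed-flag edges iff it is reversible.  Duplicate (source, target,
    reaction, flag) edges arising from set semantics are collapsed; a species
    that is both reactant and product yields a self-loop edge.
    """
    catalog: dict[str, Species] = {}
    for sp in species:
        if sp.id in catalog:
            raise ConsistencyError(f"species id {sp.id!r} declared twice")
        catalog[sp.id] = sp

    retained: dict[str, Reaction] = {}
    edges: set[tuple[str, str, str, bool]] = set()
    for reaction in reactions:
        for sid in reaction.participants:
            if sid not in catalog:
                raise ConsistencyError(
                    f"reaction {reaction.id!r} references undeclared species {sid!r}"
                )
        if reaction.incomplete:
            continue
        if reaction.id in retained:
            raise ConsistencyError(f"reaction id {reaction.id!r} declared twice")
        retained[reaction.id] = reaction
        for src in reaction.reactants:
            for tgt in reaction.products:
                edges.add((src, tgt, reaction.id, False))
                if reaction.reversible:
                    edges.add((tgt, src, reaction.id, True))

    graph = nx.MultiDiGraph()
    used = {src for src, _, _, _ in edges} | {tgt for _, tgt, _, _ in edges}
    for sid in sorted(used):
        graph.add_node(sid, compartment=catalog[sid].compartment)
    for src, tgt, rid, rev in sorted(edges):
        graph.add_edge(src, tgt, key=(rid, rev), reaction=rid, reversed=rev)
    return PathwayGraph(catalog=catalog, reactions=retained, graph=graph)


def load_pathway(document_path: str | Path) -> PathwayGraph:
    """Parse an SBML file and build its pathway graph in one step."""
    return build_graph(*parse_sbml(document_path))
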