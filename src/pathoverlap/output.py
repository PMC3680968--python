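"""SBML and report writers for a computed overlap.

Four files describe the highest-scoring solution:

1. document 1 with all non-matched reactions removed — matched reactions are
   kept in their full definition, including unmatched participants;
2. the same for document 2;
3. the overlap document: every matched pair of reaction chains becomes a
   single merged reaction carrying only the matched reactants, products and
   modifiers (written with document-1 species ids);
4. a TSV report of the species / compartment / chain / modifier mappings and
   both overlap scores.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .clique_solver import MatchSolution, SolverLimits, UNBOUNDED
from .errors import ParameterError
from .sbml_graph import Reaction, Species, parse_sbml
from .scoring import OverlapScore, matched_reaction_ids

__all__ = ["RunConfig", "write_sbml", "write_outputs"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parameters of one comparison run."""

    doc1: Path
    doc2: Path
    n_max: int = 3
    spec_file: Path | None = None
    limits: SolverLimits = UNBOUNDED
    emit_sbml: bool = False
    output_prefix: Path | None = None

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ParameterError(f"maximum path length must be >= 1, got {self.n_max}")
        if self.emit_sbml and self.output_prefix is None:
            raise ParameterError("--emit-sbml requires an output prefix")


def write_sbml(
    path: str | Path,
    species: Iterable[Species],
    reactions: Iterable[Reaction],
    model_id: str = "model",
) -> Path:
    """Serialize species and reactions as an SBML Level 2 document.

    Elements are written in sorted id order, so identical inputs produce
    byte-identical files.  Empty lists are omitted, as SBML requires.
    """
    nsmap = {None: SBML_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="2", version="4")
    model = etree.SubElement(root, "model", id=model_id)
    species = sorted(set(species))
    reactions = sorted(set(reactions), key=lambda r: r.id)

    compartments = sorted({sp.compartment for sp in species})
    if compartments:
        loc = etree.SubElement(model, "listOfCompartments")
        for cid in compartments:
            etree.SubElement(loc, "compartment", id=cid)
    if species:
        los = etree.SubElement(model, "listOfSpecies")
        for sp in species:
            el = etree.SubElement(los, "species", id=sp.id, compartment=sp.compartment)
            if sp.name is not None:
                el.set("name", sp.name)
    if reactions:
        lor = etree.SubElement(model, "listOfReactions")
        for r in reactions:
            el = etree.SubElement(
                lor, "reaction", id=r.id, reversible="true" if r.reversible else "false"
            )
            if r.name is not None:
                el.set("name", r.name)
            for list_name, ref_name, ids in (
                ("listOfReactants", "speciesReference", r.reactants),
                ("listOfProducts", "speciesReference", r.products),
                ("listOfModifiers", "modifierSpeciesReference", r.modifiers),
            ):
                if not ids:
                    continue
                lst = etree.SubElement(el, list_name)
                for sid in sorted(ids):
                    etree.SubElement(lst, ref_name, species=sid)
    path = Path(path)
    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )
    return path


def _pruned_document(
    species: Sequence[Species], reactions: Sequence[Reaction], keep_ids: frozenset[str]
) -> tuple[list[Species], list[Reaction]]:
    kept = [r for r in reactions if r.id in keep_ids]
    participant_ids = {sid for r in kept for sid in r.participants}
    return [sp for sp in species if sp.id in participant_ids], kept


def _overlap_document(
    species1: Sequence[Species], reactions1: dict[str, Reaction], solution: MatchSolution
) -> tuple[list[Species], list[Reaction]]:
    mapped = set(solution.species_map)
    merged: list[Reaction] = []
    for index, cm in enumerate(solution.chain_map, start=1):
        reactants: set[str] = set()
        products: set[str] = set()
        modifiers: set[str] = set()
        for rid in cm.chain1:
            r = reactions1[rid]
            reactants |= r.reactants & mapped
            products |= r.products & mapped
            modifiers |= r.modifiers & mapped
        merged.append(
            Reaction(
                id=f"m{index}_" + "_".join(cm.chain1),
                reactants=frozenset(reactants),
                products=frozenset(products),
                modifiers=frozenset(modifiers),
                reversible=False,
                name=",".join(cm.chain1) + " ~ " + ",".join(cm.chain2),
            )
        )
    participant_ids = {sid for r in merged for sid in r.participants}
    return [sp for sp in species1 if sp.id in participant_ids], merged


def _write_report(
    path: Path, solution: MatchSolution, scores: OverlapScore
) -> Path:
    lines: list[str] = []
    lines.append("## SPECIES")
    for a, b in sorted(solution.species_map.items()):
        lines.append(f"{a}\t{b}")
    lines.append("## COMPARTMENTS")
    for a, b in sorted(solution.compartment_map.items()):
        lines.append(f"{a}\t{b}")
    lines.append("## CHAINS")
    for cm in solution.chain_map:
        orient = "reversed" if cm.reversed2 else "forward"
        lines.append(f"{','.join(cm.chain1)}\t{','.join(cm.chain2)}\t{orient}")
    lines.append("## MODIFIERS")
    for a, b in sorted(solution.modifier_map.items()):
        lines.append(f"{a}\t{b}")
    lines.append("## SCORES")
    lines.append(f"S1\t{scores.s1:.6f}")
    lines.append(f"S2\t{scores.s2:.6f}")
    lines.append(f"truncated\t{'true' if solution.truncated else 'false'}")
    if solution.is_empty:
        lines.append("# empty overlap: no consistent path matches were found")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_outputs(
    doc1: str | Path,
    doc2: str | Path,
    solution: MatchSolution,
    scores: OverlapScore,
    config: RunConfig,
) -> list[Path]:
    """Write the three SBML output documents and the mapping report.

    Returns the four paths, derived from ``config.output_prefix``:
    ``<prefix>_map1_matched.xml``, ``<prefix>_map2_matched.xml``,
    ``<prefix>_overlap.xml`` and ``<prefix>_mapping.tsv``.
    """
    if config.output_prefix is None:
        raise ParameterError("write_outputs requires an output prefix")
    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    species1, reactions1 = parse_sbml(doc1)
    species2, reactions2 = parse_sbml(doc2)

    out: list[Path] = []
    for tag, species, reactions, side in (
        ("map1_matched", species1, reactions1, 1),
        ("map2_matched", species2, reactions2, 2),
    ):
        kept_species, kept_reactions = _pruned_document(
            species, reactions, matched_reaction_ids(solution, side)
        )
        out.append(
            write_sbml(
                prefix.parent / f"{prefix.name}_{tag}.xml",
                kept_species,
                kept_reactions,
                model_id=tag,
            )
        )
    overlap_species, overlap_reactions = _overlap_document(
        species1, {r.id: r for r in reactions1}, solution
    )
    out.append(
        write_sbml(
            prefix.parent / f"{prefix.name}_overlap.xml",
            overlap_species,
            overlap_reactions,
            model_id="overlap",
        )
    )
    out.append(_write_report(prefix.parent / f"{prefix.name}_mapping.tsv", solution, scores))
    return out
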