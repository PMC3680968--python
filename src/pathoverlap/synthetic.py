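"""Synthetic SBML document pairs with planted, known overlaps.

The generator writes real SBML files so the parser and writers are exercised
end to end.  Document 1 is built on one of four topologies; document 2 clones
a *planted core* of its reactions — same species names and structure, fresh
ids — and pads the remainder with reactions over species whose names occur
nowhere else.  Because names are unique within each document and shared only
across the core, the planted identity mapping is the global optimum and its
scores have a closed form: every core reaction is fully matched (weight 1),
everything else is unmatched (weight 0), so

    s1 = k / n1,   s2 = k / n2,

with k planted reactions and n1, n2 retained reactions per document.

A separate gap fixture inserts one extra species mid-chain in document 2, so
one reaction of document 1 must match a two-reaction chain: s1 stays 1 while
the two gap reactions each score 1/2 on the document-2 side.

The module also maintains the degenerate edge-case documents (incomplete
reaction, isolated species, nameless species, self-loop, fully reversible
chain) used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import random
from pathlib import Path
from typing import NamedTuple

from .errors import ParameterError
from .output import write_sbml
from .sbml_graph import Reaction, Species

__all__ = [
    "FixtureParams",
    "PlantedOverlap",
    "ToyPair",
    "generate_toy_pair",
    "generate_gap_pair",
    "write_degenerate_documents",
]

TOPOLOGIES = ("linear", "branched", "cyclic", "random")
Chain = tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class FixtureParams:
    """Settings for one synthetic document pair.

    ``planted_fraction`` of document 1's reactions are cloned into document 2;
    ``extra_reactions2`` pads document 2 beyond the core (None: pad back to
    ``n_reactions``).  The same seed always yields byte-identical files.
    """

    n_species: int = 8
    n_reactions: int = 6
    planted_fraction: float = 1.0
    topology: str = "linear"
    reversible_fraction: float = 0.0
    modifier_rate: float = 0.0
    seed: int = 0
    extra_reactions2: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_reactions < 1:
            raise ParameterError("n_species and n_reactions must be >= 1")
        for name in ("planted_fraction", "reversible_fraction", "modifier_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {value}")
        if self.topology not in TOPOLOGIES:
            raise ParameterError(f"unknown topology {self.topology!r}")
        if self.planted_fraction > 0 and self.n_planted < 1:
            raise ParameterError(
                "planted_fraction > 0 but it rounds to zero planted reactions"
            )
        if self.extra_reactions2 is not None and self.extra_reactions2 < 0:
            raise ParameterError("extra_reactions2 must be >= 0 or None")
        needed = {
            "linear": self.n_reactions + 1,
            "branched": self.n_reactions + 1,
            "cyclic": self.n_reactions,
            "random": 2,
        }[self.topology]
        if self.n_species < needed:
            raise ParameterError(
                f"{self.topology} topology with {self.n_reactions} reactions "
                f"needs at least {needed} species, got {self.n_species}"
            )

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_fraction * self.n_reactions))


@dataclasses.dataclass(frozen=True)
class PlantedOverlap:
    """The known solution planted in a generated pair, with closed-form scores."""

    species_map: dict[str, str]
    chain_pairs: tuple[tuple[Chain, Chain], ...]
    s1: float
    s2: float | None


class ToyPair(NamedTuple):
    doc1: Path
    doc2: Path
    expected: PlantedOverlap


def _topology_reactions(params: FixtureParams, rng: random.Random) -> list[Reaction]:
    n = params.n_reactions
    reactions: list[tuple[set[int], set[int]]] = []
    if params.topology == "linear":
        reactions = [({i}, {i + 1}) for i in range(n)]
    elif params.topology == "cyclic":
        reactions = [({i}, {(i + 1) % n}) for i in range(n)]
    elif params.topology == "branched":
        for i in range(n):
            parent = rng.randrange(i + 1)  # attach species i+1 under an earlier one
            reactions.append(({parent}, {i + 1}))
    else:  # random
        for _ in range(n):
            reactants = set(rng.sample(range(params.n_species), rng.choice((1, 2))))
            products = set(rng.sample(range(params.n_species), rng.choice((1, 2))))
            reactions.append((reactants, products))
    out: list[Reaction] = []
    for i, (reactants, products) in enumerate(reactions):
        modifiers: set[int] = set()
        if rng.random() < params.modifier_rate:
            free = sorted(set(range(params.n_species)) - reactants - products)
            if free:
                modifiers.add(rng.choice(free))
        out.append(
            Reaction(
                id=f"xr{i}",
                reactants=frozenset(f"x{j}" for j in reactants),
                products=frozenset(f"x{j}" for j in products),
                modifiers=frozenset(f"x{j}" for j in modifiers),
                reversible=rng.random() < params.reversible_fraction,
            )
        )
    return out


def _clone(reaction: Reaction, new_id: str) -> Reaction:
    swap = lambda ids: frozenset("y" + sid[1:] for sid in ids)
    return Reaction(
        id=new_id,
        reactants=swap(reaction.reactants),
        products=swap(reaction.products),
        modifiers=swap(reaction.modifiers),
        reversible=reaction.reversible,
    )


def generate_toy_pair(params: FixtureParams, out_dir: str | Path) -> ToyPair:
    """Write a synthetic pair under ``out_dir`` and return paths plus the
    planted mapping and its closed-form scores."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(params.seed)

    species1 = [Species(id=f"x{i}", compartment="cell", name=f"N{i}") for i in range(params.n_species)]
    reactions1 = _topology_reactions(params, rng)

    k = params.n_planted
    core = reactions1[:k]
    clones = [_clone(r, f"yr{i}") for i, r in enumerate(core)]
    core_species_ids = sorted({sid for r in core for sid in r.participants})
    species2 = [
        Species(id="y" + sid[1:], compartment="cell", name=f"N{sid[1:]}")
        for sid in core_species_ids
    ]
    n_extra = (
        params.n_reactions - k if params.extra_reactions2 is None else params.extra_reactions2
    )
    extras: list[Reaction] = []
    for j in range(n_extra):
        species2.append(Species(id=f"z{j}", compartment="cell", name=f"Z{j}"))
        species2.append(Species(id=f"z{j}b", compartment="cell", name=f"Z{j}b"))
        extras.append(
            Reaction(id=f"zr{j}", reactants=frozenset({f"z{j}"}), products=frozenset({f"z{j}b"}))
        )

    doc1 = write_sbml(out_dir / f"pair{params.seed}_doc1.xml", species1, reactions1, "doc1")
    doc2 = write_sbml(out_dir / f"pair{params.seed}_doc2.xml", species2, clones + extras, "doc2")

    # Retained (complete) reaction counts; random topology cannot produce
    # incomplete reactions by construction, so these equal the list lengths.
    n1 = len(reactions1)
    n2 = len(clones) + len(extras)
    expected = PlantedOverlap(
        species_map={sid: "y" + sid[1:] for sid in core_species_ids},
        chain_pairs=tuple(((r.id,), (c.id,)) for r, c in zip(core, clones)),
        s1=k / n1,
        s2=(k / n2) if n2 else None,
    )
    return ToyPair(doc1, doc2, expected)


def generate_gap_pair(out_dir: str | Path, n_reactions: int = 4, seed: int = 0) -> ToyPair:
    """A linear pair where document 2 carries one gap species mid-chain.

    Document 1 is a chain of ``n_reactions``; document 2 is the same chain with
    the middle reaction split in two through a uniquely named gap species.  The
    planted solution matches every document-1 reaction (s1 = 1); the two gap
    reactions each have one unmapped participant, so s2 = n / (n + 1).
    """
    if n_reactions < 1:
        raise ParameterError("n_reactions must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = n_reactions
    mid = n // 2

    species1 = [Species(id=f"a{i}", compartment="cell", name=f"G{i}") for i in range(n + 1)]
    reactions1 = [
        Reaction(id=f"ar{i}", reactants=frozenset({f"a{i}"}), products=frozenset({f"a{i+1}"}))
        for i in range(n)
    ]
    species2 = [Species(id=f"b{i}", compartment="cell", name=f"G{i}") for i in range(n + 1)]
    species2.append(Species(id="bgap", compartment="cell", name="GAPX"))
    reactions2: list[Reaction] = []
    chain_pairs: list[tuple[Chain, Chain]] = []
    for i in range(n):
        if i == mid:
            reactions2.append(
                Reaction(id=f"br{i}a", reactants=frozenset({f"b{i}"}), products=frozenset({"bgap"}))
            )
            reactions2.append(
                Reaction(id=f"br{i}b", reactants=frozenset({"bgap"}), products=frozenset({f"b{i+1}"}))
            )
            chain_pairs.append(((f"ar{i}",), (f"br{i}a", f"br{i}b")))
        else:
            reactions2.append(
                Reaction(id=f"br{i}", reactants=frozenset({f"b{i}"}), products=frozenset({f"b{i+1}"}))
            )
            chain_pairs.append(((f"ar{i}",), (f"br{i}",)))

    doc1 = write_sbml(out_dir / f"gap{seed}_doc1.xml", species1, reactions1, "doc1")
    doc2 = write_sbml(out_dir / f"gap{seed}_doc2.xml", species2, reactions2, "doc2")
    expected = PlantedOverlap(
        species_map={f"a{i}": f"b{i}" for i in range(n + 1)},
        chain_pairs=tuple(chain_pairs),
        s1=1.0,
        s2=n / (n + 1),
    )
    return ToyPair(doc1, doc2, expected)


def write_degenerate_documents(out_dir: str | Path) -> dict[str, Path]:
    """One small SBML file per stated edge case, keyed by case name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell = "cell"
    docs: dict[str, tuple[list[Species], list[Reaction]]] = {}

    docs["incomplete_reaction"] = (
        [Species("s_a", cell, "A"), Species("s_b", cell, "B")],
        [
            Reaction("r_ok", frozenset({"s_a"}), frozenset({"s_b"}), reversible=False),
            Reaction("r_incomplete", frozenset({"s_b"}), frozenset(), reversible=False),
        ],
    )
    docs["isolated_species"] = (
        [Species("s_a", cell, "A"), Species("s_b", cell, "B"), Species("s_lone", cell, "LONE")],
        [Reaction("r_ok", frozenset({"s_a"}), frozenset({"s_b"}), reversible=False)],
    )
    docs["nameless_species"] = (
        [Species("s_a", cell, "A"), Species("s_b", cell, None), Species("s_c", cell, "C")],
        [
            Reaction("r1", frozenset({"s_a"}), frozenset({"s_b"}), reversible=False),
            Reaction("r2", frozenset({"s_b"}), frozenset({"s_c"}), reversible=False),
        ],
    )
    docs["self_loop"] = (
        [Species("s_a", cell, "A")],
        [Reaction("r_loop", frozenset({"s_a"}), frozenset({"s_a"}), reversible=False)],
    )
    docs["reversible_chain"] = (
        [Species("s_a", cell, "A"), Species("s_b", cell, "B"), Species("s_c", cell, "C")],
        [
            Reaction("r1", frozenset({"s_a"}), frozenset({"s_b"}), reversible=True),
            Reaction("r2", frozenset({"s_b"}), frozenset({"s_c"}), reversible=True),
        ],
    )
    return {
        name: write_sbml(out_dir / f"{name}.xml", species, reactions, name)
        for name, (species, reactions) in docs.items()
    }
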