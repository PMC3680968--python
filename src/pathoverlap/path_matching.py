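"""Species equivalence and simple-path matching.

Two species are equivalent by default when they carry the same name attribute
(exact string equality after trimming surrounding whitespace); a user-supplied
:class:`EquivalenceSpec` can allow extra pairs (e.g. a gene and an orthologous
protein) or forbid pairs that would otherwise match.  Species without a name
are equivalent only through an explicit allowed pair.

Two simple paths match when they are equivalent at the extremes, and

a) neither the species pair nor the reaction-chain pair is user-forbidden;
b) no intermediate species of one path is equivalent to an intermediate
   species of the other (such paths decompose into shorter matchable
   subpaths, which are matched at their own lengths instead);
c) the endpoint mapping is class-consistent: a cycle path only matches a
   cycle path, and the two induced compartment pairs are functional and
   injective (a same-compartment path only matches a same-compartment path).

Unmatched interior species are exactly how gaps and mismatches between the two
maps arise.  When every reaction of the second path is reversible, a
reversed-orientation match (start against end) is also attempted and recorded.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParameterError
from .sbml_graph import PathwayGraph, Species
from .simple_paths import SimplePath

__all__ = [
    "EquivalenceSpec",
    "PathPair",
    "species_equivalent",
    "match_paths",
]

Chain = tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class EquivalenceSpec:
    """User-defined allowed/forbidden matches between species and chains.

    Species pairs are (id in document 1, id in document 2); chain pairs are
    ordered reaction-id tuples, one per document.  A pair may not be both
    allowed and forbidden.
    """

    allowed_species: frozenset[tuple[str, str]] = frozenset()
    forbidden_species: frozenset[tuple[str, str]] = frozenset()
    allowed_chains: frozenset[tuple[Chain, Chain]] = frozenset()
    forbidden_chains: frozenset[tuple[Chain, Chain]] = frozenset()

    def __post_init__(self) -> None:
        clash = self.allowed_species & self.forbidden_species
        if clash:
            raise ParameterError(f"species pairs both allowed and forbidden: {sorted(clash)}")
        clash_chains = self.allowed_chains & self.forbidden_chains
        if clash_chains:
            raise ParameterError(f"chain pairs both allowed and forbidden: {sorted(clash_chains)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EquivalenceSpec":
        """Read rules from a TSV file.

        One rule per line: ``<species|chain> <allow|forbid> <lhs> <rhs>`` where
        chain sides are comma-separated reaction ids.  Blank lines and lines
        starting with ``#`` are skipped.
        """
        allowed_s, forbidden_s = set(), set()
        allowed_c, forbidden_c = set(), set()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParameterError(f"{path}:{lineno}: expected 4 tab-separated fields")
            kind, action, lhs, rhs = fields
            if kind not in ("species", "chain") or action not in ("allow", "forbid"):
                raise ParameterError(f"{path}:{lineno}: bad rule {kind!r} {action!r}")
            if kind == "species":
                (allowed_s if action == "allow" else forbidden_s).add((lhs, rhs))
            else:
                pair = (tuple(lhs.split(",")), tuple(rhs.split(",")))
                (allowed_c if action == "allow" else forbidden_c).add(pair)
        return cls(
            allowed_species=frozenset(allowed_s),
            forbidden_species=frozenset(forbidden_s),
            allowed_chains=frozenset(allowed_c),
            forbidden_chains=frozenset(forbidden_c),
        )


_EMPTY_SPEC = EquivalenceSpec()


@dataclasses.dataclass(frozen=True, order=True)
class PathPair:
    """A matched pair of equivalent simple paths.

    ``reversed2`` is True when ``path2`` is traversed end-to-start.
    ``species_pairs`` are the induced endpoint mappings (doc1 id, doc2 id);
    ``compartment_pairs`` the compartment mappings they induce.
    """

    path1: SimplePath
    path2: SimplePath
    reversed2: bool
    species_pairs: tuple[tuple[str, str], ...]
    compartment_pairs: tuple[tuple[str, str], ...]

    @property
    def chain1(self) -> Chain:
        return self.path1.chain

    @property
    def chain2(self) -> Chain:
        return self.path2.chain

    @property
    def max_length(self) -> int:
        return max(self.path1.length, self.path2.length)


def species_equivalent(
    s1: Species, s2: Species, spec: EquivalenceSpec | None = None
) -> bool:
    """Default name equivalence, overridden by the user lists."""
    spec = spec or _EMPTY_SPEC
    pair = (s1.id, s2.id)
    if pair in spec.allowed_species:
        return True
    if pair in spec.forbidden_species:
        return False
    if s1.name is None or s2.name is None:
        return False
    return s1.name.strip() == s2.name.strip()


def _one_to_one(pairs: Iterable[tuple[str, str]]) -> bool:
    fwd: dict[str, str] = {}
    bwd: dict[str, str] = {}
    for a, b in pairs:
        if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
            return False
    return True


def _chain_listed(
    chain1: Chain, chain2: Chain, listed: frozenset[tuple[Chain, Chain]]
) -> bool:
    return (chain1, chain2) in listed or (chain1, chain2[::-1]) in listed


def _try_match(
    p: SimplePath,
    q: SimplePath,
    reversed2: bool,
    g1: PathwayGraph,
    g2: PathwayGraph,
    spec: EquivalenceSpec,
) -> PathPair | None:
    q_start, q_end = (q.end, q.start) if reversed2 else (q.start, q.end)
    # rule (c), cycle class: a cycle only matches a cycle
    if p.is_cycle != q.is_cycle:
        return None
    if not species_equivalent(g1.species(p.start), g2.species(q_start), spec):
        return None
    if not species_equivalent(g1.species(p.end), g2.species(q_end), spec):
        return None
    # rule (a), chain level
    if _chain_listed(p.chain, q.chain, spec.forbidden_chains):
        return None
    compartment_pairs = {
        (g1.compartment(p.start), g2.compartment(q_start)),
        (g1.compartment(p.end), g2.compartment(q_end)),
    }
    # rule (c), compartment class: the pair's own compartment mapping must be
    # one-to-one (same-compartment paths only match same-compartment paths)
    if not _one_to_one(compartment_pairs):
        return None
    # rule (b): equivalent intermediate species mean matchable subpaths exist
    if not _chain_listed(p.chain, q.chain, spec.allowed_chains):
        for x in p.interior:
            for y in q.interior:
                if species_equivalent(g1.species(x), g2.species(y), spec):
                    return None
    species_pairs = {(p.start, q_start), (p.end, q_end)}
    return PathPair(
        path1=p,
        path2=q,
        reversed2=reversed2,
        species_pairs=tuple(sorted(species_pairs)),
        compartment_pairs=tuple(sorted(compartment_pairs)),
    )


def match_paths(
    paths1: Sequence[SimplePath],
    paths2: Sequence[SimplePath],
    g1: PathwayGraph,
    g2: PathwayGraph,
    spec: EquivalenceSpec | None = None,
) -> list[PathPair]:
    """All matched pairs between two path collections, sorted.

    Forward matches pair start with start; a reversed match (start with end) is
    additionally attempted when every reaction of the second chain is
    reversible, so the reversed chain is an actual path.  Duplicates that
    induce identical mappings are collapsed, and the result is independent of
    the input ordering.
    """
    spec = spec or _EMPTY_SPEC
    pairs: set[PathPair] = set()
    for p in paths1:
        for q in paths2:
            pair = _try_match(p, q, False, g1, g2, spec)
            if pair is not None:
                pairs.add(pair)
            if not q.is_cycle and all(g2.reactions[rid].reversible for rid in q.chain):
                pair = _try_match(p, q, True, g1, g2, spec)
                if pair is not None:
                    pairs.add(pair)
    return sorted(pairs)
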