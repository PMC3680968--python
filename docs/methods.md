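# Methods

## Graph model

A pathway is the labeled multidigraph of its SBML document. A reaction with
reactant set R(r) and product set P(r) is spliced into |R(r)|·|P(r)| directed
edges labeled with the reaction id; a reversible reaction also contributes the
|R(r)|·|P(r)| reversed edges, each carrying a reversed flag so that later
stages can tell which orientation a chain was traversed in. Participant sets
have set semantics: a species listed twice in one role counts once, and a
species that is both reactant and product yields a self-loop edge. Modifiers
are not traversal vertices — they are attributes of the reaction, looked up
again when modifiers of matched chains are paired and when reactions are
scored. Incomplete reactions (empty reactant or product set) and isolated
species are dropped from the graph, but every declared species stays in the
document catalog so modifier-only species can still be name-compared.

Parsing accepts SBML Level 2 and Level 3 documents and reads only species,
compartments, reactions, species references and the reversibility flag;
kinetic laws, rules, events and SBML packages are ignored. A missing
`reversible` attribute defaults to true, the Level 2 core default.

## Simple paths

Path length is counted in reactions. For each source species, a layered
breadth-first expansion grows walks one reaction at a time, pruning any
extension that reuses a reaction id. The first layer at which a target is
reached fixes the minimal length for that ordered pair; all distinct
(chain, interior) realizations at that layer are kept. Consequences of this
definition that the implementation commits to:

- minimality is per ordered (start, end) pair; a cycle (u, u) competes only
  against other cycles on u;
- species may repeat inside a walk as long as reaction ids do not — a "valid
  path" is any directed walk over spliced edges with distinct reaction ids;
- forward and reversed-flag edges may mix inside one chain.

The default maximum length N = 3 reflects the tool's intended use: longer
chains dilute endpoint equivalence into near-arbitrary matches and inflate
the compatibility graph. N is a CLI flag (`-n/--max-path-length`).

## Matching rules

Endpoint equivalence is exact, case-sensitive name equality after trimming
surrounding whitespace — the conservative reading of "same name". The user
list overrides it in both directions: allowed pairs match regardless of
names, forbidden pairs never match. Allowed pairs are not closed
transitively: each listed pair stands alone. Chain-level rules: a forbidden
chain pair suppresses the match in either traversal orientation; an allowed
chain pair exempts that pair from the equivalent-intermediates rejection
(endpoint equivalence is still required) — the list file format is a plain
TSV, one rule per line.

Start maps to start and end to end; additionally, when every reaction of the
second chain is reversible, the reversed pairing (start against end) is
attempted and recorded, since the reversed chain is then itself a realizable
path. The equivalent-intermediates rule is evaluated on interior species
only, endpoints excluded. Compartment consistency at the pair level requires
the pair's own two compartment correspondences to be functional and injective;
consistency *across* pairs is the compatibility graph's job.

## Staged clique solving

Two path pairs are compatible when the union of their induced mappings stays
one-to-one on species, compartments and chains, and no reaction id is claimed
by two distinct chains (a chain and its reversed tuple are canonicalized to
one key). Maximal cliques are enumerated with the pivoting Bron–Kerbosch
variant; the pivot is the vertex of P ∪ X with the most neighbours in P
(smallest index on ties) and candidates expand in index order, making the
enumeration deterministic.

The solver accumulates: at stage i = 1..N the candidates are the pairs of
maximum chain length i compatible with everything already accepted; the
cliques of the subgraph they induce are enumerated and the best is folded in.
Ranking is by summed provisional score S(G1)+S(G2) (with modifier mapping
applied), then clique size, then lexicographically smallest vertex set. This
stage-by-stage accumulation — rather than re-solving globally as longer pairs
arrive — is a deliberate design choice: it keeps each clique instance small
and gives shortest (safest) matches strict priority, at the cost of global
optimality. The test suite checks on planted instances that the staged result
never exceeds the exhaustive-clique optimum and attains it when the optimum
uses only shortest-length pairs.

Limits: `max_solutions` bounds enumerated cliques per stage; `max_time` is
split evenly across the N stages, and a stage that exhausts its share keeps
its best-so-far. Both default to unbounded. With a time bound, results can
vary with machine load; with only `max_solutions`, runs are deterministic.

Modifier mapping runs after clique selection, per matched chain pair in
sorted order, greedily pairing equivalent, not-yet-mapped modifiers. A pair
is skipped when it would break species- or compartment-map injectivity; the
compartment map is extended by accepted modifier pairs.

## Scoring conventions

"Contained in E" means: the species appears in the induced species mapping
(as a path endpoint or a mapped modifier) *and* the reaction's id lies in a
matched chain. Interior species of a gap-match that were never themselves
mapped do not count toward w(r). The denominator of w(r) is at least 2
because incomplete reactions never enter the graph; a graph with zero
retained reactions has no defined score and raises a degenerate-input error.

## Outputs

Three SBML documents and a TSV report describe the best solution found: the
two inputs pruned to their matched reactions (kept in full definition,
unmatched participants included), and an overlap document in which each
matched chain pair becomes one merged reaction (id `m<k>_<chain1 ids>`,
doc1-side species ids, only matched participants; the report ties them to
doc2 ids). The overlap document preserves document-1 compartments. A merged
reaction for a chain traversed only against its declared direction can have
an empty reactant list; the file remains well-formed and re-parseable.

## Synthetic data

The generator emulates a curated pathway pair with a known shared core: one
document on a linear / branched / cyclic / random topology, unique species
names, single compartment; a planted fraction of its reactions cloned into
the second document (same names and structure, fresh ids) and padded with
reactions over species named disjointly from everything else. Because names
are unique and shared only across the core, the planted identity mapping is
the unique optimum and the closed-form scores are k/n1 and k/n2 for k planted
reactions. Reversible reactions and modifiers are sprinkled at configurable
rates; a separate fixture splits one reaction through an inserted gap
species, and a maintained set of degenerate documents covers incomplete
reactions, isolated species, nameless species, self-loops and fully
reversible chains. Fixtures are written as real SBML files so parser and
writers are exercised end to end; identical seeds yield byte-identical files.

What the generator does *not* emulate: the heavy reuse of ubiquitous
small molecules (ATP, H2O) across unrelated curated maps, many-compartment
localization, duplicated names within one document, and map sizes in the
hundreds of reactions. Passing tests therefore demonstrate correctness of
the algorithmic machinery on planted ground truth, not retrieval quality on
a real database; the benchmark harness accepts any directory of SBML maps
with a shared reaction-id namespace for that purpose. Test and acceptance
problem sizes (≤ 10 reactions per map, five-map benchmark, 200-graph oracle
sweeps) were chosen so the planted optima are exactly checkable by brute
force.

## Known limitations

- The staged heuristic can miss overlaps whose optimal explanation uses only
  long chains that conflict with locally optimal short ones.
- Path enumeration stores all minimal walks explicitly; dense multidigraphs
  with large N can make this the memory bottleneck before clique solving
  becomes the time bottleneck.
- Name-based default equivalence is brittle across databases with different
  naming conventions; the allowed/forbidden lists are the intended escape
  hatch, and no sequence-similarity fallback is provided.
- The shared-reaction gold standard in the benchmark is meaningful only when
  the compared documents genuinely share a reaction-id namespace.
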