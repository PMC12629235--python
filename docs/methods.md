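# Methods

## Data model

A mapping is a directed triple *(subject, predicate, object)* over
CURIE-identified entities. Directionality is modeled explicitly even for
symmetric predicates — *(A, exactMatch, B)* and *(B, exactMatch, A)* are
distinct mappings — because provenance attaches to the direction a source
actually published. Each unique triple carries a non-empty evidence set;
ingesting a duplicate triple merges evidence (deduplicated by content
hash) rather than duplicating the triple. Evidence comes in two forms:

- **simple evidence** — a provenance leaf: a justification term from a
  SEMAPV-style vocabulary, an optional ORCID author, an optional producer
  confidence, and a reference to the mapping set it came from (name,
  version, license, consumer confidence);
- **reasoned evidence** — an inference node: the operation (inversion,
  mutation, chain, prioritization), an operation factor γ, and ordered
  pointers to the supporting mappings. Provenance forms a DAG; confidence
  evaluation carries an active-set guard and raises on cycles.

## Confidence calculus

Confidences are probabilities of correctness, combined as independent
events (noisy-OR):

- simple evidence: c_e = 1 − (1 − c_MappingSet)(1 − c_Producer). A missing
  producer confidence is represented as *absent*, not as a number, and the
  fallback branch returns c_MappingSet exactly — numerically identical to
  assuming 1.0, but auditable.
- mapping: c_m = 1 − ∏_e (1 − c_e): the probability that at least one
  evidence is correct. Monotone in each factor and under evidence growth.
- reasoned evidence: c_e = γ_op (1 − ∏_m (1 − c_m)) over supports.

A chain's supports are the path's mappings, combined by the same noisy-OR.
An alternative reading would multiply confidences along the path
(AND-semantics for a chain); we keep the single-formula model, expose γ as
the per-operation discount, and note that a consumer who wants AND-like
behavior can lower γ_chain.

Default γ values: inversion 1.0 (logically lossless), chain 1.0, mutation
per rule — generalizations (e.g. owl:equivalentClass → skos:exactMatch)
default to 1.0, while strengthenings (cross-reference → exact, has-gene-
product → exact) have no default and must be given explicitly, since they
encode risky prior knowledge the user should own.

## Content hashing

SHA-256 over a canonical UTF-8 serialization: a type tag plus `tag=value`
fields joined by `|`, with `\` and `|` backslash-escaped inside values,
absent optionals as the empty string, and floats via `repr`. The exact
record layouts are documented in `src/semmap/model.py`. A mapping's hash
covers only its triple, so evidence accrual never changes mapping
identity (required for merging); evidence hashes cover full content
including the mapping-set hash; mapping-set hashes cover
name/version/license but not consumer confidence, which is the consumer's
annotation rather than the set's content. The algorithm name is recorded
in exported metadata so digests are comparable across implementations.

## Prefix registry and vocabulary

CURIEs are validated against a pluggable prefix registry; the default is
a small frozen JSON shipped with the package (common vocabulary prefixes,
a handful of widely used resource prefixes, and reserved synthetic test
prefixes), so no network access is ever needed. Prefixes normalize
through a case-insensitive synonym table to a canonical form; local
identifiers pass through verbatim — validation, not rewriting. The
predicate vocabulary (SKOS match predicates, OWL equivalences, the
low-precision database cross-reference, has-gene-product and its inverse)
ships as editable JSON with an involutive inverse table.

## Inference

Built on a networkx `MultiDiGraph` (edge key = predicate CURIE), iterated
in lexicographic CURIE order so all outputs are byte-stable.

- **Inversion** adds *(B, inverse(p), A)* for every edge lacking its
  counterpart; a second pass is a fixpoint.
- **Mutation** adds a parallel edge with the target predicate for every
  edge matching a rule (optionally scoped to a subject/object prefix
  pair).
- **Chaining** runs a depth-first enumeration of simple paths (no node
  revisited) of length 2..`max_path_length` (default 5), folding the
  predicate-composition table left to right and pruning dead
  compositions. Each ordered node pair reached by a composable path and
  not already directly connected by the composed predicate gains one
  mapping; every distinct supporting path attaches its own reasoned
  evidence, so equally long paths contribute symmetrically and the
  resulting confidence is independent of discovery order. Negative
  triples are never traversed and never emitted.

The composition table (shipped as editable JSON) follows community
chaining conventions: exact is the identity element among match
predicates; broad and narrow absorb exact and self-compose; broad∘narrow
and narrow∘broad compose to nothing; close/related compose only with
exact; the database cross-reference composes with nothing and must be
mutated to a match predicate first.

Chaining is a single pass over the pre-inference edge set, which matches
an exhaustive path-enumeration oracle exactly. Consequently "process
twice is a fixpoint" holds when `max_path_length` covers the diameter of
each exact-match component — true for all shipped configurations; for
larger graphs the pipeline can simply be run again to close longer
compositions.

"Resolution of conflicting mappings" during traversal is deliberately
deferred: a node pair receiving both exact and non-exact composed
predicates keeps both triples, and the cardinality/confidence filters
adjudicate afterwards.

## Filters and QA

Prefix filters remove mappings by subject prefix, object prefix, or
prefix pair (e.g. forbidding disease→gene mappings). The confidence
filter removes mappings with c_m below a threshold. Negative triples are
removed wherever present and excluded as chain steps. All filters return
(retained, removed) partitions.

Cardinality QA flags each (entity, target prefix) with more than one
exact-match partner in that prefix. Flagging is the default — these
groups need curation, and auto-deleting a heuristic subset would bake in
errors — with an opt-in mode that deletes whole violating groups.
Assessment is directional by default, matching the graph model; an
undirected mode serves symmetric predicates before inversion. The report
is a TSV with a violation-group key, designed to be hand-edited into a
negatives file (SSSOM with `predicate_modifier = Not`).

Stage order (mutations → inversions → chains → filters) is explicit in
the pipeline configuration rather than fixed; cardinality QA can be
placed before or after inference by the user.

## Assembly

"Clique" means a connected component of the exact-match subgraph:
chaining turns components into true cliques, and component semantics
tolerate incomplete closure. Prioritization elects as canonical the member
whose prefix appears earliest in the priority list, assuming at most one
entity per prefix per clique; on violation the default is a hard error,
with configurable fallbacks (demote to the highest-priority *singleton*
prefix, or skip the clique). Every member maps to the canonical entity
(the canonical to itself), giving a star graph per clique; a structural
checker asserts this on every output. Entities in no exact-match mapping
enter only when a full term list is supplied (`extra_terms`), otherwise
totals are lower bounds, and weaker-than-exact edges are ignored for
clique membership.

Projection sets collect exact matches (direct or inferred) for one
ordered prefix pair; subjects with several targets are excluded and
reported, so the output is functional and prefix-pure by construction.

Consolidation metrics: raw = distinct entities in any mapping, unique =
raw − (clique members − cliques), reduction = (raw − unique)/raw as a
percentage.

## SSSOM dialect and property-graph export

SSSOM TSV is read with an optional leading `#`-prefixed embedded YAML
metadata block (prefix map, set metadata); an external defaults object is
also accepted. One row per (mapping, evidence) pair on write; rows are
sorted so files are byte-stable. Standard SSSOM has no slot for
multi-mapping inference provenance, so reasoned rows use extension
columns (`evidence_type`, `reasoning_operation`, `reasoning_factor`,
`supporting_mapping_hashes`); on read, reasoned rows resolve their
supports within the document iteratively, so chains over inferred
mappings round-trip. Unknown columns pass through untouched. Strictness:
fail-fast with line numbers in library mode, skip-and-log in pipeline
mode. Projection and prioritization sets also export as two-column TSV —
the compact tabular form used for bulk remapping.

The property-graph layout writes four node files (concepts, mappings,
evidences, mapping sets, keyed by CURIE or hash) and four edge files
(concept–concept mapping edges, mapping→evidence, evidence→mapping-set,
reasoned-evidence→support), referentially closed, plus a `metadata.json`
naming the hash algorithm.

## Synthetic fixtures

The generator plants equivalence cliques (default 10 cliques over 6
prefixes, sizes 2–5, at most one entity per prefix) and emits, per source
(one source per subject prefix), a random spanning tree of each clique —
sparse by design, so recovery genuinely requires inversion and chaining.
Noise modes, all off by default and seed-controlled: edge dropout,
wrong edges fusing two cliques (the failure mode cardinality QA must
catch), many-to-many planting (a duplicate term in the target prefix),
and demotion of exact edges to cross-references (recoverable only via a
mutation rule). Consumer confidence defaults to 0.9, a realistic level of
trust in a curated source. Ground-truth raw/unique/reduction numbers are
derived from the *emitted* edges with an independent union-find, so they
remain honest under noise; with zero noise they equal the planted cliques
exactly. The generator emulates landscape fragmentation and multi-source
provenance; it does not emulate lexical similarity, hierarchical
structure, or realistic identifier schemes of any particular resource, so
passing tests demonstrate correctness of assembly logic, not performance
on any specific real resource.

A hard-coded six-resource toy landscape (`fig1_toy`) reproduces the
canonical motivating situation: one entity known to a registry, an
ontology, a tissue vocabulary, two clinical databases, and an
experimental-factor vocabulary, connected only by sparse directed
cross-references, where the ontology/tissue equivalence requires mutation,
inversion, and a two-step chain.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen to finish
in seconds while exercising every code path: 10,000 random draws for the
confidence calculus (checked against brute-force Bernoulli enumeration at
1e−12, far above accumulated float error), 500 random graphs of ≤12 nodes
for closure (exact set equality against path enumeration), 100 seeds for
planted-clique recovery, and 3–20 seeds for I/O and QA properties.
Confidence comparisons in tests use absolute tolerances (1e−12/1e−15);
ties in prioritization and iteration order everywhere are broken
lexicographically by CURIE. Degenerate inputs are defined: empty documents
round-trip to header-only files, empty evidence sets are rejected at
construction, and zero-entity metrics report a reduction of 0%.

## Limitations

- Chaining cost grows with path enumeration; the default
  `max_path_length` of 5 with the no-revisit guard keeps it tractable on
  desk-scale graphs but is not tuned for multi-million-edge assemblies.
- No OWL/RDF parsing, lexical mapping prediction, alternative-identifier
  or replaced-by handling; importers beyond SSSOM and bare cross-reference
  TSV are left to the plug-in contract (any function returning a
  `MappingDocument`).
- Cardinality QA identifies inconsistent groups but does not adjudicate
  them; resolution is a curation task by design.
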