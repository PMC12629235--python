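# semmap

Assembly and reasoning over biomedical semantic mappings.

Hundreds of ontologies and databases assign identifiers to the same
biomedical concepts — genes, diseases, cell lines, chemicals — and the
mappings between them are incomplete, fragmented across sources, and often
published with imprecise semantics (a bare database cross-reference rather
than an asserted equivalence). Integrating data keyed to different
identifier spaces therefore requires *assembling* mappings: collecting them
from many sources, inferring the links the sources never state directly,
flagging the links that would make integration inconsistent, and choosing
one canonical identifier per concept.

`semmap` is a toolkit for exactly that. It is aimed at data engineers and
ontologists building knowledge graphs, harmonizing datasets, or maintaining
identifier-mapping resources.

## The model

A mapping is a directed triple *(s, p, o)* between CURIE-identified
entities, with *p* drawn from a SKOS-style predicate vocabulary
(`skos:exactMatch`, `skos:broadMatch`, `oboinowl:hasDbXref`, ...). Each
unique triple carries one or more **evidences**: simple evidences record a
source mapping set (name, version, license, and the consumer's confidence
in it) and optionally the producer's own confidence; reasoned evidences
record an inference step and point at the mappings it consumed.

Confidence propagates as independent-event probabilities (noisy-OR):

- simple evidence: c_e = 1 − (1 − c_MappingSet)(1 − c_Producer), falling
  back to c_MappingSet exactly when no producer confidence is given;
- mapping: c_m = 1 − ∏_{e∈E} (1 − c_e), the probability that at least one
  supporting evidence is correct;
- reasoned evidence: c_e = γ_op · (1 − ∏_{m∈M} (1 − c_m)) over its
  supporting mappings, with γ_op an operation-specific factor.

Three inference operations run over the directed mapping graph:
**inversion** adds the reverse edge under the inverse predicate,
**mutation** adds a parallel edge with a replaced predicate under
configured rules (e.g. upgrading cross-references known to be exact), and
**chaining** composes predicates along simple paths under a composition
table (exact∘exact = exact, exact∘broad = broad, ...). Filters remove
mappings by prefix, by confidence, or by curated negative triples, and a
cardinality QA flags entities with exact matches to more than one entity
in a single target prefix.

Two outputs support integration: **projection sets** (a functional map
from one prefix onto another) and **prioritization sets**, which partition
the exact-match graph into cliques of equivalent entities and map every
member onto the clique's canonical entity — the one whose prefix comes
earliest in a priority list — forming a star graph per clique. The
consolidation achieved is reported as raw/unique term counts and a
reduction percentage: unique = raw − (clique members − cliques).

Every mapping, evidence, and mapping set has a deterministic SHA-256
content hash (canonical serialization documented in
`src/semmap/model.py`), used for deduplication and cross-file provenance.

## Worked example

The shipped demo (`configs/demo.yaml`) processes a toy landscape in which
one cell line is known to six resources but linked only by sparse,
directed, mostly low-precision cross-references — there is no direct link
between the tissue vocabulary (`tis`) and the ontology (`ont`):

```console
$ assemble run configs/demo.yaml
mappings: 38
raw terms: 6
unique terms: 1
cliques: 1
reduction: 83.3%
```

Six raw terms collapse into a single clique (reduction 5/6 = 83.3%): the
pipeline upgraded cross-references to exact matches, added reverse edges,
and chained across the registry hub. The projection output now contains
the `tis`→`ont` equivalence no source stated, with chaining provenance:

```console
$ grep -v "^#" configs/out/tis_to_ont.sssom.tsv | cut -f1-4
subject_id      predicate_id    object_id       mapping_justification
tis:0001        skos:exactMatch ont:0001        semapv:MappingChaining
tis:0001        skos:exactMatch ont:0001        semapv:MappingChaining
```

(two rows: one per supporting chain), and the prioritization table sends
every identifier to the top-priority prefix `exp`:

```console
$ head -4 configs/out/prioritization.tsv
subject_id      object_id
dep:ACH-000001  exp:0001
enc:1321N1      exp:0001
exp:0001        exp:0001
```

Other CLI verbs: `assemble io convert`, `assemble qa cardinality`,
`assemble standardize`, `assemble fixtures generate`. The same
functionality is available as a library (`import semmap`).

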