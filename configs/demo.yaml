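# Desk-scale demo: the six-resource toy cell-line landscape.
#
# The toy landscape holds one underlying cell line known to six resources,
# linked only by sparse directed cross-references.  The pipeline upgrades
# cross-references to exact matches, adds reverse edges, chains across
# resources, and prioritizes every identifier onto the experimental-factor
# vocabulary.  Expected outcome: one clique of six entities (reduction
# 83.3%), including a tissue-vocabulary/ontology equivalence that exists in
# no input and needs a two-step chain.
schema_version: 1
inputs:
  - kind: fig1_toy
mutations:
  - source_predicate: "oboinowl:hasDbXref"
    target_predicate: "skos:exactMatch"
    confidence_factor: 0.7
max_path_length: 5
priority: [exp, reg, ont, tis, enc, dep]
outputs:
  - format: sssom
    path: out/processed.sssom.tsv
  - format: prioritization
    path: out/prioritization.tsv
  - format: projection
    path: out/tis_to_ont.sssom.tsv
    source_prefix: tis
    target_prefix: ont
  - format: qa_cardinality
    path: out/cardinality_qa.tsv
  - format: report
    path: out/report.json
seed: 0
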