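{
  "predicates": [
    {"curie": "skos:exactMatch", "label": "exact match", "inverse": "skos:exactMatch"},
    {"curie": "skos:closeMatch", "label": "close match", "inverse": "skos:closeMatch"},
    {"curie": "skos:relatedMatch", "label": "related match", "inverse": "skos:relatedMatch"},
    {"curie": "skos:broadMatch", "label": "broad match", "inverse": "skos:narrowMatch"},
    {"curie": "skos:narrowMatch", "label": "narrow match", "inverse": "skos:broadMatch"},
    {"curie": "owl:equivalentClass", "label": "equivalent class", "inverse": "owl:equivalentClass"},
    {"curie": "owl:equivalentProperty", "label": "equivalent property", "inverse": "owl:equivalentProperty"},
    {"curie": "oboinowl:hasDbXref", "label": "database cross-reference", "inverse": "oboinowl:hasDbXref"},
    {"curie": "ro:0002205", "label": "has gene product", "inverse": "ro:0002204"},
    {"curie": "ro:0002204", "label": "gene product of", "inverse": "ro:0002205"}
  ],
  "justifications": [
    "semapv:ManualMappingCuration",
    "semapv:LexicalMatching",
    "semapv:LogicalReasoning",
    "semapv:UnspecifiedMatching",
    "semapv:MappingChaining",
    "semapv:MappingInversion",
    "semapv:MappingMutation",
    "semapv:MappingPrioritization"
  ]
}
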