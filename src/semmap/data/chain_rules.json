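{
  "comment": "Predicate composition table for two-step chaining. Pairs not listed compose to nothing (no mapping is inferred). Longer chains fold this table left to right.",
  "rules": [
    ["skos:exactMatch", "skos:exactMatch", "skos:exactMatch"],
    ["skos:exactMatch", "skos:broadMatch", "skos:broadMatch"],
    ["skos:broadMatch", "skos:exactMatch", "skos:broadMatch"],
    ["skos:broadMatch", "skos:broadMatch", "skos:broadMatch"],
    ["skos:exactMatch", "skos:narrowMatch", "skos:narrowMatch"],
    ["skos:narrowMatch", "skos:exactMatch", "skos:narrowMatch"],
    ["skos:narrowMatch", "skos:narrowMatch", "skos:narrowMatch"],
    ["skos:closeMatch", "skos:exactMatch", "skos:closeMatch"],
    ["skos:exactMatch", "skos:closeMatch", "skos:closeMatch"],
    ["skos:relatedMatch", "skos:exactMatch", "skos:relatedMatch"],
    ["skos:exactMatch", "skos:relatedMatch", "skos:relatedMatch"]
  ]
}
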