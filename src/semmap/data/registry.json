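{
  "skos": {"uri_prefix": "http://www.w3.org/2004/02/skos/core#", "synonyms": ["SKOS"]},
  "owl": {"uri_prefix": "http://www.w3.org/2002/07/owl#", "synonyms": ["OWL"]},
  "oboinowl": {"uri_prefix": "http://www.geneontology.org/formats/oboInOwl#", "synonyms": ["oboInOwl", "OBOINOWL"]},
  "semapv": {"uri_prefix": "https://w3id.org/semapv/vocab/", "synonyms": ["SEMAPV"]},
  "ro": {"uri_prefix": "http://purl.obolibrary.org/obo/RO_", "synonyms": ["RO"]},
  "orcid": {"uri_prefix": "https://orcid.org/", "synonyms": ["ORCID"]},
  "clo": {"uri_prefix": "http://purl.obolibrary.org/obo/CLO_", "synonyms": ["CLO"]},
  "bto": {"uri_prefix": "http://purl.obolibrary.org/obo/BTO_", "synonyms": ["BTO"]},
  "efo": {"uri_prefix": "http://www.ebi.ac.uk/efo/EFO_", "synonyms": ["EFO"]},
  "cellosaurus": {"uri_prefix": "https://www.cellosaurus.org/CVCL_", "synonyms": ["Cellosaurus", "cvcl"]},
  "mesh": {"uri_prefix": "http://id.nlm.nih.gov/mesh/", "synonyms": ["MESH", "MeSH"]},
  "ncit": {"uri_prefix": "http://purl.obolibrary.org/obo/NCIT_", "synonyms": ["NCIT", "NCIt"]},
  "mondo": {"uri_prefix": "http://purl.obolibrary.org/obo/MONDO_", "synonyms": ["MONDO"]},
  "doid": {"uri_prefix": "http://purl.obolibrary.org/obo/DOID_", "synonyms": ["DOID", "DO"]},
  "hgnc": {"uri_prefix": "https://bioregistry.io/hgnc:", "synonyms": ["HGNC"]},
  "ncbigene": {"uri_prefix": "https://www.ncbi.nlm.nih.gov/gene/", "synonyms": ["NCBIGene", "entrez", "EGID"]},
  "uniprot": {"uri_prefix": "https://purl.uniprot.org/uniprot/", "synonyms": ["UniProt", "UNIPROT"]},
  "chebi": {"uri_prefix": "http://purl.obolibrary.org/obo/CHEBI_", "synonyms": ["ChEBI", "CHEBI"]},
  "umls": {"uri_prefix": "https://uts.nlm.nih.gov/uts/umls/concept/", "synonyms": ["UMLS"]},
  "reg": {"uri_prefix": "https://example.org/test/reg/", "synonyms": []},
  "ont": {"uri_prefix": "https://example.org/test/ont/", "synonyms": []},
  "tis": {"uri_prefix": "https://example.org/test/tis/", "synonyms": []},
  "dep": {"uri_prefix": "https://example.org/test/dep/", "synonyms": []},
  "enc": {"uri_prefix": "https://example.org/test/enc/", "synonyms": []},
  "exp": {"uri_prefix": "https://example.org/test/exp/", "synonyms": []}
}
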