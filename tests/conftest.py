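from __future__ import annotations

import random

import pytest

from semmap.fixtures import fixture_registry
from semmap.io import MappingDocument
from semmap.model import (
    Mapping,
    MappingSet,
    Predicate,
    Reference,
    SimpleEvidence,
    default_registry,
    default_vocabulary,
)

MANUAL = "semapv:ManualMappingCuration"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture
def mapping_set():
    return MappingSet(name="test-set", version="1", license="CC0-1.0", consumer_confidence=0.9)


@pytest.fixture
def make_mapping(mapping_set):
    """Build a mapping ``prefix:id -pred-> prefix:id`` with one simple evidence."""

    def build(subject: str, predicate: str, obj: str, confidence=None, mset=None) -> Mapping:
        s_prefix, _, s_id = subject.partition(":")
        p_prefix, _, p_id = predicate.partition(":")
        o_prefix, _, o_id = obj.partition(":")
        evidence = SimpleEvidence(
            justification=MANUAL,
            mapping_set=mset or mapping_set,
            producer_confidence=confidence,
        )
        return Mapping(
            Reference(s_prefix, s_id),
            Predicate(Reference(p_prefix, p_id)),
            Reference(o_prefix, o_id),
            [evidence],
        )

    return build


@pytest.fixture
def make_doc(make_mapping):
    """Build a document over synthetic test prefixes from triple strings."""

    def build(*triples, n_prefixes: int = 12) -> MappingDocument:
        doc = MappingDocument(registry=fixture_registry(n_prefixes))
        for s, p, o in triples:
            doc.add(make_mapping(s, p, o))
        return doc

    return build


def random_graph_triples(rng: random.Random, n_nodes: int, n_edges: int):
    """Random directed mapping edges over synthetic-prefix nodes."""
    predicates = [
        "skos:exactMatch",
        "skos:broadMatch",
        "skos:narrowMatch",
        "skos:closeMatch",
        "oboinowl:hasDbXref",
    ]
    nodes = [f"xp{i % 6}:N{i}" for i in range(n_nodes)]
    triples = set()
    for _ in range(n_edges):
        s, o = rng.sample(nodes, 2)
        triples.add((s, rng.choice(predicates), o))
    return sorted(triples)
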