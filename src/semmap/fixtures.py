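"""Synthetic multi-source mapping fixtures with known ground truth.

Real mapping landscapes are fragmented: each resource publishes only a
sparse subset of the links within a group of equivalent entities, so
recovering full equivalence cliques requires inversion and chaining across
sources.  The generator emulates exactly that situation: it plants cliques
of cross-prefix equivalent entities, emits per-source mapping documents
containing a random spanning subset (a spanning tree) of each clique's
edges, and optionally injects the noise modes that matter in practice —

* **edge dropout** — links are missing, fragmenting cliques;
* **wrong edges** — spurious exact matches fusing two distinct cliques
  (the hardest failure mode, and the one cardinality QA must catch);
* **many-to-many planting** — a duplicate term in the target prefix, so
  one entity gains exact matches to two entities of that prefix;
* **imprecise predicates** — exact links demoted to low-precision
  database cross-references, recoverable only through a mutation rule.

Fixture CURIEs use reserved synthetic prefixes (``xp0``, ``xp1``, ...),
never real resource prefixes.  All draws are fixed by the seed; identical
specs produce byte-identical fixtures.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .io import MappingDocument, write_sssom
from .model import (
    DB_XREF,
    EXACT_MATCH,
    Mapping,
    MappingSet,
    PrefixRegistry,
    Reference,
    SimpleEvidence,
    default_registry,
)

__all__ = ["FixtureSpec", "GroundTruth", "generate", "fig1_toy", "fixture_registry"]

MANUAL = "semapv:ManualMappingCuration"


class FixtureSpec(BaseModel):
    """Declarative description of a synthetic mapping landscape."""

    n_prefixes: int = Field(6, ge=2)
    n_cliques: int = Field(10, ge=0)
    clique_size_min: int = Field(2, ge=1)
    clique_size_max: int = Field(5, ge=1)
    dropout: float = Field(0.0, ge=0.0, le=1.0)
    wrong_edge_rate: float = Field(0.0, ge=0.0, le=1.0)
    many_to_many_rate: float = Field(0.0, ge=0.0, le=1.0)
    imprecise_rate: float = Field(0.0, ge=0.0, le=1.0)
    consumer_confidence: float = Field(0.9, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "FixtureSpec":
        if self.clique_size_min > self.clique_size_max:
            raise ValueError("clique_size_min must not exceed clique_size_max")
        if self.clique_size_max > self.n_prefixes:
            raise ValueError(
                "clique_size_max exceeds n_prefixes: cliques hold at most one "
                "entity per prefix"
            )
        return self


@dataclass
class GroundTruth:
    """What the generator planted, and the numbers a perfect pipeline recovers."""

    cliques: list[list[str]]
    #: (entity curie, target prefix) pairs with >1 planted exact object
    violations: list[tuple[str, str]]
    raw_terms: int
    unique_terms: int
    reduction_percent: float
    n_edges: int
    n_wrong_edges: int
    seed: int

    def to_json(self) -> str:
        payload = {
            "cliques": self.cliques,
            "violations": [list(v) for v in self.violations],
            "raw_terms": self.raw_terms,
            "unique_terms": self.unique_terms,
            "reduction_percent": self.reduction_percent,
            "n_edges": self.n_edges,
            "n_wrong_edges": self.n_wrong_edges,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def fixture_registry(n_prefixes: int) -> PrefixRegistry:
    """The frozen registry extended with the reserved synthetic prefixes."""
    registry = default_registry().copy()
    for i in range(n_prefixes):
        registry.register(f"xp{i}", f"https://example.org/synthetic/xp{i}/")
    return registry


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def generate(spec: FixtureSpec) -> tuple[dict[str, MappingDocument], GroundTruth]:
    """Generate per-source mapping documents plus ground truth.

    Each planted clique takes one entity in each of a random subset of
    prefixes and a random spanning tree of exact-match edges over them.
    Edges group into one source per subject prefix.  Ground-truth raw /
    unique / reduction numbers are derived from the *emitted* edges with an
    independent union-find, so they stay honest under dropout and wrong
    edges; with zero noise they equal the planted cliques exactly.
    """
    rng = random.Random(spec.seed)
    registry = fixture_registry(spec.n_prefixes)
    prefixes = [f"xp{i}" for i in range(spec.n_prefixes)]

    planted: list[list[Reference]] = []
    for ci in range(spec.n_cliques):
        size = rng.randint(spec.clique_size_min, spec.clique_size_max)
        members = [Reference(p, f"E{ci:04d}") for p in rng.sample(prefixes, size)]
        planted.append(members)

    # spanning tree per clique; each edge kept unless dropped
    edges: list[tuple[Reference, Reference, int]] = []  # (subject, object, clique idx)
    for ci, members in enumerate(planted):
        order = members[:]
        rng.shuffle(order)
        for i in range(1, len(order)):
            parent = order[rng.randrange(i)]
            edges.append((parent, order[i], ci))
    kept = [e for e in edges if rng.random() >= spec.dropout]

    # many-to-many planting: duplicate target-prefix term reachable from one subject
    violations: list[tuple[str, str]] = []
    extra: list[tuple[Reference, Reference, int]] = []
    for subject, obj, ci in kept:
        if rng.random() < spec.many_to_many_rate:
            duplicate = Reference(obj.prefix, f"{obj.identifier}dup")
            extra.append((subject, duplicate, ci))
            violations.append((subject.curie, obj.prefix))
    kept.extend(extra)

    # wrong edges: fuse two distinct cliques
    n_wrong = int(round(spec.wrong_edge_rate * len(kept)))
    if spec.n_cliques >= 2:
        for _ in range(n_wrong):
            ca, cb = rng.sample(range(spec.n_cliques), 2)
            a = rng.choice(planted[ca])
            b = rng.choice(planted[cb])
            kept.append((a, b, -1))
    else:
        n_wrong = 0

    # imprecise predicates: demote exact edges to database cross-references
    emitted: list[tuple[Reference, Reference, bool]] = [
        (s, o, rng.random() < spec.imprecise_rate) for s, o, _ in kept
    ]

    # ground truth from emitted edges
    uf = _UnionFind()
    entities: set[str] = set()
    for s, o, _ in emitted:
        entities.update((s.curie, o.curie))
        uf.union(s.curie, o.curie)
    components = len({uf.find(e) for e in entities})
    raw = len(entities)
    unique = components
    reduction = 100.0 * (raw - unique) / raw if raw else 0.0

    # group into one source per subject prefix
    documents: dict[str, MappingDocument] = {}
    for s, o, imprecise in sorted(emitted, key=lambda e: (e[0], e[1])):
        source = f"source-{s.prefix}"
        if source not in documents:
            documents[source] = MappingDocument(registry=registry.copy())
        mapping_set = MappingSet(
            name=source, version="1.0", license="CC0-1.0",
            consumer_confidence=spec.consumer_confidence,
        )
        evidence = SimpleEvidence(justification=MANUAL, mapping_set=mapping_set)
        predicate = DB_XREF if imprecise else EXACT_MATCH
        documents[source].add(Mapping(s, predicate, o, [evidence]))

    truth = GroundTruth(
        cliques=[sorted(r.curie for r in members) for members in planted],
        violations=sorted(set(violations)),
        raw_terms=raw,
        unique_terms=unique,
        reduction_percent=reduction,
        n_edges=len(emitted),
        n_wrong_edges=n_wrong,
        seed=spec.seed,
    )
    return documents, truth


def write_fixture(spec: FixtureSpec, out_dir) -> tuple[list[Path], Path]:
    """Materialize a fixture as SSSOM files plus a ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    documents, truth = generate(spec)
    paths = []
    for source, doc in sorted(documents.items()):
        target = out_dir / f"{source}.sssom.tsv"
        write_sssom(doc, target, metadata={"mapping_set_name": source})
        paths.append(target)
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(truth.to_json(), encoding="utf-8")
    return paths, truth_path


# ---------------------------------------------------------------------------
# The worked toy landscape
# ---------------------------------------------------------------------------


def fig1_toy(registry: Optional[PrefixRegistry] = None) -> MappingDocument:
    """A six-resource cell-line-style toy landscape (re-keyed test prefixes).

    One underlying entity appears in six resources — a registry (``reg``),
    a tissue vocabulary (``tis``), an ontology (``ont``), a dependency
    database (``dep``), an encyclopedia (``enc``), and an experimental-
    factor vocabulary (``exp``) — but the published links are sparse,
    directed, and mostly low-precision cross-references:

    * ``reg:0110``  xref  ``tis:0001``, ``ont:0001``, ``dep:ACH-000001``
    * ``dep:ACH-000001``  exact  ``enc:1321N1``
    * ``exp:0001``  exact  ``reg:0110``  (curated secondary mapping)
    * ``exp:0001``  xref  ``tis:0001``

    There is no direct ``tis``/``ont`` link: producing one requires a
    cross-reference-to-exact mutation, inversion, and a two-step chain
    through ``reg:0110``.  After full processing the six entities form a
    single clique.
    """
    registry = registry or default_registry()
    doc = MappingDocument(registry=registry)
    primary = MappingSet(name="registry-xrefs", version="2024", license="CC-BY-4.0",
                         consumer_confidence=0.8)
    dep_primary = MappingSet(name="dep-primary", version="24Q2", license="CC-BY-4.0",
                             consumer_confidence=0.95)
    secondary = MappingSet(name="curated-secondary", version="1.0", license="CC0-1.0",
                           consumer_confidence=0.99)

    def simple(mapping_set: MappingSet) -> SimpleEvidence:
        return SimpleEvidence(justification=MANUAL, mapping_set=mapping_set)

    reg = Reference("reg", "0110")
    tis = Reference("tis", "0001")
    ont = Reference("ont", "0001")
    dep = Reference("dep", "ACH-000001")
    enc = Reference("enc", "1321N1")
    exp = Reference("exp", "0001")

    doc.add(Mapping(reg, DB_XREF, tis, [simple(primary)]))
    doc.add(Mapping(reg, DB_XREF, ont, [simple(primary)]))
    doc.add(Mapping(reg, DB_XREF, dep, [simple(primary)]))
    doc.add(Mapping(dep, EXACT_MATCH, enc, [simple(dep_primary)]))
    doc.add(Mapping(exp, EXACT_MATCH, reg, [simple(secondary)]))
    doc.add(Mapping(exp, DB_XREF, tis, [simple(secondary)]))
    return doc
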