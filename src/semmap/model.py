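"""Core data model for semantic mappings.

A semantic mapping is a directed triple ``(subject, predicate, object)``
between entities in two identifier spaces, written as CURIEs
(``prefix:local_id``).  Each unique triple carries one or more *evidence*
objects: :class:`SimpleEvidence` records provenance from a source mapping
set, while :class:`ReasonedEvidence` records an inference step (inversion,
mutation, or predicate chaining) together with pointers to the mappings it
was derived from.  Confidence propagates through this structure as
independent-event probabilities (noisy-OR):

* simple evidence: ``c_e = 1 - (1 - c_set)(1 - c_producer)``, falling back
  to ``c_set`` exactly when no producer confidence is given;
* mapping: ``c_m = 1 - prod_e (1 - c_e)`` — the probability that at least
  one supporting evidence is correct;
* reasoned evidence: ``c_e = gamma_op * (1 - prod_m (1 - c_m))`` over the
  supporting mappings, where ``gamma_op`` is an operation-specific factor.

Every object has a deterministic content hash (see :func:`content_hash`)
used for identity, deduplication, and cross-file references.  A mapping's
hash covers only its triple, so accruing evidence never changes mapping
identity; evidence hashes cover their full content including the hash of
their mapping set.

Canonical serialization for hashing (bit-exact contract)
--------------------------------------------------------
The digest is SHA-256 over the UTF-8 encoding of a one-line record: a type
tag followed by ``tag=value`` fields, all joined by ``|``.  Within values,
``\\`` is escaped as ``\\\\`` and ``|`` as ``\\|``.  Absent optional fields
serialize as the empty string; floats serialize via :func:`repr`.  Records:

* ``mappingset|name=N|version=V|license=L``  (consumer confidence excluded:
  it is the consumer's opinion, not the set's content)
* ``mapping|s=CURIE|p=CURIE|o=CURIE``
* ``evidence:simple|j=CURIE|author=A|pc=F|set=HEX``
* ``evidence:reasoned|j=CURIE|op=OP|gamma=F|supports=HEX,HEX,...``
  (supports in stored order; a chain's path order is part of its content)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources as _ilr
from typing import Iterable, Mapping as TMapping, Optional, Union

__all__ = [
    "Reference",
    "Predicate",
    "PredicateVocabulary",
    "MappingSet",
    "SimpleEvidence",
    "ReasonedEvidence",
    "Evidence",
    "Mapping",
    "PrefixRegistry",
    "default_registry",
    "default_vocabulary",
    "validate_reference",
    "evidence_confidence",
    "mapping_confidence",
    "reasoned_evidence_confidence",
    "content_hash",
    "HASH_ALGORITHM",
    "UnknownPrefixError",
    "MalformedCurieError",
    "ProvenanceError",
]

HASH_ALGORITHM = "sha256"

#: Operations a ReasonedEvidence may record.
OPERATIONS = ("inversion", "mutation", "chain", "prioritization")


class UnknownPrefixError(ValueError):
    """A CURIE used a prefix absent from the active registry."""


class MalformedCurieError(ValueError):
    """A string could not be parsed as ``prefix:local_id``."""


class ProvenanceError(ValueError):
    """Evidence provenance is unresolvable or cyclic."""


# ---------------------------------------------------------------------------
# References and the prefix registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Reference:
    """A pointer to one entity in one identifier space.

    Equality and ordering are over the (normalized) prefix and the verbatim
    local identifier; the serialized form is the CURIE ``prefix:local_id``.
    """

    prefix: str
    identifier: str

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.identifier}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


class PrefixRegistry:
    """Registry of recognized identifier-space prefixes.

    Maps each canonical prefix to a URI expansion and accepts case/synonym
    variants, normalizing them to the canonical form.  The default registry
    is a small frozen table shipped with the package; it is pluggable so a
    deployment may substitute a community registry export.
    """

    def __init__(self, records: TMapping[str, dict] | None = None) -> None:
        self._records: dict[str, dict] = {}
        self._synonyms: dict[str, str] = {}
        for prefix, record in (records or {}).items():
            self.register(prefix, record.get("uri_prefix", ""), record.get("synonyms", ()))

    def register(self, prefix: str, uri_prefix: str = "", synonyms: Iterable[str] = ()) -> None:
        if not prefix:
            raise ValueError("prefix must be non-empty")
        self._records[prefix] = {"uri_prefix": uri_prefix, "synonyms": list(synonyms)}
        self._synonyms[prefix.casefold()] = prefix
        for synonym in synonyms:
            self._synonyms[synonym.casefold()] = prefix

    def normalize_prefix(self, raw: str) -> Optional[str]:
        return self._synonyms.get(raw.casefold())

    def uri_prefix(self, prefix: str) -> Optional[str]:
        record = self._records.get(prefix)
        return record["uri_prefix"] if record else None

    def __contains__(self, prefix: str) -> bool:
        return prefix.casefold() in self._synonyms

    def __iter__(self):
        return iter(self._records)

    def prefix_map(self) -> dict[str, str]:
        return {p: r["uri_prefix"] for p, r in sorted(self._records.items())}

    def copy(self) -> "PrefixRegistry":
        out = PrefixRegistry()
        for prefix, record in self._records.items():
            out.register(prefix, record["uri_prefix"], record["synonyms"])
        return out


def _load_data(name: str) -> dict:
    with _ilr.files("semmap.data").joinpath(name).open("r", encoding="utf-8") as handle:
        return json.load(handle)


def default_registry() -> PrefixRegistry:
    """The frozen in-repo prefix registry (real vocab prefixes + reserved test prefixes)."""
    return PrefixRegistry(_load_data("registry.json"))


def validate_reference(raw_curie: str, registry: PrefixRegistry) -> Reference:
    """Parse and validate a CURIE against a prefix registry.

    The prefix is normalized to the registry's canonical casing/synonym; the
    local identifier is preserved verbatim (validation, not rewriting).
    """
    if not isinstance(raw_curie, str) or ":" not in raw_curie:
        raise MalformedCurieError(f"not a CURIE (missing colon): {raw_curie!r}")
    raw_prefix, _, identifier = raw_curie.partition(":")
    if not raw_prefix or not identifier:
        raise MalformedCurieError(f"empty prefix or local id in {raw_curie!r}")
    canonical = registry.normalize_prefix(raw_prefix)
    if canonical is None:
        raise UnknownPrefixError(f"unknown prefix {raw_prefix!r} in {raw_curie!r}")
    return Reference(canonical, identifier)


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Predicate:
    """A mapping predicate from the SKOS/OWL/cross-reference vocabulary."""

    reference: Reference

    @property
    def curie(self) -> str:
        return self.reference.curie


class PredicateVocabulary:
    """Closed-but-extensible predicate vocabulary with an inverse table.

    The inverse table is an involution: ``inverse(inverse(p)) == p`` for
    every predicate, and symmetric predicates are their own inverse.
    """

    def __init__(self) -> None:
        self._inverse: dict[str, str] = {}
        self._labels: dict[str, str] = {}

    def add(self, curie: str, inverse: str, label: str = "") -> None:
        self._inverse[curie] = inverse
        self._labels[curie] = label

    def __contains__(self, predicate: Union[Predicate, str]) -> bool:
        curie = predicate.curie if isinstance(predicate, Predicate) else predicate
        return curie in self._inverse

    def __iter__(self):
        return iter(sorted(self._inverse))

    def predicate(self, curie: str, registry: PrefixRegistry) -> Predicate:
        if curie not in self._inverse:
            raise KeyError(f"predicate {curie!r} not in vocabulary")
        return Predicate(validate_reference(curie, registry))

    def inverse(self, predicate: Predicate) -> Predicate:
        curie = predicate.curie
        if curie not in self._inverse:
            raise KeyError(f"predicate {curie!r} has no declared inverse")
        inv = self._inverse[curie]
        prefix, _, identifier = inv.partition(":")
        return Predicate(Reference(prefix, identifier))

    def is_symmetric(self, predicate: Predicate) -> bool:
        return self._inverse.get(predicate.curie) == predicate.curie

    def label(self, curie: str) -> str:
        return self._labels.get(curie, "")


def default_vocabulary() -> PredicateVocabulary:
    vocab = PredicateVocabulary()
    for record in _load_data("predicates.json")["predicates"]:
        vocab.add(record["curie"], record["inverse"], record.get("label", ""))
    return vocab


#: Convenience predicate constants (prefixes match the frozen registry).
EXACT_MATCH = Predicate(Reference("skos", "exactMatch"))
CLOSE_MATCH = Predicate(Reference("skos", "closeMatch"))
RELATED_MATCH = Predicate(Reference("skos", "relatedMatch"))
BROAD_MATCH = Predicate(Reference("skos", "broadMatch"))
NARROW_MATCH = Predicate(Reference("skos", "narrowMatch"))
EQUIVALENT_CLASS = Predicate(Reference("owl", "equivalentClass"))
DB_XREF = Predicate(Reference("oboinowl", "hasDbXref"))
HAS_GENE_PRODUCT = Predicate(Reference("ro", "0002205"))

UNSPECIFIED_MATCHING = "semapv:UnspecifiedMatching"
CHAINING_JUSTIFICATION = "semapv:MappingChaining"
INVERSION_JUSTIFICATION = "semapv:MappingInversion"
MUTATION_JUSTIFICATION = "semapv:MappingMutation"
PRIORITIZATION_JUSTIFICATION = "semapv:MappingPrioritization"


# ---------------------------------------------------------------------------
# Mapping sets and evidence
# ---------------------------------------------------------------------------


def _check_unit(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MappingSet:
    """A named, versioned, licensed mapping source.

    ``consumer_confidence`` is the confidence the *consumer* of the set
    places in it (``c_MappingSet``); it is an annotation, not part of the
    set's content hash.
    """

    name: str
    version: str = ""
    license: str = ""
    consumer_confidence: float = 1.0

    def __post_init__(self) -> None:
        _check_unit(self.consumer_confidence, "consumer_confidence")


@dataclass(frozen=True)
class SimpleEvidence:
    """Provenance leaf: one row of one source mapping set.

    ``producer_confidence`` is the confidence the *producer* annotated on the
    row (``c_Producer``); ``None`` means absent — numerically the fallback is
    identical to assuming 1.0, but absence is represented explicitly so the
    fallback branch is auditable.
    """

    justification: str
    mapping_set: MappingSet
    author: Optional[str] = None
    producer_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.producer_confidence is not None:
            _check_unit(self.producer_confidence, "producer_confidence")

    @property
    def confidence(self) -> float:
        return evidence_confidence(self)


@dataclass(frozen=True)
class ReasonedEvidence:
    """Inference node: the result of one reasoning operation.

    ``supporting_mappings`` are the mappings the operation consumed, in
    operation order (a chain stores its path).  ``operation_factor`` is the
    operation-specific scaling factor gamma_op.
    """

    justification: str
    operation: str
    supporting_mappings: tuple["Mapping", ...]
    operation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise ValueError(f"unknown operation {self.operation!r}")
        if not self.supporting_mappings:
            raise ValueError("reasoned evidence requires at least one supporting mapping")
        _check_unit(self.operation_factor, "operation_factor")

    @property
    def confidence(self) -> float:
        return reasoned_evidence_confidence(self)


Evidence = Union[SimpleEvidence, ReasonedEvidence]


@dataclass
class Mapping:
    """A unique directed mapping triple with its supporting evidence.

    ``(A, p, B)`` and ``(B, p, A)`` are distinct mappings even for symmetric
    predicates: directionality carries provenance.  Evidence is a non-empty
    list, deduplicated by content hash when documents merge triples.
    """

    subject: Reference
    predicate: Predicate
    object: Reference
    evidences: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.evidences:
            raise ValueError("a mapping requires at least one evidence")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.subject.curie, self.predicate.curie, self.object.curie)

    @property
    def confidence(self) -> float:
        return mapping_confidence(self)

    @property
    def hash(self) -> str:
        return content_hash(self)

    def merge_evidence(self, evidences: Iterable[Evidence]) -> None:
        """Add evidences not already present (by content hash)."""
        seen = {content_hash(e) for e in self.evidences}
        for evidence in evidences:
            digest = content_hash(evidence)
            if digest not in seen:
                self.evidences.append(evidence)
                seen.add(digest)


# ---------------------------------------------------------------------------
# Confidence calculus
# ---------------------------------------------------------------------------


def evidence_confidence(evidence: SimpleEvidence) -> float:
    """Confidence of a simple evidence: noisy-OR of set and producer confidence."""
    if evidence.mapping_set is None:  # defensive; dataclass requires it
        raise ProvenanceError("simple evidence has no resolvable mapping set")
    c_set = evidence.mapping_set.consumer_confidence
    c_producer = evidence.producer_confidence
    if c_producer is None:
        return c_set
    return 1.0 - (1.0 - c_set) * (1.0 - c_producer)


def mapping_confidence(mapping: Mapping, _active: frozenset | None = None) -> float:
    """Probability that at least one supporting evidence is correct."""
    if not mapping.evidences:
        raise ValueError("mapping has an empty evidence set")
    active = (_active or frozenset()) | {id(mapping)}
    product = 1.0
    for evidence in mapping.evidences:
        if isinstance(evidence, ReasonedEvidence):
            c_e = reasoned_evidence_confidence(evidence, active)
        else:
            c_e = evidence_confidence(evidence)
        product *= 1.0 - c_e
    return 1.0 - product


def reasoned_evidence_confidence(
    evidence: ReasonedEvidence, _active: frozenset | None = None
) -> float:
    """gamma_op times the noisy-OR of the supporting mappings' confidences."""
    active = _active or frozenset()
    product = 1.0
    for support in evidence.supporting_mappings:
        if id(support) in active:
            raise ProvenanceError(
                f"cyclic reasoning provenance through mapping {support.triple}"
            )
        product *= 1.0 - mapping_confidence(support, active)
    return evidence.operation_factor * (1.0 - product)


# ---------------------------------------------------------------------------
# Content hashing
# ---------------------------------------------------------------------------


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("|", "\\|")


def _float_field(value: Optional[float]) -> str:
    return "" if value is None else repr(float(value))


def _canonical(x: Union[Mapping, SimpleEvidence, ReasonedEvidence, MappingSet]) -> str:
    if isinstance(x, MappingSet):
        return "|".join(
            [
                "mappingset",
                f"name={_escape(x.name)}",
                f"version={_escape(x.version)}",
                f"license={_escape(x.license)}",
            ]
        )
    if isinstance(x, Mapping):
        return "|".join(
            [
                "mapping",
                f"s={_escape(x.subject.curie)}",
                f"p={_escape(x.predicate.curie)}",
                f"o={_escape(x.object.curie)}",
            ]
        )
    if isinstance(x, SimpleEvidence):
        return "|".join(
            [
                "evidence:simple",
                f"j={_escape(x.justification)}",
                f"author={_escape(x.author or '')}",
                f"pc={_float_field(x.producer_confidence)}",
                f"set={content_hash(x.mapping_set)}",
            ]
        )
    if isinstance(x, ReasonedEvidence):
        supports = ",".join(content_hash(m) for m in x.supporting_mappings)
        return "|".join(
            [
                "evidence:reasoned",
                f"j={_escape(x.justification)}",
                f"op={_escape(x.operation)}",
                f"gamma={_float_field(x.operation_factor)}",
                f"supports={supports}",
            ]
        )
    raise TypeError(f"cannot hash object of type {type(x).__name__}")


def content_hash(x: Union[Mapping, SimpleEvidence, ReasonedEvidence, MappingSet]) -> str:
    """Deterministic SHA-256 hex digest of the canonical serialization.

    Mapping hashes cover only the triple, so evidence accrual never changes
    mapping identity; evidence hashes cover full content including their
    mapping set's hash; mapping-set hashes cover name/version/license.
    """
    return hashlib.sha256(_canonical(x).encode("utf-8")).hexdigest()
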