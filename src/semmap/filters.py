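"""Filtering and quality assurance over mapping collections.

Three filter families operate on assembled documents: prefix-based removal
(by subject prefix, object prefix, or prefix pair), cardinality checks
(entities with exact matches to more than one entity in a single target
prefix — these break one-to-one data integration and are routed to
curation), and confidence thresholds.  Negative mappings — curated
assertions that two entities are *not* related — are subtracted from
documents and excluded as inference steps.

Every filter returns both the retained document and the removed mappings,
so ``removed + retained`` always partitions the input exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from .io import MappingDocument, _split_header_and_rows
from .model import (
    EXACT_MATCH,
    Mapping,
    Predicate,
    PrefixRegistry,
    default_registry,
    validate_reference,
)

__all__ = [
    "FilterRule",
    "CardinalityViolation",
    "CardinalityReport",
    "filter_prefixes",
    "flag_cardinality_violations",
    "remove_cardinality_violations",
    "filter_confidence",
    "apply_negatives",
    "apply_filter",
    "read_negatives_sssom",
    "write_qa_report",
]

logger = logging.getLogger(__name__)

FilterKind = Literal[
    "subject_prefix", "object_prefix", "prefix_pair", "cardinality",
    "confidence_threshold", "negatives",
]


@dataclass(frozen=True)
class FilterRule:
    """One declarative filter: which family, and its parameters."""

    kind: FilterKind
    prefix: Optional[str] = None
    subject_prefix: Optional[str] = None
    object_prefix: Optional[str] = None
    threshold: Optional[float] = None
    negatives: tuple[tuple[str, str, str], ...] = ()
    #: for cardinality rules: drop whole violating groups instead of flagging
    delete: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("subject_prefix", "object_prefix") and not self.prefix:
            raise ValueError(f"{self.kind} rule requires a non-empty prefix")
        if self.kind == "prefix_pair" and not (self.subject_prefix and self.object_prefix):
            raise ValueError("prefix_pair rule requires subject_prefix and object_prefix")
        if self.kind == "confidence_threshold":
            if self.threshold is None or not (0.0 <= self.threshold <= 1.0):
                raise ValueError("confidence_threshold rule requires threshold in [0, 1]")


# ---------------------------------------------------------------------------
# Prefix filters
# ---------------------------------------------------------------------------


def filter_prefixes(doc: MappingDocument, rule: FilterRule) -> tuple[MappingDocument, list[Mapping]]:
    """Remove mappings whose subject/object prefix (or pair) is excluded."""

    def matches(m: Mapping) -> bool:
        if rule.kind == "subject_prefix":
            return m.subject.prefix == rule.prefix
        if rule.kind == "object_prefix":
            return m.object.prefix == rule.prefix
        if rule.kind == "prefix_pair":
            return (m.subject.prefix == rule.subject_prefix
                    and m.object.prefix == rule.object_prefix)
        raise ValueError(f"not a prefix filter: {rule.kind}")

    removed = [m for m in doc.mappings if matches(m)]
    retained = doc.copy()
    retained.remove(removed)
    for mapping in removed:
        logger.info("filtered by %s rule: %s", rule.kind, mapping.triple)
    return retained, removed


# ---------------------------------------------------------------------------
# Cardinality QA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CardinalityViolation:
    """One entity with >1 exact-match partner inside one target prefix."""

    entity: str
    target_prefix: str
    mappings: tuple[Mapping, ...]

    @property
    def group_key(self) -> str:
        return f"{self.entity}->{self.target_prefix}"


@dataclass
class CardinalityReport:
    predicate: Predicate
    directional: bool
    violations: list[CardinalityViolation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.violations)

    def planted_keys(self) -> set[tuple[str, str]]:
        return {(v.entity, v.target_prefix) for v in self.violations}


def flag_cardinality_violations(
    doc: MappingDocument,
    predicate: Predicate = EXACT_MATCH,
    directional: bool = True,
) -> CardinalityReport:
    """Flag entities mapping to more than one entity in a single prefix.

    Directional assessment follows the mapping graph: only outgoing edges of
    each entity count.  The undirected mode additionally counts incoming
    edges, which is appropriate for symmetric predicates before inversion.
    Violations are flagged, never silently removed; the report is designed
    to be reviewed and hand-edited into a negatives file.
    """
    groups: dict[tuple[str, str], dict[str, list[Mapping]]] = {}
    for mapping in doc.mappings:
        if mapping.predicate != predicate:
            continue
        pairs = [(mapping.subject.curie, mapping.object)]
        if not directional:
            pairs.append((mapping.object.curie, mapping.subject))
        for entity, partner in pairs:
            bucket = groups.setdefault((entity, partner.prefix), {})
            bucket.setdefault(partner.curie, []).append(mapping)
    report = CardinalityReport(predicate=predicate, directional=directional)
    for (entity, target_prefix), partners in sorted(groups.items()):
        if len(partners) > 1:
            mappings = tuple(m for ms in partners.values() for m in ms)
            report.violations.append(
                CardinalityViolation(entity, target_prefix, mappings)
            )
    return report


def remove_cardinality_violations(
    doc: MappingDocument, report: CardinalityReport
) -> tuple[MappingDocument, list[Mapping]]:
    """Opt-in deletion mode: drop every mapping of every violating group.

    The whole group is removed — never a heuristic subset — since choosing a
    winner automatically would bake in exactly the errors the QA flags.
    """
    doomed: dict[str, Mapping] = {}
    for violation in report.violations:
        for mapping in violation.mappings:
            doomed[mapping.hash] = mapping
    removed = [m for m in doc.mappings if m.hash in doomed]
    retained = doc.copy()
    retained.remove(removed)
    return retained, removed


def write_qa_report(report: CardinalityReport, path) -> None:
    """Write the cardinality report as TSV, one row per flagged mapping."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_key", "entity", "target_prefix",
                         "subject_id", "predicate_id", "object_id", "confidence"])
        for violation in report.violations:
            for mapping in violation.mappings:
                s, p, o = mapping.triple
                writer.writerow([violation.group_key, violation.entity,
                                 violation.target_prefix, s, p, o,
                                 repr(mapping.confidence)])


# ---------------------------------------------------------------------------
# Confidence filter
# ---------------------------------------------------------------------------


def filter_confidence(
    doc: MappingDocument, threshold: float
) -> tuple[MappingDocument, list[Mapping]]:
    """Remove mappings whose overall confidence is below ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold!r}")
    removed = [m for m in doc.mappings if m.confidence < threshold]
    retained = doc.copy()
    retained.remove(removed)
    return retained, removed


# ---------------------------------------------------------------------------
# Negative mappings
# ---------------------------------------------------------------------------


def apply_negatives(
    doc: MappingDocument, negatives: Iterable[tuple[str, str, str]]
) -> tuple[MappingDocument, list[Mapping]]:
    """Remove curated negative triples wherever present.

    The same negative set should also be passed to chain inference so the
    listed triples are never used as path steps.
    """
    negative_set = set(negatives)
    present = doc.triples()
    for triple in sorted(negative_set - present):
        logger.info("negative triple not present (no-op): %s", triple)
    removed = [m for m in doc.mappings if m.triple in negative_set]
    retained = doc.copy()
    retained.remove(removed)
    return retained, removed


def read_negatives_sssom(path, registry: Optional[PrefixRegistry] = None) -> set[tuple[str, str, str]]:
    """Read negative triples from an SSSOM TSV using the negated-predicate
    convention: rows whose ``predicate_modifier`` column equals ``Not``.

    Files with no ``predicate_modifier`` column are treated as all-negative
    (a dedicated negatives file).
    """
    registry = registry or default_registry()
    _, header, rows = _split_header_and_rows(Path(path))
    idx = {c: i for i, c in enumerate(header)}
    for column in ("subject_id", "predicate_id", "object_id"):
        if column not in idx:
            raise ValueError(f"{path}: negatives file missing column {column!r}")
    modifier = idx.get("predicate_modifier")
    out: set[tuple[str, str, str]] = set()
    for _, cells in rows:
        if modifier is not None and (len(cells) <= modifier or cells[modifier].strip() != "Not"):
            continue
        s = validate_reference(cells[idx["subject_id"]], registry)
        p = validate_reference(cells[idx["predicate_id"]], registry)
        o = validate_reference(cells[idx["object_id"]], registry)
        out.add((s.curie, p.curie, o.curie))
    return out


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def apply_filter(doc: MappingDocument, rule: FilterRule) -> tuple[MappingDocument, list[Mapping]]:
    """Apply one declarative filter rule, returning (retained, removed)."""
    if rule.kind in ("subject_prefix", "object_prefix", "prefix_pair"):
        return filter_prefixes(doc, rule)
    if rule.kind == "confidence_threshold":
        return filter_confidence(doc, rule.threshold)
    if rule.kind == "negatives":
        return apply_negatives(doc, rule.negatives)
    if rule.kind == "cardinality":
        report = flag_cardinality_violations(doc)
        if rule.delete:
            return remove_cardinality_violations(doc, report)
        for violation in report.violations:
            logger.warning("cardinality violation flagged: %s", violation.group_key)
        return doc, []
    raise ValueError(f"unknown filter kind {rule.kind!r}")
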