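"""Reading and writing mapping collections.

Supported formats:

* **SSSOM TSV** (read/write) — tab-separated with the standard columns
  (``subject_id``, ``predicate_id``, ``object_id``, ``mapping_justification``,
  optional ``confidence``, ``author_id``) and an optional leading
  ``#``-prefixed embedded YAML metadata block carrying the prefix map and
  set-level metadata.  One row per (mapping, evidence) pair; rows sharing a
  triple merge into one mapping with several evidences.  Inference
  provenance, which standard SSSOM cannot express, is carried in extension
  columns (``evidence_type``, ``reasoning_operation``, ``reasoning_factor``,
  ``supporting_mapping_hashes``); unknown columns pass through untouched.
* **bare cross-reference TSV** (read) — two columns of CURIEs ingested under
  a declared default predicate with an unspecified-matching justification.
* **property-graph TSV layout** (write) — concepts, mappings, evidences and
  mapping sets as node files plus the edge files connecting them, suitable
  for bulk-loading a graph database.

Column inventories for every file written here are given in the module
constants below.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .model import (
    Evidence,
    Mapping,
    MappingSet,
    MalformedCurieError,
    Predicate,
    PrefixRegistry,
    ProvenanceError,
    ReasonedEvidence,
    Reference,
    SimpleEvidence,
    UnknownPrefixError,
    UNSPECIFIED_MATCHING,
    content_hash,
    default_registry,
    validate_reference,
)

__all__ = [
    "MappingDocument",
    "SSSOMFormatError",
    "read_sssom",
    "write_sssom",
    "read_xref_tsv",
    "export_property_graph",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "predicate_id", "object_id", "mapping_justification")

#: Columns written by :func:`write_sssom`, in order.  Everything after
#: ``author_id`` is an extension column.
SSSOM_COLUMNS = [
    "subject_id",
    "predicate_id",
    "object_id",
    "mapping_justification",
    "confidence",
    "author_id",
    "mapping_set",
    "mapping_set_version",
    "mapping_set_license",
    "mapping_set_confidence",
    "evidence_type",
    "reasoning_operation",
    "reasoning_factor",
    "supporting_mapping_hashes",
]


class SSSOMFormatError(ValueError):
    """The file does not satisfy the SSSOM TSV contract."""


# ---------------------------------------------------------------------------
# The document container
# ---------------------------------------------------------------------------


@dataclass
class MappingDocument:
    """An ordered collection of unique mappings with set and prefix context.

    Ingesting a mapping whose triple is already present merges its evidences
    into the existing mapping (deduplicated by evidence hash) instead of
    duplicating the triple.
    """

    registry: PrefixRegistry = field(default_factory=default_registry)
    mappings: list[Mapping] = field(default_factory=list)
    mapping_sets: dict[str, MappingSet] = field(default_factory=dict)
    prefix_map: dict[str, str] = field(default_factory=dict)
    #: pass-through for unknown SSSOM columns: (mapping_hash, evidence_hash) -> {column: value}
    extensions: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)
    _by_hash: dict[str, Mapping] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for mapping in list(self.mappings):
            self._by_hash.setdefault(mapping.hash, mapping)
            self._register_context(mapping)

    def __len__(self) -> int:
        return len(self.mappings)

    def __iter__(self):
        return iter(self.mappings)

    def get(self, mapping_hash: str) -> Optional[Mapping]:
        return self._by_hash.get(mapping_hash)

    def _register_context(self, mapping: Mapping) -> None:
        for reference in (mapping.subject, mapping.object, mapping.predicate.reference):
            if reference.prefix not in self.prefix_map:
                uri = self.registry.uri_prefix(reference.prefix)
                self.prefix_map[reference.prefix] = uri or f"https://bioregistry.io/{reference.prefix}:"
        for evidence in mapping.evidences:
            if isinstance(evidence, SimpleEvidence):
                self.mapping_sets.setdefault(content_hash(evidence.mapping_set), evidence.mapping_set)

    def add(self, mapping: Mapping) -> Mapping:
        """Add a mapping, merging evidences if the triple already exists."""
        existing = self._by_hash.get(mapping.hash)
        if existing is not None:
            existing.merge_evidence(mapping.evidences)
            self._register_context(mapping)
            return existing
        self.mappings.append(mapping)
        self._by_hash[mapping.hash] = mapping
        self._register_context(mapping)
        return mapping

    def extend(self, mappings: Iterable[Mapping]) -> None:
        for mapping in mappings:
            self.add(mapping)

    def remove(self, mappings: Iterable[Mapping]) -> None:
        doomed = {m.hash for m in mappings}
        self.mappings = [m for m in self.mappings if m.hash not in doomed]
        for h in doomed:
            self._by_hash.pop(h, None)

    def copy(self) -> "MappingDocument":
        out = MappingDocument(registry=self.registry)
        out.prefix_map.update(self.prefix_map)
        out.mapping_sets.update(self.mapping_sets)
        out.extensions.update(self.extensions)
        out.extend(self.mappings)
        return out

    def triples(self) -> set[tuple[str, str, str]]:
        return {m.triple for m in self.mappings}


# ---------------------------------------------------------------------------
# SSSOM TSV reading
# ---------------------------------------------------------------------------


def _parse_metadata_block(lines: list[str]) -> dict:
    stripped = []
    for line in lines:
        body = line[1:]
        if body.startswith(" "):
            body = body[1:]
        stripped.append(body)
    try:
        meta = yaml.safe_load("\n".join(stripped)) or {}
    except yaml.YAMLError:
        logger.warning("unparseable embedded metadata block; ignoring")
        return {}
    return meta if isinstance(meta, dict) else {}


def _split_header_and_rows(path: Path) -> tuple[dict, list[str], list[tuple[int, list[str]]]]:
    meta_lines: list[str] = []
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#") and header is None:
                meta_lines.append(line)
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                rows.append((lineno, cells))
    if header is None:
        raise SSSOMFormatError(f"{path}: no header row found")
    return _parse_metadata_block(meta_lines), header, rows


def _float_or_none(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


def read_sssom(
    path,
    set_defaults: Optional[MappingSet] = None,
    consumer_confidence: Optional[float] = None,
    registry: Optional[PrefixRegistry] = None,
    strict: bool = True,
) -> MappingDocument:
    """Read an SSSOM TSV file into a :class:`MappingDocument`.

    ``set_defaults`` supplies mapping-set metadata for rows that do not carry
    their own; the embedded metadata block, when present, fills the same
    role.  ``consumer_confidence`` overrides the default set's consumer
    confidence.  With ``strict`` (library default) malformed rows raise with
    their line number; otherwise they are skipped and logged (pipeline mode).
    """
    path = Path(path)
    registry = registry or default_registry()
    meta, header, rows = _split_header_and_rows(path)

    for column in REQUIRED_COLUMNS:
        if column not in header:
            raise SSSOMFormatError(f"{path}: missing required column {column!r}")

    # prefix map from the metadata block extends the registry for this read
    curie_map = meta.get("curie_map") or meta.get("prefix_map") or {}
    if curie_map:
        registry = registry.copy()
        for prefix, uri in curie_map.items():
            if prefix not in registry:
                registry.register(str(prefix), str(uri))

    default_set = MappingSet(
        name=str(meta.get("mapping_set_name") or meta.get("mapping_set_id") or
                 (set_defaults.name if set_defaults else path.stem)),
        version=str(meta.get("mapping_set_version") or (set_defaults.version if set_defaults else "")),
        license=str(meta.get("license") or (set_defaults.license if set_defaults else "")),
        consumer_confidence=(
            consumer_confidence
            if consumer_confidence is not None
            else float(meta.get("mapping_set_confidence",
                                set_defaults.consumer_confidence if set_defaults else 1.0))
        ),
    )

    known = set(SSSOM_COLUMNS)
    extra_columns = [c for c in header if c not in known]
    doc = MappingDocument(registry=registry)
    for prefix, uri in curie_map.items():
        canon = registry.normalize_prefix(str(prefix))
        if canon:
            doc.prefix_map.setdefault(canon, str(uri))
    deferred: list[tuple[int, dict]] = []

    for lineno, cells in rows:
        record = dict(zip(header, cells))
        try:
            subject = validate_reference(record["subject_id"], registry)
            predicate = Predicate(validate_reference(record["predicate_id"], registry))
            obj = validate_reference(record["object_id"], registry)
        except (MalformedCurieError, UnknownPrefixError) as err:
            if strict:
                raise type(err)(f"{path}:{lineno}: {err}") from err
            logger.warning("%s:%d: skipping row (%s)", path, lineno, err)
            continue
        if record.get("evidence_type", "").strip() == "reasoned":
            deferred.append((lineno, record))
            continue
        mapping_set = default_set
        if record.get("mapping_set", "").strip():
            mapping_set = MappingSet(
                name=record["mapping_set"].strip(),
                version=record.get("mapping_set_version", "").strip(),
                license=record.get("mapping_set_license", "").strip(),
                consumer_confidence=_float_or_none(record.get("mapping_set_confidence", ""))
                if record.get("mapping_set_confidence", "").strip()
                else default_set.consumer_confidence,
            )
        evidence = SimpleEvidence(
            justification=record.get("mapping_justification", "").strip() or UNSPECIFIED_MATCHING,
            mapping_set=mapping_set,
            author=record.get("author_id", "").strip() or None,
            producer_confidence=_float_or_none(record.get("confidence", "")),
        )
        mapping = doc.add(Mapping(subject, predicate, obj, [evidence]))
        extras = {c: record[c] for c in extra_columns if record.get(c, "").strip()}
        if extras:
            doc.extensions[(mapping.hash, content_hash(evidence))] = extras

    # second pass: reasoned rows resolve against mappings in the same document;
    # a reasoned row may support another reasoned row, so iterate to a fixpoint
    pending = deferred
    while pending:
        progressed = False
        still_pending = []
        for lineno, record in pending:
            support_hashes = [
                h for h in record.get("supporting_mapping_hashes", "").split("|") if h
            ]
            supports = [doc.get(h) for h in support_hashes]
            if not supports or any(s is None for s in supports):
                still_pending.append((lineno, record))
                continue
            subject = validate_reference(record["subject_id"], registry)
            predicate = Predicate(validate_reference(record["predicate_id"], registry))
            obj = validate_reference(record["object_id"], registry)
            factor_text = record.get("reasoning_factor", "").strip()
            evidence = ReasonedEvidence(
                justification=record.get("mapping_justification", "").strip(),
                operation=record.get("reasoning_operation", "chain").strip() or "chain",
                supporting_mappings=tuple(supports),
                operation_factor=float(factor_text) if factor_text else 1.0,
            )
            doc.add(Mapping(subject, predicate, obj, [evidence]))
            progressed = True
        if not progressed:
            for lineno, record in still_pending:
                message = (f"{path}:{lineno}: unresolvable supporting mapping(s) "
                           f"{record.get('supporting_mapping_hashes', '')}")
                if strict:
                    raise ProvenanceError(message)
                logger.warning("%s; skipping row", message)
            break
        pending = still_pending

    logger.info("read %d mappings from %s", len(doc), path)
    return doc


# ---------------------------------------------------------------------------
# SSSOM TSV writing
# ---------------------------------------------------------------------------


def _evidence_row(mapping: Mapping, evidence: Evidence, doc: MappingDocument) -> dict[str, str]:
    row = {c: "" for c in SSSOM_COLUMNS}
    row["subject_id"], row["predicate_id"], row["object_id"] = mapping.triple
    row["mapping_justification"] = evidence.justification
    if isinstance(evidence, SimpleEvidence):
        row["evidence_type"] = "simple"
        row["confidence"] = "" if evidence.producer_confidence is None else repr(evidence.producer_confidence)
        row["author_id"] = evidence.author or ""
        row["mapping_set"] = evidence.mapping_set.name
        row["mapping_set_version"] = evidence.mapping_set.version
        row["mapping_set_license"] = evidence.mapping_set.license
        row["mapping_set_confidence"] = repr(evidence.mapping_set.consumer_confidence)
    else:
        row["evidence_type"] = "reasoned"
        row["reasoning_operation"] = evidence.operation
        row["reasoning_factor"] = repr(evidence.operation_factor)
        row["supporting_mapping_hashes"] = "|".join(
            content_hash(m) for m in evidence.supporting_mappings
        )
    extras = doc.extensions.get((mapping.hash, content_hash(evidence)), {})
    row.update(extras)
    return row


def write_sssom(doc: MappingDocument, path, metadata: Optional[dict] = None) -> None:
    """Write a document as SSSOM TSV: one row per (mapping, evidence) pair.

    Rows are sorted by triple then evidence hash so output is byte-stable.
    Simple-evidence rows precede reasoned ones globally so that a reading
    pass can resolve reasoned provenance within the same file.
    """
    path = Path(path)
    extra_columns = sorted({c for extras in doc.extensions.values() for c in extras})
    columns = SSSOM_COLUMNS + [c for c in extra_columns if c not in SSSOM_COLUMNS]

    used_prefixes = sorted(
        {r.prefix for m in doc.mappings for r in (m.subject, m.object, m.predicate.reference)}
    )
    meta = dict(metadata or {})
    meta.setdefault("curie_map", {p: doc.prefix_map.get(p, "") for p in used_prefixes})

    simple_rows: list[dict[str, str]] = []
    reasoned_rows: list[dict[str, str]] = []
    for mapping in doc.mappings:
        for evidence in mapping.evidences:
            row = _evidence_row(mapping, evidence, doc)
            (reasoned_rows if row["evidence_type"] == "reasoned" else simple_rows).append(row)
    key = lambda r: (r["subject_id"], r["predicate_id"], r["object_id"], r["mapping_justification"],
                     r["supporting_mapping_hashes"], r["mapping_set"], r["confidence"], r["author_id"])
    simple_rows.sort(key=key)
    reasoned_rows.sort(key=key)

    buffer = _stdio.StringIO()
    meta_yaml = yaml.safe_dump(meta, sort_keys=True, default_flow_style=False).rstrip("\n")
    for line in meta_yaml.split("\n"):
        buffer.write(f"#{line}\n")
    writer = csv.DictWriter(buffer, fieldnames=columns, delimiter="\t", lineterminator="\n")
    writer.writeheader()
    for row in simple_rows + reasoned_rows:
        writer.writerow(row)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(buffer.getvalue(), encoding="utf-8")
    logger.info("wrote %d mappings (%d rows) to %s", len(doc), len(simple_rows) + len(reasoned_rows), path)


# ---------------------------------------------------------------------------
# Bare cross-reference TSV
# ---------------------------------------------------------------------------


def read_xref_tsv(
    path,
    default_predicate: Predicate,
    set_metadata: MappingSet,
    registry: Optional[PrefixRegistry] = None,
    excluded_prefixes: Iterable[str] = (),
    strict: bool = True,
) -> MappingDocument:
    """Read a plain two-column cross-reference TSV.

    Every row becomes a mapping ``subject default_predicate object`` with an
    unspecified-matching justification under ``set_metadata``.  Rows whose
    subject or object prefix is in ``excluded_prefixes`` are dropped with a
    log entry.  Identical rows deduplicate to one mapping with one evidence.
    """
    path = Path(path)
    registry = registry or default_registry()
    excluded = {p.casefold() for p in excluded_prefixes}
    doc = MappingDocument(registry=registry)
    evidence = SimpleEvidence(justification=UNSPECIFIED_MATCHING, mapping_set=set_metadata)
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                message = f"{path}:{lineno}: expected >=2 tab-separated columns"
                if strict:
                    raise SSSOMFormatError(message)
                logger.warning("%s; skipping", message)
                continue
            try:
                subject = validate_reference(cells[0], registry)
                obj = validate_reference(cells[1], registry)
            except (MalformedCurieError, UnknownPrefixError) as err:
                if strict:
                    raise type(err)(f"{path}:{lineno}: {err}") from err
                logger.warning("%s:%d: skipping row (%s)", path, lineno, err)
                continue
            if subject.prefix.casefold() in excluded or obj.prefix.casefold() in excluded:
                logger.info("%s:%d: dropped (excluded prefix): %s -> %s",
                            path, lineno, subject.curie, obj.curie)
                continue
            doc.add(Mapping(subject, default_predicate, obj, [evidence]))
    return doc


# ---------------------------------------------------------------------------
# Property-graph export
# ---------------------------------------------------------------------------

PG_FILES = {
    "concept_nodes.tsv": ["curie", "prefix"],
    "mapping_nodes.tsv": ["mapping_hash", "subject_id", "predicate_id", "object_id", "confidence"],
    "evidence_nodes.tsv": ["evidence_hash", "evidence_type", "justification", "confidence",
                           "operation", "operation_factor"],
    "mapping_set_nodes.tsv": ["mapping_set_hash", "name", "version", "license", "consumer_confidence"],
    "mapping_edges.tsv": ["subject_id", "object_id", "predicate_id", "mapping_hash"],
    "mapping_evidence_edges.tsv": ["mapping_hash", "evidence_hash"],
    "evidence_mapping_set_edges.tsv": ["evidence_hash", "mapping_set_hash"],
    "evidence_support_edges.tsv": ["evidence_hash", "supporting_mapping_hash"],
}


def export_property_graph(doc: MappingDocument, out_dir) -> dict[str, Path]:
    """Export the document as a property-graph file layout.

    Concepts, mappings, evidences and mapping sets become node files keyed
    by CURIE or content hash; edge files connect concepts through mappings,
    mappings to their evidences, evidences to their mapping sets, and
    reasoned evidences to their supporting mappings.  Also writes a
    ``metadata.json`` recording the hash algorithm so digests are comparable
    across implementations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    concepts: set[tuple[str, str]] = set()
    mapping_rows, evidence_rows, set_rows = [], {}, {}
    mapping_edges, ev_edges, set_edges, support_edges = [], [], [], []

    for mapping in doc.mappings:
        mh = mapping.hash
        for ref in (mapping.subject, mapping.object):
            concepts.add((ref.curie, ref.prefix))
        s, p, o = mapping.triple
        mapping_rows.append([mh, s, p, o, repr(mapping.confidence)])
        mapping_edges.append([s, o, p, mh])
        for evidence in mapping.evidences:
            eh = content_hash(evidence)
            ev_edges.append([mh, eh])
            if isinstance(evidence, SimpleEvidence):
                evidence_rows[eh] = [eh, "simple", evidence.justification,
                                     repr(evidence.confidence), "", ""]
                sh = content_hash(evidence.mapping_set)
                set_rows[sh] = [sh, evidence.mapping_set.name, evidence.mapping_set.version,
                                evidence.mapping_set.license,
                                repr(evidence.mapping_set.consumer_confidence)]
                set_edges.append([eh, sh])
            else:
                evidence_rows[eh] = [eh, "reasoned", evidence.justification,
                                     repr(evidence.confidence), evidence.operation,
                                     repr(evidence.operation_factor)]
                for support in evidence.supporting_mappings:
                    support_edges.append([eh, content_hash(support)])

    tables = {
        "concept_nodes.tsv": sorted([c, p] for c, p in concepts),
        "mapping_nodes.tsv": sorted(mapping_rows),
        "evidence_nodes.tsv": sorted(evidence_rows.values()),
        "mapping_set_nodes.tsv": sorted(set_rows.values()),
        "mapping_edges.tsv": sorted(mapping_edges),
        "mapping_evidence_edges.tsv": sorted(set(map(tuple, ev_edges))),
        "evidence_mapping_set_edges.tsv": sorted(set(map(tuple, set_edges))),
        "evidence_support_edges.tsv": sorted(set(map(tuple, support_edges))),
    }
    written = {}
    for name, rows in tables.items():
        target = out_dir / name
        with open(target, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(PG_FILES[name])
            writer.writerows(rows)
        written[name] = target
    import json as _json

    (out_dir / "metadata.json").write_text(
        _json.dumps({"hash_algorithm": "sha256", "files": sorted(tables)}, indent=2) + "\n",
        encoding="utf-8",
    )
    return written
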