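"""Assembling processed mappings into output artifacts.

Two artifacts serve downstream data integration:

* a **projection mapping set** maps identifiers of one resource onto
  another: all subjects share one prefix, all objects share another, and
  the map is functional (at most one object per subject; ambiguous
  subjects are excluded and reported);
* a **prioritization mapping set** standardizes identifiers: the
  exact-match subgraph is partitioned into cliques of mutually equivalent
  entities (connected components, which inference closes into true
  cliques), each clique elects a canonical entity by a prefix priority
  list, and every member maps to that canonical entity — a star graph per
  clique, with each entity the subject of exactly one mapping.

The landscape metric reported alongside is the consolidation a
prioritization achieves: ``unique = raw − (clique members − cliques)`` and
``reduction = (raw − unique) / raw``, i.e. how many raw terms collapse
onto shared canonical representatives.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import networkx as nx

from .io import MappingDocument
from .model import (
    EXACT_MATCH,
    Mapping,
    MappingSet,
    Predicate,
    PRIORITIZATION_JUSTIFICATION,
    ReasonedEvidence,
    Reference,
    SimpleEvidence,
)

__all__ = [
    "PrioritizationSet",
    "ProjectionSet",
    "extract_cliques",
    "build_prioritization",
    "standardize",
    "build_projection",
    "check_star_graphs",
    "landscape_metrics",
    "CliqueConflictError",
]

logger = logging.getLogger(__name__)


class CliqueConflictError(ValueError):
    """A clique violated the one-entity-per-prefix assumption."""


# ---------------------------------------------------------------------------
# Cliques
# ---------------------------------------------------------------------------


def extract_cliques(
    doc: MappingDocument, predicate: Predicate = EXACT_MATCH
) -> list[frozenset[Reference]]:
    """Partition entities of the ``predicate`` subgraph into cliques.

    Cliques are connected components of the (undirected view of the)
    exact-match subgraph: after chaining, components become true cliques,
    and component semantics tolerate incomplete closure.  Output is sorted
    by smallest member, so membership is deterministic.
    """
    graph = nx.Graph()
    for mapping in doc.mappings:
        if mapping.predicate == predicate:
            graph.add_edge(mapping.subject, mapping.object)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: min(c))
    return components


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------


@dataclass
class PrioritizationSet:
    """Star-graph mapping of every known entity onto its canonical form."""

    priority: list[str]
    mappings: list[Mapping] = field(default_factory=list)
    _canonical: dict[str, Reference] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.mappings)

    @property
    def canonical_entities(self) -> set[Reference]:
        return {m.object for m in self.mappings}

    def lookup(self, curie: str) -> Optional[Reference]:
        return self._canonical.get(curie)


def _clique_support(
    doc: MappingDocument, member: Reference, clique: frozenset[Reference], predicate: Predicate
) -> tuple[Mapping, ...]:
    supports = [
        m
        for m in doc.mappings
        if m.predicate == predicate
        and (m.subject == member or m.object == member)
        and m.subject in clique
        and m.object in clique
    ]
    supports.sort(key=lambda m: m.triple)
    return tuple(supports)


def build_prioritization(
    doc: MappingDocument,
    priority: list[str],
    predicate: Predicate = EXACT_MATCH,
    on_conflict: Literal["error", "demote", "skip"] = "error",
    extra_terms: Iterable[Reference] = (),
) -> PrioritizationSet:
    """Elect a canonical entity per clique and map every member to it.

    The canonical entity is the member whose prefix appears earliest in
    ``priority``; each clique is assumed to hold at most one entity per
    prefix.  On violation of that assumption the default is a hard error;
    ``demote`` falls back to the highest-priority prefix that *is* a
    singleton within the clique, and ``skip`` drops the clique with a log
    entry.  Cliques with no prefix in the priority list are dropped with a
    log entry.  ``extra_terms`` adds entities that appear in no mapping as
    self-mappings (used when a full term list for a prefix is available;
    otherwise unmapped terms are omitted and totals are lower bounds).
    """
    if not priority:
        raise ValueError("priority prefix list must be non-empty")
    rank = {prefix: i for i, prefix in enumerate(priority)}
    result = PrioritizationSet(priority=list(priority))

    for clique in extract_cliques(doc, predicate):
        by_prefix: dict[str, list[Reference]] = {}
        for member in sorted(clique):
            by_prefix.setdefault(member.prefix, []).append(member)
        duplicated = {p for p, members in by_prefix.items() if len(members) > 1}
        candidates = sorted(
            (p for p in by_prefix if p in rank), key=lambda p: rank[p]
        )
        if not candidates:
            logger.info("clique %s has no prefix in the priority list; skipped",
                        sorted(r.curie for r in clique))
            continue
        canonical: Optional[Reference] = None
        if duplicated:
            if on_conflict == "error":
                raise CliqueConflictError(
                    f"clique {sorted(r.curie for r in clique)} holds multiple entities "
                    f"for prefix(es) {sorted(duplicated)}"
                )
            if on_conflict == "skip":
                logger.warning("clique with duplicated prefix(es) %s skipped", sorted(duplicated))
                continue
            for prefix in candidates:  # demote past duplicated prefixes
                if prefix not in duplicated:
                    canonical = by_prefix[prefix][0]
                    break
            if canonical is None:
                logger.warning("clique has no singleton prefix in priority list; skipped")
                continue
        else:
            canonical = by_prefix[candidates[0]][0]

        for member in sorted(clique):
            supports = _clique_support(doc, member, clique, predicate)
            evidence = ReasonedEvidence(
                justification=PRIORITIZATION_JUSTIFICATION,
                operation="prioritization",
                supporting_mappings=supports,
            )
            result.mappings.append(Mapping(member, predicate, canonical, [evidence]))
            result._canonical[member.curie] = canonical

    placeholder_set = MappingSet(name="prioritization-self", consumer_confidence=1.0)
    for term in sorted(set(extra_terms)):
        if term.curie in result._canonical:
            continue
        evidence = SimpleEvidence(
            justification=PRIORITIZATION_JUSTIFICATION, mapping_set=placeholder_set
        )
        result.mappings.append(Mapping(term, predicate, term, [evidence]))
        result._canonical[term.curie] = term

    check_star_graphs(result)
    return result


def check_star_graphs(prioritization: PrioritizationSet) -> None:
    """Assert the structural guarantees of a prioritization set.

    Per clique: exactly one self-mapping (the canonical), all other members
    map to that same canonical, and no entity appears as subject twice.
    """
    subjects = [m.subject.curie for m in prioritization.mappings]
    if len(subjects) != len(set(subjects)):
        raise AssertionError("an entity appears as the subject of more than one mapping")
    targets_by_canonical: dict[str, list[Mapping]] = {}
    for mapping in prioritization.mappings:
        targets_by_canonical.setdefault(mapping.object.curie, []).append(mapping)
    for canonical, mappings in targets_by_canonical.items():
        self_maps = [m for m in mappings if m.subject.curie == canonical]
        if len(self_maps) != 1:
            raise AssertionError(f"canonical {canonical} lacks exactly one self-mapping")


def standardize(prioritization: PrioritizationSet, curie: str) -> tuple[str, bool]:
    """Map a CURIE to its clique's canonical CURIE.

    Returns ``(canonical, True)`` for known entities and ``(curie, False)``
    unchanged for unknown ones; idempotent and total.
    """
    canonical = prioritization.lookup(curie)
    if canonical is None:
        return curie, False
    return canonical.curie, True


def write_prioritization_tsv(prioritization: PrioritizationSet, path) -> None:
    """Two-column TSV (entity, canonical) with a one-line header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "object_id"])
        for mapping in sorted(prioritization.mappings, key=lambda m: m.triple):
            writer.writerow([mapping.subject.curie, mapping.object.curie])


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


@dataclass
class ProjectionSet:
    """Functional, prefix-pure mapping from one identifier space to another."""

    source_prefix: str
    target_prefix: str
    mappings: list[Mapping] = field(default_factory=list)
    #: subjects excluded for mapping to more than one target, with their mappings
    excluded: dict[str, list[Mapping]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mappings)

    def as_dict(self) -> dict[str, str]:
        return {m.subject.curie: m.object.curie for m in self.mappings}


def build_projection(
    doc: MappingDocument,
    source_prefix: str,
    target_prefix: str,
    predicate: Predicate = EXACT_MATCH,
) -> ProjectionSet:
    """Collect exact matches from ``source_prefix`` onto ``target_prefix``.

    Direct and inferred mappings both qualify (simple and reasoned
    evidence).  Subjects with multiple distinct targets are excluded from
    the projection and reported, so the output is a functional map.
    """
    by_subject: dict[str, dict[str, Mapping]] = {}
    for mapping in doc.mappings:
        if (
            mapping.predicate == predicate
            and mapping.subject.prefix == source_prefix
            and mapping.object.prefix == target_prefix
        ):
            by_subject.setdefault(mapping.subject.curie, {})[mapping.object.curie] = mapping
    projection = ProjectionSet(source_prefix=source_prefix, target_prefix=target_prefix)
    for subject, targets in sorted(by_subject.items()):
        if len(targets) == 1:
            projection.mappings.append(next(iter(targets.values())))
        else:
            projection.excluded[subject] = [targets[k] for k in sorted(targets)]
            logger.warning("projection %s->%s: subject %s has %d targets; excluded",
                           source_prefix, target_prefix, subject, len(targets))
    for mapping in projection.mappings:
        assert mapping.subject.prefix == source_prefix
        assert mapping.object.prefix == target_prefix
    return projection


# ---------------------------------------------------------------------------
# Landscape metrics
# ---------------------------------------------------------------------------


def landscape_metrics(
    doc: MappingDocument, predicate: Predicate = EXACT_MATCH
) -> dict[str, float]:
    """Raw/unique term counts and the reduction percentage.

    ``raw`` counts distinct entities appearing in any mapping; merging each
    clique onto one canonical entity removes ``members − 1`` terms, so
    ``unique = raw − (clique members − cliques)`` and the reduction is
    ``(raw − unique) / raw`` as a percentage.
    """
    entities = {m.subject for m in doc.mappings} | {m.object for m in doc.mappings}
    cliques = extract_cliques(doc, predicate)
    members = sum(len(c) for c in cliques)
    raw = len(entities)
    unique = raw - (members - len(cliques))
    reduction = 100.0 * (raw - unique) / raw if raw else 0.0
    return {
        "raw_terms": raw,
        "unique_terms": unique,
        "reduction_percent": reduction,
        "n_cliques": len(cliques),
    }
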