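"""Graph-based inference over mapping collections.

Mappings form a directed multigraph (subject -> object, one edge per
predicate).  Three operations infer new mappings from existing ones, each
attaching a :class:`~semmap.model.ReasonedEvidence` whose supporting
mappings are the inputs of the operation:

* **inversion** — for an edge ``(A, p, B)`` with no counterpart
  ``(B, inverse(p), A)``, add the reverse edge.  If A is an exact match of
  B then B is an exact match of A; if A is a narrow match of B then B is a
  broad match of A.
* **mutation** — replace a predicate under a configured rule, adding a
  parallel edge.  Generalizations (OWL equivalent-class to SKOS exact
  match) are safe defaults; strengthenings (database cross-reference to
  exact match, has-gene-product to exact match) encode prior knowledge
  about a source's curation practice and carry a per-rule confidence
  factor.
* **chaining** — compose predicates along simple paths of length 2..L
  under a composition table (exact∘exact=exact, exact∘broad=broad, ...),
  adding one mapping per newly connected node pair; every distinct
  supporting path contributes its own evidence to that one mapping.

All traversals iterate nodes and edges in lexicographic CURIE order, so
outputs are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources as _ilr
from typing import Iterable, Optional

import networkx as nx

from .filters import FilterRule, apply_filter
from .io import MappingDocument
from .model import (
    CHAINING_JUSTIFICATION,
    INVERSION_JUSTIFICATION,
    MUTATION_JUSTIFICATION,
    Mapping,
    Predicate,
    PredicateVocabulary,
    ReasonedEvidence,
    Reference,
    default_vocabulary,
)

__all__ = [
    "MappingGraph",
    "ChainRuleTable",
    "MutationRule",
    "default_chain_rules",
    "infer_inversions",
    "apply_mutations",
    "infer_chains",
    "full_process",
    "ProcessingConfig",
    "ProcessingReport",
    "VocabularyError",
]

logger = logging.getLogger(__name__)


class VocabularyError(ValueError):
    """An operation referenced a predicate outside the active vocabulary."""


# ---------------------------------------------------------------------------
# Graph view
# ---------------------------------------------------------------------------


class MappingGraph:
    """Directed multigraph view of a document (lossless, edge key = predicate)."""

    def __init__(self, doc: MappingDocument) -> None:
        self.doc = doc
        self.graph = nx.MultiDiGraph()
        for mapping in doc.mappings:
            self.graph.add_edge(
                mapping.subject, mapping.object, key=mapping.predicate.curie, mapping=mapping
            )

    def has_triple(self, subject: Reference, predicate_curie: str, obj: Reference) -> bool:
        return self.graph.has_edge(subject, obj, key=predicate_curie)

    def sorted_nodes(self) -> list[Reference]:
        return sorted(self.graph.nodes)

    def sorted_out_edges(self, node: Reference) -> list[tuple[Reference, str, Mapping]]:
        edges = [
            (target, key, data["mapping"])
            for _, target, key, data in self.graph.out_edges(node, keys=True, data=True)
        ]
        edges.sort(key=lambda e: (e[0], e[1]))
        return edges

    def triples(self) -> set[tuple[str, str, str]]:
        return {data["mapping"].triple for _, _, data in self.graph.edges(data=True)}


# ---------------------------------------------------------------------------
# Chain-rule table
# ---------------------------------------------------------------------------


class ChainRuleTable:
    """Predicate-pair composition table; missing pairs compose to nothing."""

    def __init__(self, rules: Iterable[tuple[str, str, str]] = ()) -> None:
        self._table: dict[tuple[str, str], str] = {}
        for first, second, result in rules:
            self._table[(first, second)] = result

    def add(self, first: str, second: str, result: str) -> None:
        self._table[(first, second)] = result

    def compose(self, first: Optional[str], second: str) -> Optional[str]:
        """Compose two predicate CURIEs; None is absorbing."""
        if first is None:
            return None
        return self._table.get((first, second))

    def compose_path(self, predicates: Iterable[str]) -> Optional[str]:
        """Left-fold composition of a predicate sequence."""
        result: Optional[str] = None
        for i, predicate in enumerate(predicates):
            result = predicate if i == 0 else self.compose(result, predicate)
            if result is None and i > 0:
                return None
        return result

    def items(self):
        return sorted(self._table.items())


def default_chain_rules() -> ChainRuleTable:
    """The shipped composition table (editable data file)."""
    with _ilr.files("semmap.data").joinpath("chain_rules.json").open("r", encoding="utf-8") as h:
        payload = json.load(h)
    return ChainRuleTable(tuple(rule) for rule in payload["rules"])


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------


def infer_inversions(
    doc: MappingDocument,
    vocabulary: Optional[PredicateVocabulary] = None,
    operation_factor: float = 1.0,
) -> MappingDocument:
    """Add the reverse edge for every mapping lacking one.

    Applying the operation twice is a fixpoint: every edge then has its
    counterpart, so the second pass adds nothing.
    """
    vocabulary = vocabulary or default_vocabulary()
    for mapping in doc.mappings:
        if mapping.predicate not in vocabulary:
            raise VocabularyError(
                f"predicate {mapping.predicate.curie!r} has no declared inverse"
            )
    out = doc.copy()
    graph = MappingGraph(doc)
    for mapping in sorted(doc.mappings, key=lambda m: m.triple):
        inverse = vocabulary.inverse(mapping.predicate)
        if graph.has_triple(mapping.object, inverse.curie, mapping.subject):
            continue
        evidence = ReasonedEvidence(
            justification=INVERSION_JUSTIFICATION,
            operation="inversion",
            supporting_mappings=(mapping,),
            operation_factor=operation_factor,
        )
        out.add(Mapping(mapping.object, inverse, mapping.subject, [evidence]))
    logger.info("inversion: %d -> %d mappings", len(doc), len(out))
    return out


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRule:
    """Replace ``source_predicate`` with ``target_predicate`` on matching edges.

    An optional prefix-pair scope restricts the rule to edges whose subject
    and object prefixes match; ``confidence_factor`` is the gamma applied to
    the mutation evidence.
    """

    source_predicate: str
    target_predicate: str
    subject_prefix: Optional[str] = None
    object_prefix: Optional[str] = None
    confidence_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_factor <= 1.0):
            raise ValueError("confidence_factor must lie in [0, 1]")

    def matches(self, mapping: Mapping) -> bool:
        if mapping.predicate.curie != self.source_predicate:
            return False
        if self.subject_prefix and mapping.subject.prefix != self.subject_prefix:
            return False
        if self.object_prefix and mapping.object.prefix != self.object_prefix:
            return False
        return True


def apply_mutations(
    doc: MappingDocument,
    rules: Iterable[MutationRule],
    vocabulary: Optional[PredicateVocabulary] = None,
) -> MappingDocument:
    """Apply mutation rules, adding a parallel edge per match."""
    vocabulary = vocabulary or default_vocabulary()
    rules = list(rules)
    for rule in rules:
        for curie in (rule.source_predicate, rule.target_predicate):
            if curie not in vocabulary:
                raise VocabularyError(f"mutation rule references unknown predicate {curie!r}")
    out = doc.copy()
    for mapping in sorted(doc.mappings, key=lambda m: m.triple):
        for rule in rules:
            if not rule.matches(mapping):
                continue
            target = vocabulary.predicate(rule.target_predicate, doc.registry)
            evidence = ReasonedEvidence(
                justification=MUTATION_JUSTIFICATION,
                operation="mutation",
                supporting_mappings=(mapping,),
                operation_factor=rule.confidence_factor,
            )
            out.add(Mapping(mapping.subject, target, mapping.object, [evidence]))
    logger.info("mutation: %d -> %d mappings", len(doc), len(out))
    return out


# ---------------------------------------------------------------------------
# Chaining (transitivity)
# ---------------------------------------------------------------------------


def infer_chains(
    doc: MappingDocument,
    rules: Optional[ChainRuleTable] = None,
    max_path_length: int = 5,
    negatives: Iterable[tuple[str, str, str]] = (),
    operation_factor: float = 1.0,
) -> MappingDocument:
    """Infer mappings along predicate-composable simple paths.

    For every ordered node pair connected by a composable path of length
    2..``max_path_length`` and *not* already directly connected by the
    composed predicate, one mapping is added carrying one reasoned evidence
    per supporting path (path mappings in order).  Paths never revisit a
    node, never traverse a triple listed in ``negatives``, and inferred
    triples listed there are suppressed.  The traversal runs over the
    pre-inference edge set only; call the function (or the full pipeline)
    again to close over longer compositions than ``max_path_length``.

    The document should already contain inverted edges so that the directed
    traversal sees every usable step.
    """
    if max_path_length < 2:
        raise ValueError("max_path_length must be at least 2")
    rules = rules or default_chain_rules()
    negative_set = set(negatives)
    graph = MappingGraph(doc)
    existing = graph.triples()

    # (subject, composed predicate, object) -> list of supporting paths
    inferred: dict[tuple[Reference, str, Reference], list[tuple[Mapping, ...]]] = {}

    for start in graph.sorted_nodes():
        # DFS over simple paths; prune when composition dies
        stack: list[tuple[Reference, Optional[str], tuple[Mapping, ...], frozenset]] = [
            (start, None, (), frozenset([start]))
        ]
        while stack:
            node, composed, path, visited = stack.pop()
            if len(path) >= max_path_length:
                continue
            for target, predicate_curie, mapping in graph.sorted_out_edges(node):
                if target in visited:
                    continue
                if mapping.triple in negative_set:
                    continue
                next_composed = (
                    predicate_curie if composed is None
                    else rules.compose(composed, predicate_curie)
                )
                if next_composed is None:
                    continue
                next_path = path + (mapping,)
                if len(next_path) >= 2:
                    candidate = (start.curie, next_composed, target.curie)
                    if candidate not in negative_set and candidate not in existing:
                        inferred.setdefault(
                            (start, next_composed, target), []
                        ).append(next_path)
                stack.append((target, next_composed, next_path, visited | {target}))

    out = doc.copy()
    for (subject, predicate_curie, obj), paths in sorted(
        inferred.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        prefix, _, identifier = predicate_curie.partition(":")
        predicate = Predicate(Reference(prefix, identifier))
        evidences = [
            ReasonedEvidence(
                justification=CHAINING_JUSTIFICATION,
                operation="chain",
                supporting_mappings=path,
                operation_factor=operation_factor,
            )
            for path in sorted(paths, key=lambda p: tuple(m.triple for m in p))
        ]
        out.add(Mapping(subject, predicate, obj, evidences))
    logger.info("chaining: %d -> %d mappings", len(doc), len(out))
    return out


# ---------------------------------------------------------------------------
# High-level processing
# ---------------------------------------------------------------------------


@dataclass
class ProcessingConfig:
    """Everything the high-level processing function needs, in stage order."""

    mutation_rules: list[MutationRule] = field(default_factory=list)
    chain_rules: Optional[ChainRuleTable] = None
    max_path_length: int = 5
    negatives: set[tuple[str, str, str]] = field(default_factory=set)
    filters: list[FilterRule] = field(default_factory=list)
    gamma_inversion: float = 1.0
    gamma_chain: float = 1.0
    vocabulary: Optional[PredicateVocabulary] = None
    stage_order: tuple[str, ...] = ("mutations", "inversions", "chains", "filters")
    enable_inference: bool = True


@dataclass
class ProcessingReport:
    """Per-stage mapping counts for one processing run."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, count: int, removed: int = 0) -> None:
        self.stages.append({"stage": stage, "mappings": count, "removed": removed})


def full_process(
    doc: MappingDocument, config: Optional[ProcessingConfig] = None
) -> tuple[MappingDocument, ProcessingReport]:
    """Run mutations, inversions, chain inference, and filters in order.

    With inference disabled and no filters this is the identity on triples.
    """
    config = config or ProcessingConfig()
    vocabulary = config.vocabulary or default_vocabulary()
    report = ProcessingReport()
    report.record("input", len(doc))
    for stage in config.stage_order:
        if stage == "mutations" and config.enable_inference:
            doc = apply_mutations(doc, config.mutation_rules, vocabulary)
            report.record("mutations", len(doc))
        elif stage == "inversions" and config.enable_inference:
            doc = infer_inversions(doc, vocabulary, config.gamma_inversion)
            report.record("inversions", len(doc))
        elif stage == "chains" and config.enable_inference:
            doc = infer_chains(
                doc,
                config.chain_rules,
                config.max_path_length,
                config.negatives,
                config.gamma_chain,
            )
            report.record("chains", len(doc))
        elif stage == "filters":
            if config.negatives:
                doc, removed = apply_filter(
                    doc, FilterRule(kind="negatives", negatives=tuple(sorted(config.negatives)))
                )
                report.record("negatives", len(doc), len(removed))
            for rule in config.filters:
                doc, removed = apply_filter(doc, rule)
                report.record(f"filter:{rule.kind}", len(doc), len(removed))
    return doc, report
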