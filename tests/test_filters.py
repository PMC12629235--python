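"""Prefix, cardinality, confidence, and negative-mapping filters."""

from __future__ import annotations

import pytest

from semmap.filters import (
    FilterRule,
    apply_filter,
    apply_negatives,
    filter_confidence,
    filter_prefixes,
    flag_cardinality_violations,
    read_negatives_sssom,
    remove_cardinality_violations,
    write_qa_report,
)
from semmap.fixtures import FixtureSpec, fixture_registry, generate
from semmap.inference import infer_chains
from semmap.io import MappingDocument


def merge(documents: dict) -> MappingDocument:
    doc = MappingDocument(registry=fixture_registry(12))
    for part in documents.values():
        doc.extend(part.mappings)
    return doc


# ---------------------------------------------------------------------------
# Prefix filters
# ---------------------------------------------------------------------------


def test_prefix_pair_exclusion_removes_disease_to_gene_mappings(make_doc):
    doc = make_doc(("mondo:1", "oboinowl:hasDbXref", "ncbigene:5"),
                   ("mondo:1", "skos:exactMatch", "doid:9"))
    retained, removed = filter_prefixes(
        doc, FilterRule(kind="prefix_pair", subject_prefix="mondo", object_prefix="ncbigene"))
    assert [m.triple for m in removed] == [("mondo:1", "oboinowl:hasDbXref", "ncbigene:5")]
    assert retained.triples() == {("mondo:1", "skos:exactMatch", "doid:9")}


def test_prefix_filter_matching_nothing_is_identity(make_doc):
    doc = make_doc(("xp0:1", "skos:exactMatch", "xp1:1"))
    retained, removed = filter_prefixes(doc, FilterRule(kind="subject_prefix", prefix="xp5"))
    assert removed == []
    assert retained.triples() == doc.triples()


def test_subject_prefix_exclusion_is_directional(make_doc):
    doc = make_doc(("xp0:1", "skos:exactMatch", "xp1:1"),
                   ("xp1:2", "skos:exactMatch", "xp0:2"))
    retained, removed = filter_prefixes(doc, FilterRule(kind="subject_prefix", prefix="xp0"))
    assert len(removed) == 1  # outgoing only, not incoming
    assert ("xp1:2", "skos:exactMatch", "xp0:2") in retained.triples()


def test_filters_partition_the_input_exactly(make_doc):
    doc = make_doc(*[(f"xp{i % 3}:{i}", "skos:exactMatch", f"xp{(i + 1) % 3}:{i}")
                     for i in range(9)])
    for rule in (FilterRule(kind="subject_prefix", prefix="xp0"),
                 FilterRule(kind="confidence_threshold", threshold=0.5)):
        retained, removed = apply_filter(doc, rule)
        assert len(retained) + len(removed) == len(doc)
        assert retained.triples() | {m.triple for m in removed} == doc.triples()
        assert retained.triples() & {m.triple for m in removed} == set()


def test_disjoint_filters_commute(make_doc):
    doc = make_doc(("xp0:1", "skos:exactMatch", "xp1:1"),
                   ("xp2:1", "skos:exactMatch", "xp3:1"),
                   ("xp4:1", "skos:exactMatch", "xp5:1"))
    a = FilterRule(kind="subject_prefix", prefix="xp0")
    b = FilterRule(kind="object_prefix", prefix="xp3")
    ab, _ = apply_filter(apply_filter(doc, a)[0], b)
    ba, _ = apply_filter(apply_filter(doc, b)[0], a)
    assert ab.triples() == ba.triples()


# ---------------------------------------------------------------------------
# Cardinality
# ---------------------------------------------------------------------------


def test_cardinality_flags_two_targets_in_one_prefix(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B1"),
                   ("xp0:A", "skos:exactMatch", "xp1:B2"))
    report = flag_cardinality_violations(doc)
    assert len(report) == 1
    violation = report.violations[0]
    assert (violation.entity, violation.target_prefix) == ("xp0:A", "xp1")
    assert len(violation.mappings) == 2


def test_cardinality_ok_across_different_prefixes(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                   ("xp0:A", "skos:exactMatch", "xp2:C"))
    assert len(flag_cardinality_violations(doc)) == 0


def test_cardinality_star_graph_has_no_violations(make_doc):
    doc = make_doc(*[(f"xp{i}:S{i}", "skos:exactMatch", "xp0:HUB") for i in range(1, 6)])
    assert len(flag_cardinality_violations(doc)) == 0


def test_cardinality_undirected_mode_counts_incoming(make_doc):
    doc = make_doc(("xp1:B1", "skos:exactMatch", "xp0:A"),
                   ("xp0:A", "skos:exactMatch", "xp1:B2"))
    assert len(flag_cardinality_violations(doc, directional=True)) == 0
    undirected = flag_cardinality_violations(doc, directional=False)
    assert {(v.entity, v.target_prefix) for v in undirected.violations} >= {("xp0:A", "xp1")}


def test_cardinality_delete_mode_drops_whole_group(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B1"),
                   ("xp0:A", "skos:exactMatch", "xp1:B2"),
                   ("xp2:C", "skos:exactMatch", "xp3:D"))
    report = flag_cardinality_violations(doc)
    retained, removed = remove_cardinality_violations(doc, report)
    assert len(removed) == 2
    assert retained.triples() == {("xp2:C", "skos:exactMatch", "xp3:D")}


def test_cardinality_report_recovers_planted_violations(tmp_path):
    spec = FixtureSpec(n_prefixes=6, n_cliques=20, many_to_many_rate=0.4, seed=11)
    documents, truth = generate(spec)
    assert truth.violations  # the spec actually planted some
    report = flag_cardinality_violations(merge(documents))
    assert report.planted_keys() == set(map(tuple, truth.violations))
    out = tmp_path / "qa.tsv"
    write_qa_report(report, out)
    lines = out.read_text().splitlines()
    assert len(lines) == 1 + sum(len(v.mappings) for v in report.violations)


def test_cardinality_clean_fixture_has_no_violations():
    documents, truth = generate(FixtureSpec(n_prefixes=6, n_cliques=20, seed=3))
    assert truth.violations == []
    assert len(flag_cardinality_violations(merge(documents))) == 0


# ---------------------------------------------------------------------------
# Confidence filter
# ---------------------------------------------------------------------------


def test_confidence_threshold_boundaries(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"))  # confidence 0.9
    assert filter_confidence(doc, 0.0)[1] == []
    retained, removed = filter_confidence(doc, 1.0)
    assert len(removed) == 1 and len(retained) == 0


def test_confidence_filter_uses_noisy_or_of_evidences(make_mapping):
    doc = MappingDocument(registry=fixture_registry(4))
    mapping = make_mapping("xp0:A", "skos:exactMatch", "xp1:B")
    # two evidences at c_e = 0.5 each -> c_m = 0.75
    from semmap.model import MappingSet, SimpleEvidence
    half = MappingSet(name="half", consumer_confidence=0.5)
    mapping.evidences[:] = [
        SimpleEvidence(justification="semapv:ManualMappingCuration", mapping_set=half),
        SimpleEvidence(justification="semapv:LexicalMatching", mapping_set=half),
    ]
    doc.add(mapping)
    assert mapping.confidence == pytest.approx(0.75, abs=1e-15)
    _, removed = filter_confidence(doc, 0.8)
    assert len(removed) == 1


# ---------------------------------------------------------------------------
# Negatives
# ---------------------------------------------------------------------------


def test_negative_triple_is_removed(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"))
    retained, removed = apply_negatives(doc, {("xp0:A", "skos:exactMatch", "xp1:B")})
    assert len(removed) == 1 and len(retained) == 0


def test_negative_middle_edge_blocks_inferred_endpoint(make_doc):
    triples = [("xp0:A", "skos:exactMatch", "xp1:B"),
               ("xp1:B", "skos:exactMatch", "xp2:C"),
               ("xp2:C", "skos:exactMatch", "xp3:D")]
    doc = make_doc(*triples)
    negatives = {("xp1:B", "skos:exactMatch", "xp2:C")}
    open_doc = infer_chains(doc)
    blocked = infer_chains(doc, negatives=negatives)
    assert ("xp0:A", "skos:exactMatch", "xp3:D") in open_doc.triples()
    assert ("xp0:A", "skos:exactMatch", "xp3:D") not in blocked.triples()
    assert ("xp2:C", "skos:exactMatch", "xp3:D") in blocked.triples()


def test_absent_negatives_are_a_noop_with_notice(make_doc, caplog):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"))
    with caplog.at_level("INFO"):
        retained, removed = apply_negatives(doc, {("xp5:Z", "skos:exactMatch", "xp4:Y")})
    assert removed == [] and retained.triples() == doc.triples()
    assert any("no-op" in r.message for r in caplog.records)


def test_read_negatives_sssom_predicate_modifier_convention(tmp_path):
    path = tmp_path / "negatives.sssom.tsv"
    path.write_text(
        "subject_id\tpredicate_id\tobject_id\tmapping_justification\tpredicate_modifier\n"
        "xp0:A\tskos:exactMatch\txp1:B\tsemapv:ManualMappingCuration\tNot\n"
        "xp0:A\tskos:exactMatch\txp2:C\tsemapv:ManualMappingCuration\t\n",
        encoding="utf-8",
    )
    negatives = read_negatives_sssom(path, fixture_registry(4))
    assert negatives == {("xp0:A", "skos:exactMatch", "xp1:B")}
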