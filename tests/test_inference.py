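"""Inversion, mutation, and chain inference against brute-force oracles."""

from __future__ import annotations

import random

import pytest

from oracles import closure_oracle
from semmap.inference import (
    ChainRuleTable,
    MutationRule,
    ProcessingConfig,
    VocabularyError,
    apply_mutations,
    default_chain_rules,
    full_process,
    infer_chains,
    infer_inversions,
)
from semmap.fixtures import fig1_toy
from semmap.model import ReasonedEvidence
from conftest import random_graph_triples


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------


def test_inversion_adds_symmetric_counterpart(make_doc):
    doc = infer_inversions(make_doc(("xp0:A", "skos:exactMatch", "xp1:B")))
    assert ("xp1:B", "skos:exactMatch", "xp0:A") in doc.triples()
    assert len(doc) == 2


def test_inversion_swaps_broad_and_narrow(make_doc):
    doc = infer_inversions(make_doc(("xp0:A", "skos:narrowMatch", "xp1:B")))
    assert ("xp1:B", "skos:broadMatch", "xp0:A") in doc.triples()


def test_inversion_is_a_fixpoint_and_adds_no_duplicates(make_doc):
    doc = make_doc(
        ("xp0:A", "skos:exactMatch", "xp1:B"),
        ("xp1:B", "skos:exactMatch", "xp0:A"),  # counterpart already present
        ("xp2:C", "skos:broadMatch", "xp3:D"),
    )
    once = infer_inversions(doc)
    assert len(once) == 4
    twice = infer_inversions(once)
    assert twice.triples() == once.triples()
    assert len(twice) == len(once)


def test_inversion_evidence_points_at_source_mapping(make_doc):
    doc = infer_inversions(make_doc(("xp0:A", "skos:narrowMatch", "xp1:B")))
    inverted = [m for m in doc.mappings if m.triple[1] == "skos:broadMatch"][0]
    evidence = inverted.evidences[0]
    assert isinstance(evidence, ReasonedEvidence)
    assert evidence.operation == "inversion"
    assert evidence.supporting_mappings[0].triple == ("xp0:A", "skos:narrowMatch", "xp1:B")


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


def test_mutation_generalizes_owl_equivalence(make_doc):
    doc = apply_mutations(
        make_doc(("xp0:A", "owl:equivalentClass", "xp1:B")),
        [MutationRule("owl:equivalentClass", "skos:exactMatch")],
    )
    assert ("xp0:A", "skos:exactMatch", "xp1:B") in doc.triples()
    assert ("xp0:A", "owl:equivalentClass", "xp1:B") in doc.triples()  # parallel edge


def test_mutation_strengthens_gene_product_with_scoped_rule(make_mapping, make_doc):
    doc = make_doc(("xp0:gene1", "ro:0002205", "xp1:protein1"),
                   ("xp2:gene2", "ro:0002205", "xp3:protein2"))
    rule = MutationRule("ro:0002205", "skos:exactMatch",
                        subject_prefix="xp0", object_prefix="xp1",
                        confidence_factor=0.8)
    out = apply_mutations(doc, [rule])
    assert ("xp0:gene1", "skos:exactMatch", "xp1:protein1") in out.triples()
    assert ("xp2:gene2", "skos:exactMatch", "xp3:protein2") not in out.triples()
    mutated = [m for m in out.mappings
               if m.triple == ("xp0:gene1", "skos:exactMatch", "xp1:protein1")][0]
    assert mutated.evidences[0].operation_factor == 0.8
    assert mutated.confidence <= 0.8 + 1e-15


def test_mutation_with_empty_rule_list_is_identity(make_doc):
    doc = make_doc(("xp0:A", "oboinowl:hasDbXref", "xp1:B"))
    assert apply_mutations(doc, []).triples() == doc.triples()


def test_mutation_rejects_unknown_predicate(make_doc):
    with pytest.raises(VocabularyError):
        apply_mutations(make_doc(("xp0:A", "skos:exactMatch", "xp1:B")),
                        [MutationRule("skos:exactMatch", "skos:notAPredicate")])


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def test_chain_exact_exact_yields_exact(make_doc):
    doc = infer_chains(make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                                ("xp1:B", "skos:exactMatch", "xp2:C")))
    assert ("xp0:A", "skos:exactMatch", "xp2:C") in doc.triples()


def test_chain_exact_broad_yields_broad(make_doc):
    doc = infer_chains(make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                                ("xp1:B", "skos:broadMatch", "xp2:C")))
    assert ("xp0:A", "skos:broadMatch", "xp2:C") in doc.triples()


def test_chain_broad_narrow_composes_to_nothing(make_doc):
    doc = make_doc(("xp0:A", "skos:broadMatch", "xp1:B"),
                   ("xp1:B", "skos:narrowMatch", "xp2:C"))
    out = infer_chains(doc)
    assert out.triples() == doc.triples()


def test_chain_respects_negatives_as_path_steps(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                   ("xp1:B", "skos:exactMatch", "xp2:C"))
    blocked = infer_chains(doc, negatives={("xp1:B", "skos:exactMatch", "xp2:C")})
    assert ("xp0:A", "skos:exactMatch", "xp2:C") not in blocked.triples()


def test_chain_multiple_paths_attach_multiple_evidences(make_doc):
    doc = make_doc(
        ("xp0:A", "skos:exactMatch", "xp1:B"),
        ("xp1:B", "skos:exactMatch", "xp3:D"),
        ("xp0:A", "skos:exactMatch", "xp2:C"),
        ("xp2:C", "skos:exactMatch", "xp3:D"),
    )
    out = infer_chains(doc)
    inferred = [m for m in out.mappings if m.triple == ("xp0:A", "skos:exactMatch", "xp3:D")]
    assert len(inferred) == 1
    assert len(inferred[0].evidences) == 2  # one per supporting path


def test_chain_confidence_order_invariance(make_doc):
    # the same two paths discovered in either order give the same noisy-OR
    doc_ab = make_doc(
        ("xp0:A", "skos:exactMatch", "xp1:B"),
        ("xp1:B", "skos:exactMatch", "xp3:D"),
        ("xp0:A", "skos:exactMatch", "xp2:C"),
        ("xp2:C", "skos:exactMatch", "xp3:D"),
    )
    doc_ba = make_doc(
        ("xp0:A", "skos:exactMatch", "xp2:C"),
        ("xp2:C", "skos:exactMatch", "xp3:D"),
        ("xp0:A", "skos:exactMatch", "xp1:B"),
        ("xp1:B", "skos:exactMatch", "xp3:D"),
    )
    get = lambda doc: [m for m in infer_chains(doc).mappings
                       if m.triple == ("xp0:A", "skos:exactMatch", "xp3:D")][0].confidence
    assert get(doc_ab) == pytest.approx(get(doc_ba), abs=1e-15)


def test_chain_rejects_bad_max_path_length(make_doc):
    with pytest.raises(ValueError):
        infer_chains(make_doc(("xp0:A", "skos:exactMatch", "xp1:B")), max_path_length=1)


def test_chain_inferred_confidence_bounded_by_gamma(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                   ("xp1:B", "skos:exactMatch", "xp2:C"))
    out = infer_chains(doc, operation_factor=0.5)
    inferred = [m for m in out.mappings if m.triple == ("xp0:A", "skos:exactMatch", "xp2:C")][0]
    assert inferred.confidence <= 0.5 + 1e-15


@pytest.mark.parametrize("seed", range(30))
def test_chain_closure_matches_path_enumeration_oracle(make_doc, seed):
    rng = random.Random(seed)
    n_nodes = rng.randint(4, 12)
    triples = random_graph_triples(rng, n_nodes, rng.randint(n_nodes, 2 * n_nodes))
    max_len = rng.choice([2, 3, 4])
    doc = make_doc(*triples)
    out = infer_chains(doc, max_path_length=max_len)
    table = dict(default_chain_rules().items())
    expected = closure_oracle(triples, {k: v for k, v in table.items()}, max_len)
    assert out.triples() - doc.triples() == expected


def test_chain_provenance_is_grounded_in_pre_inference_graph(make_doc):
    doc = make_doc(("xp0:A", "skos:exactMatch", "xp1:B"),
                   ("xp1:B", "skos:exactMatch", "xp2:C"),
                   ("xp2:C", "skos:exactMatch", "xp3:D"))
    original = doc.triples()
    out = infer_chains(doc)
    for mapping in out.mappings:
        for evidence in mapping.evidences:
            if isinstance(evidence, ReasonedEvidence):
                for support in evidence.supporting_mappings:
                    assert support.triple in original
                # confidence computable => provenance is a DAG
                assert 0.0 <= evidence.confidence <= 1.0


# ---------------------------------------------------------------------------
# Full processing
# ---------------------------------------------------------------------------


def test_full_process_without_inference_is_identity_on_triples(make_doc):
    doc = make_doc(("xp0:A", "oboinowl:hasDbXref", "xp1:B"))
    out, _ = full_process(doc, ProcessingConfig(enable_inference=False))
    assert out.triples() == doc.triples()


def test_full_process_toy_graph_produces_multi_hop_equivalence():
    doc = fig1_toy()
    assert ("tis:0001", "skos:exactMatch", "ont:0001") not in doc.triples()
    config = ProcessingConfig(
        mutation_rules=[MutationRule("oboinowl:hasDbXref", "skos:exactMatch",
                                     confidence_factor=0.7)]
    )
    out, report = full_process(doc, config)
    assert ("tis:0001", "skos:exactMatch", "ont:0001") in out.triples()
    assert [s["stage"] for s in report.stages] == ["input", "mutations", "inversions", "chains"]


def test_full_process_twice_reaches_fixpoint():
    config = ProcessingConfig(
        mutation_rules=[MutationRule("oboinowl:hasDbXref", "skos:exactMatch")],
        max_path_length=6,
    )
    once, _ = full_process(fig1_toy(), config)
    twice, _ = full_process(once, config)
    assert twice.triples() == once.triples()


def test_chain_rule_table_override():
    table = ChainRuleTable([("skos:closeMatch", "skos:closeMatch", "skos:closeMatch")])
    assert table.compose_path(["skos:closeMatch", "skos:closeMatch"]) == "skos:closeMatch"
    assert table.compose_path(["skos:closeMatch", "skos:exactMatch"]) is None
    assert table.compose(None, "skos:exactMatch") is None
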