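"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own closed forms and graph
traversal: confidence oracles enumerate the underlying Bernoulli
correctness events outright, and the closure oracle enumerates every
simple path and folds the composition table over it.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional


def enumerate_or(probabilities: list[float]) -> float:
    """P(at least one of several independent events) by full enumeration."""
    total = 0.0
    for outcome in itertools.product([True, False], repeat=len(probabilities)):
        weight = 1.0
        for happened, p in zip(outcome, probabilities):
            weight *= p if happened else (1.0 - p)
        if any(outcome):
            total += weight
    return total


def simple_evidence_oracle(c_set: float, c_producer: Optional[float]) -> float:
    if c_producer is None:
        return c_set
    return enumerate_or([c_set, c_producer])


def mapping_oracle(evidence_probs: list[float]) -> float:
    return enumerate_or(evidence_probs)


def reasoned_oracle(gamma: float, support_probs: list[float]) -> float:
    return gamma * enumerate_or(support_probs)


def closure_oracle(
    edges: Iterable[tuple[str, str, str]],
    table: dict[tuple[str, str], str],
    max_path_length: int,
    negatives: Iterable[tuple[str, str, str]] = (),
) -> set[tuple[str, str, str]]:
    """All triples implied by composable simple paths of length 2..L.

    Enumerates every simple path explicitly, composes predicates left to
    right through ``table`` (missing pair kills the path), and keeps
    endpoint triples that are not already direct edges and not negative.
    Paths never traverse a negative triple.
    """
    edges = [e for e in edges]
    negative_set = set(negatives)
    existing = set(edges)
    out_edges: dict[str, list[tuple[str, str]]] = {}
    for s, p, o in edges:
        if (s, p, o) in negative_set:
            continue
        out_edges.setdefault(s, []).append((p, o))

    inferred: set[tuple[str, str, str]] = set()

    def walk(start: str, node: str, composed: Optional[str], length: int, visited: set[str]) -> None:
        if length >= max_path_length:
            return
        for predicate, target in out_edges.get(node, ()):  # parallel edges included
            if target in visited:
                continue
            next_composed = predicate if composed is None else table.get((composed, predicate))
            if next_composed is None:
                continue
            if length + 1 >= 2:
                candidate = (start, next_composed, target)
                if candidate not in existing and candidate not in negative_set:
                    inferred.add(candidate)
            walk(start, target, next_composed, length + 1, visited | {target})

    for node in sorted(out_edges):
        walk(node, node, None, 0, {node})
    return inferred
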