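"""Declarative pipeline: ingest -> process -> assemble -> export.

A pipeline is described by a YAML configuration (schema:
:class:`PipelineConfig`, version 1) listing the sources to integrate, the
inference and filter settings, the prefix priority list, and the outputs
to write.  The run itself is deterministic by construction — repeated runs
on identical inputs and configuration produce byte-identical outputs —
and emits a run report with per-stage counts, landscape metrics, and a
content-hash manifest of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import assembly as _assembly
from .filters import FilterRule, flag_cardinality_violations, read_negatives_sssom, write_qa_report
from .inference import (
    ChainRuleTable,
    MutationRule,
    ProcessingConfig,
    default_chain_rules,
    full_process,
)
from .io import MappingDocument, export_property_graph, read_sssom, read_xref_tsv, write_sssom
from .model import (
    MappingSet,
    Predicate,
    default_registry,
    default_vocabulary,
    validate_reference,
)
from .fixtures import fig1_toy

__all__ = [
    "PipelineConfig",
    "InputConfig",
    "OutputConfig",
    "load_config",
    "dump_config",
    "run_pipeline",
    "RunReport",
]

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


class InputConfig(BaseModel):
    """One source to ingest."""

    kind: Literal["sssom", "xref", "fig1_toy"]
    path: Optional[str] = None
    name: str = ""
    version: str = ""
    license: str = ""
    consumer_confidence: float = Field(1.0, ge=0.0, le=1.0)
    #: for kind=xref: the declared default predicate CURIE
    default_predicate: str = "oboinowl:hasDbXref"
    excluded_prefixes: list[str] = Field(default_factory=list)


class MutationConfig(BaseModel):
    source_predicate: str
    target_predicate: str
    subject_prefix: Optional[str] = None
    object_prefix: Optional[str] = None
    confidence_factor: float = Field(1.0, ge=0.0, le=1.0)


class FilterConfig(BaseModel):
    kind: Literal[
        "subject_prefix", "object_prefix", "prefix_pair", "cardinality",
        "confidence_threshold", "negatives",
    ]
    prefix: Optional[str] = None
    subject_prefix: Optional[str] = None
    object_prefix: Optional[str] = None
    threshold: Optional[float] = Field(None, ge=0.0, le=1.0)
    negatives: list[list[str]] = Field(default_factory=list)
    delete: bool = False


class OutputConfig(BaseModel):
    format: Literal["sssom", "pgraph", "prioritization", "projection", "qa_cardinality", "report"]
    path: str
    #: for format=projection
    source_prefix: Optional[str] = None
    target_prefix: Optional[str] = None


class PipelineConfig(BaseModel):
    """The declarative pipeline specification (YAML schema, version 1)."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    inputs: list[InputConfig] = Field(default_factory=list)
    mutations: list[MutationConfig] = Field(default_factory=list)
    chain_rules: Optional[list[list[str]]] = None
    max_path_length: int = Field(5, ge=2)
    gamma_inversion: float = Field(1.0, ge=0.0, le=1.0)
    gamma_chain: float = Field(1.0, ge=0.0, le=1.0)
    enable_inference: bool = True
    stage_order: list[str] = Field(
        default_factory=lambda: ["mutations", "inversions", "chains", "filters"]
    )
    filters: list[FilterConfig] = Field(default_factory=list)
    negatives_paths: list[str] = Field(default_factory=list)
    priority: list[str] = Field(default_factory=list)
    on_clique_conflict: Literal["error", "demote", "skip"] = "error"
    outputs: list[OutputConfig] = Field(default_factory=list)
    seed: int = 0
    strict: bool = False

    @field_validator("stage_order")
    @classmethod
    def _known_stages(cls, value: list[str]) -> list[str]:
        known = {"mutations", "inversions", "chains", "filters"}
        unknown = set(value) - known
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; known: {sorted(known)}")
        return value

    def needs_prioritization(self) -> bool:
        return any(o.format == "prioritization" for o in self.outputs)


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML."""
    with open(path, "r", encoding="utf-8") as handle:
        payload = yaml.safe_load(handle) or {}
    config = PipelineConfig.model_validate(payload)
    if config.needs_prioritization() and not config.priority:
        raise ValueError("priority prefix list must be non-empty when a "
                         "prioritization output is requested")
    return config


def dump_config(config: PipelineConfig, path) -> None:
    """Write a configuration back to YAML (lossless round-trip)."""
    payload = config.model_dump(mode="json")
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True, default_flow_style=False), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Counts, metrics, and output manifest for one pipeline run."""

    stage_counts: list[dict] = field(default_factory=list)
    evidence_counts: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "evidence_counts": self.evidence_counts,
                "metrics": self.metrics,
                "output_hashes": self.output_hashes,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def _sha256_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _ingest(config: PipelineConfig, base_dir: Path) -> MappingDocument:
    registry = default_registry()
    doc = MappingDocument(registry=registry)
    for source in config.inputs:
        if source.kind == "fig1_toy":
            part = fig1_toy(registry)
        elif source.kind == "sssom":
            defaults = MappingSet(
                name=source.name or Path(source.path).stem,
                version=source.version,
                license=source.license,
                consumer_confidence=source.consumer_confidence,
            )
            part = read_sssom(
                base_dir / source.path,
                set_defaults=defaults,
                consumer_confidence=source.consumer_confidence,
                registry=registry,
                strict=config.strict,
            )
        elif source.kind == "xref":
            metadata = MappingSet(
                name=source.name or Path(source.path).stem,
                version=source.version,
                license=source.license,
                consumer_confidence=source.consumer_confidence,
            )
            predicate = Predicate(validate_reference(source.default_predicate, registry))
            part = read_xref_tsv(
                base_dir / source.path,
                default_predicate=predicate,
                set_metadata=metadata,
                registry=registry,
                excluded_prefixes=source.excluded_prefixes,
                strict=config.strict,
            )
        else:  # pragma: no cover - pydantic forbids
            raise ValueError(f"unknown input kind {source.kind!r}")
        for prefix, uri in part.prefix_map.items():
            doc.prefix_map.setdefault(prefix, uri)
        doc.extensions.update(part.extensions)
        doc.extend(part.mappings)
    return doc


def run_pipeline(config: PipelineConfig, base_dir=".") -> RunReport:
    """Execute a declarative pipeline end to end."""
    base_dir = Path(base_dir)
    report = RunReport()

    doc = _ingest(config, base_dir)
    negatives: set[tuple[str, str, str]] = set()
    for negatives_path in config.negatives_paths:
        negatives |= read_negatives_sssom(base_dir / negatives_path, doc.registry)

    chain_rules: Optional[ChainRuleTable] = None
    if config.chain_rules is not None:
        chain_rules = default_chain_rules()
        for first, second, result in config.chain_rules:
            chain_rules.add(first, second, result)

    processing = ProcessingConfig(
        mutation_rules=[MutationRule(**m.model_dump()) for m in config.mutations],
        chain_rules=chain_rules,
        max_path_length=config.max_path_length,
        negatives=negatives,
        filters=[FilterRule(
            kind=f.kind, prefix=f.prefix, subject_prefix=f.subject_prefix,
            object_prefix=f.object_prefix, threshold=f.threshold,
            negatives=tuple(tuple(t) for t in f.negatives), delete=f.delete,
        ) for f in config.filters],
        gamma_inversion=config.gamma_inversion,
        gamma_chain=config.gamma_chain,
        vocabulary=default_vocabulary(),
        stage_order=tuple(config.stage_order),
        enable_inference=config.enable_inference,
    )
    processed, processing_report = full_process(doc, processing)
    report.stage_counts = processing_report.stages

    report.evidence_counts = {
        "mappings": len(processed),
        "evidences": sum(len(m.evidences) for m in processed.mappings),
        "mapping_sets": len(processed.mapping_sets),
    }
    report.metrics = _assembly.landscape_metrics(processed)

    prioritization = None
    if config.priority:
        prioritization = _assembly.build_prioritization(
            processed, config.priority, on_conflict=config.on_clique_conflict
        )
        report.metrics["canonical_entities"] = len(prioritization.canonical_entities)

    for output in config.outputs:
        target = base_dir / output.path
        if output.format == "sssom":
            write_sssom(processed, target)
            report.output_hashes[output.path] = _sha256_file(target)
        elif output.format == "pgraph":
            written = export_property_graph(processed, target)
            for name, file_path in sorted(written.items()):
                report.output_hashes[f"{output.path}/{name}"] = _sha256_file(file_path)
        elif output.format == "prioritization":
            _assembly.write_prioritization_tsv(prioritization, target)
            report.output_hashes[output.path] = _sha256_file(target)
        elif output.format == "projection":
            projection = _assembly.build_projection(
                processed, output.source_prefix, output.target_prefix
            )
            projection_doc = MappingDocument(registry=processed.registry)
            projection_doc.extend(projection.mappings)
            write_sssom(projection_doc, target)
            report.output_hashes[output.path] = _sha256_file(target)
        elif output.format == "qa_cardinality":
            qa = flag_cardinality_violations(processed)
            write_qa_report(qa, target)
            report.output_hashes[output.path] = _sha256_file(target)
        elif output.format == "report":
            target.parent.mkdir(parents=True, exist_ok=True)
            # written last, below, so it can include every other hash
            continue
    for output in config.outputs:
        if output.format == "report":
            target = base_dir / output.path
            target.parent.mkdir(parents=True, exist_ok=True)
            target.write_text(report.to_json(), encoding="utf-8")
    return report
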