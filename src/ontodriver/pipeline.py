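"""High-level orchestration: ontologies + annotations -> corpora ->
embedding tables -> gene representations -> cross-validated classifiers ->
candidate predictions.  Used by the CLI and by programmatic callers that
want the whole chain in a few calls."""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

from .classifier import (
    CVReport,
    DriverGeneClassifier,
    LabelMatrix,
    ModelConfig,
)
from .corpus import AnnotationRecord, build_corpus
from .embedding import (
    EmbeddingParams,
    EmbeddingTable,
    GeneFeatureMatrix,
    build_representation,
)
from .embedding import train_embeddings
from .ontology import Ontology, infer_subclass_closure, merge_ontologies

__all__ = ["train_all_tables", "build_features", "evaluate_mode", "predict_novel"]


def _tag_seed(base_seed: int, tag: str) -> int:
    # stable across runs and processes (no builtin hash randomization)
    return (base_seed * 1_000_003 + sum(ord(c) for c in tag)) % (2**31)


def train_all_tables(
    ontologies: Mapping[str, Ontology],
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    params: EmbeddingParams,
    include_metadata: bool = True,
    include_inferred: bool = True,
    merged_tag: str = "MERGED",
) -> dict[str, EmbeddingTable]:
    """One embedding table per ontology plus one for the merged ontology.

    Each source's corpus contains its (closed) axioms, class-label
    metadata, and that source's gene associations; the merged table is
    trained on the union ontology with all annotations.
    """
    tables: dict[str, EmbeddingTable] = {}
    closed = {
        tag: infer_subclass_closure(ontology) if include_inferred else ontology
        for tag, ontology in ontologies.items()
    }
    for tag in sorted(closed):
        corpus = build_corpus(
            closed[tag],
            list(annotations.get(tag, ())),
            include_metadata=include_metadata,
            include_inferred=include_inferred,
        )
        genes = {record.gene_id for record in annotations.get(tag, ())}
        tables[tag] = train_embeddings(
            corpus, replace(params, seed=_tag_seed(params.seed, tag)), genes
        )

    merged = merge_ontologies(sorted(closed.values(), key=lambda o: o.source_tag), merged_tag)
    all_annotations = [r for tag in sorted(annotations) for r in annotations[tag]]
    merged_corpus = build_corpus(
        merged,
        all_annotations,
        include_metadata=include_metadata,
        include_inferred=include_inferred,
    )
    genes = {record.gene_id for record in all_annotations}
    tables[merged_tag] = train_embeddings(
        merged_corpus, replace(params, seed=_tag_seed(params.seed, merged_tag)), genes
    )
    return tables


def build_features(
    mode: str,
    tables: Mapping[str, EmbeddingTable],
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    source_order: Sequence[str] | None = None,
) -> GeneFeatureMatrix:
    order = tuple(source_order) if source_order else tuple(sorted(t for t in tables if t != "MERGED"))
    return build_representation(mode, tables, annotations, source_order=order)


def evaluate_mode(
    mode: str,
    tables: Mapping[str, EmbeddingTable],
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    labels: LabelMatrix,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    source_order: Sequence[str] | None = None,
) -> tuple[GeneFeatureMatrix, CVReport]:
    """Assemble one representation and cross-validate it."""
    features = build_features(mode, tables, annotations, source_order)
    report = DriverGeneClassifier(features, labels, config).cross_validate(k=k, seed=seed)
    return features, report


def predict_novel(
    features: GeneFeatureMatrix,
    labels: LabelMatrix,
    config: ModelConfig | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> dict[str, list[tuple[str, float]]]:
    """Train on the full balanced sets and list novel candidates per type."""
    clf = DriverGeneClassifier(features, labels, config)
    return clf.fit(seed=seed).predict_candidates(threshold=threshold)
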