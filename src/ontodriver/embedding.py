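"""Train gene/class embeddings on the sentence corpus and assemble the
five gene feature representations (per-ontology, intersection, union).

Genes are themselves corpus tokens (they occur in "hasAnnotation"
sentences), so a gene's feature vector is read directly from the trained
vocabulary.  Gene tokens are exempt from ``min_count`` pruning: a gene with
a single annotation still occurs in the corpus and must receive a vector
for the union representation to cover every annotated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotationRecord, Corpus
from .skipgram import train_sgns

__all__ = [
    "EmbeddingParams",
    "EmbeddingTable",
    "GeneFeatureMatrix",
    "train_embeddings",
    "build_representation",
    "REPRESENTATION_MODES",
]

REPRESENTATION_MODES = ("cmpo", "go", "mp", "intersection", "union")


@dataclass(frozen=True)
class EmbeddingParams:
    """Skip-gram hyperparameters.

    ``dim``, ``window`` and ``min_count`` default to the values selected in
    the underlying study (100 / 5 / 5); ``epochs`` is not reported there
    and defaults to 60, enough for convergence on corpora of a few
    thousand short sentences.
    """

    dim: int = 100
    window: int = 5
    min_count: int = 5
    model: str = "skip-gram"
    epochs: int = 60
    seed: int = 0
    negative: int = 5
    learning_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.window <= 0 or self.min_count <= 0 or self.epochs <= 0:
            raise ValueError("dim, window, min_count and epochs must be positive")
        if self.model != "skip-gram":
            raise ValueError(f"unsupported model {self.model!r}")


@dataclass
class EmbeddingTable:
    """Token -> d-dimensional vector map with its training parameters."""

    vectors: dict[str, np.ndarray]
    params: EmbeddingParams

    def __post_init__(self) -> None:
        for token, vec in self.vectors.items():
            if vec.shape != (self.params.dim,):
                raise ValueError(f"vector for {token!r} has shape {vec.shape}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite vector for {token!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __len__(self) -> int:
        return len(self.vectors)

    def save(self, path: str | Path) -> None:
        """Write word2vec text format: header "N dim", then token + floats."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"{len(self.vectors)} {self.params.dim}\n")
            for token in sorted(self.vectors):
                floats = " ".join(repr(float(x)) for x in self.vectors[token])
                handle.write(f"{token} {floats}\n")

    @classmethod
    def load(cls, path: str | Path, params: EmbeddingParams | None = None) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as handle:
            header = handle.readline().split()
            n, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in handle:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise ValueError(f"{path}: header promises {n} vectors, found {len(vectors)}")
        if params is None:
            params = EmbeddingParams(dim=dim)
        return cls(vectors, params)


def train_embeddings(
    corpus: Corpus | Sequence[Sequence[str]],
    params: EmbeddingParams,
    entity_tokens: Iterable[str] = (),
) -> EmbeddingTable:
    """Train skip-gram vectors on a corpus.

    ``entity_tokens`` (gene ids) are kept in the vocabulary regardless of
    corpus frequency.  Training is deterministic for a fixed
    ``params.seed`` (single worker, fixed window).
    """
    sentences = (
        [list(s.tokens) for s in corpus.sentences]
        if isinstance(corpus, Corpus)
        else [list(s) for s in corpus]
    )
    if not sentences:
        raise ValueError("empty corpus")
    vectors = train_sgns(
        sentences,
        dim=params.dim,
        window=params.window,
        min_count=params.min_count,
        epochs=params.epochs,
        negative=params.negative,
        learning_rate=params.learning_rate,
        seed=params.seed,
        keep_tokens=entity_tokens,
    )
    return EmbeddingTable(vectors, params)


@dataclass
class GeneFeatureMatrix:
    """Per-gene feature rows for one representation mode."""

    gene_ids: list[str]
    matrix: np.ndarray
    mode: str
    source_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("row count must match gene_ids")

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.matrix[self.gene_ids.index(gene_id)]

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.matrix, index=pd.Index(self.gene_ids, name="gene_id"))
        frame.columns = [f"f{i}" for i in range(self.p)]
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "unknown") -> "GeneFeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(list(frame.index.astype(str)), frame.to_numpy(), mode)


def _annotated_genes(annotations: Sequence[AnnotationRecord]) -> set[str]:
    return {record.gene_id for record in annotations}


def build_representation(
    mode: str,
    tables: Mapping[str, EmbeddingTable],
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    source_order: Sequence[str] = ("CMPO", "GO", "MP"),
    merged_tag: str = "MERGED",
) -> GeneFeatureMatrix:
    """Assemble one of the five gene representations.

    Modes
    -----
    single source (e.g. ``"cmpo"``)
        Genes with at least one annotation in that source and a stored
        vector in its table; feature width = dim.
    ``"intersection"``
        Genes annotated in all sources; features are the per-source
        vectors concatenated in ``source_order``; width = len(sources)*dim.
    ``"union"``
        Genes with a vector in the merged-ontology table (every gene with
        at least one annotation anywhere); width = dim.
    """
    mode = mode.lower()
    order = tuple(source_order)
    by_tag = {tag.lower(): tag for tag in order}

    if mode == "union":
        if merged_tag not in tables:
            raise KeyError(f"union mode requires a {merged_tag!r} embedding table")
        table = tables[merged_tag]
        annotated = set().union(*(_annotated_genes(a) for a in annotations.values()))
        genes = sorted(g for g in annotated if g in table)
        matrix = np.vstack([table[g] for g in genes]) if genes else np.empty((0, table.params.dim))
        return GeneFeatureMatrix(genes, matrix, mode, (merged_tag,))

    if mode == "intersection":
        missing = [tag for tag in order if tag not in tables]
        if missing:
            raise KeyError(f"intersection mode requires tables for {missing}")
        gene_sets = [
            {g for g in _annotated_genes(annotations.get(tag, ())) if g in tables[tag]}
            for tag in order
        ]
        genes = sorted(set.intersection(*gene_sets)) if gene_sets else []
        dim = tables[order[0]].params.dim
        matrix = (
            np.vstack([np.concatenate([tables[tag][g] for tag in order]) for g in genes])
            if genes
            else np.empty((0, len(order) * dim))
        )
        return GeneFeatureMatrix(genes, matrix, mode, order)

    if mode in by_tag:
        tag = by_tag[mode]
        if tag not in tables:
            raise KeyError(f"mode {mode!r} requires an embedding table for {tag!r}")
        table = tables[tag]
        genes = sorted(
            g for g in _annotated_genes(annotations.get(tag, ())) if g in table
        )
        matrix = np.vstack([table[g] for g in genes]) if genes else np.empty((0, table.params.dim))
        return GeneFeatureMatrix(genes, matrix, mode, (tag,))

    raise ValueError(f"unknown representation mode {mode!r}")
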