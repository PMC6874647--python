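"""Render ontology axioms, class labels, and gene annotations into a
sentence corpus for skip-gram training.

Each axiom becomes one short sentence ("T_2 SubClassOf T_1"; existential
restrictions render as five tokens), each gene-class association becomes a
three-token "hasAnnotation" sentence, and class labels optionally become
metadata sentences.  Plain subclass sentences are 3 tokens and existential
ones 5, so a window of 5 spans essentially every sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ontology import Axiom, Ontology

__all__ = [
    "AnnotationRecord",
    "Sentence",
    "Corpus",
    "render_axiom",
    "build_corpus",
    "read_annotations",
    "write_annotations",
    "write_corpus",
    "read_corpus",
]

ASSOCIATION_RELATION = "hasAnnotation"


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene -> ontology-class association from one annotation source."""

    gene_id: str
    class_id: str
    source_tag: str

    def __post_init__(self) -> None:
        if not self.gene_id or not self.class_id:
            raise ValueError("gene_id and class_id must be non-empty")


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError("a sentence needs at least two tokens")
        if any((not t) or any(c.isspace() for c in t) for t in self.tokens):
            raise ValueError("tokens must be non-empty and whitespace-free")

    def __str__(self) -> str:
        return " ".join(self.tokens)


@dataclass
class Corpus:
    sentences: list[Sentence]
    counts: dict[str, int] = field(
        default_factory=lambda: {"axiom": 0, "metadata": 0, "association": 0}
    )

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != len(self.sentences):
            raise ValueError("category tallies must sum to the sentence count")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


def _token(class_id: str) -> str:
    """Underscore form of a class id, so each id is a single token."""
    return class_id.replace(":", "_")


def render_axiom(axiom: Axiom) -> Sentence:
    """Render a subclass axiom as one sentence.

    Plain subclass axioms give 3 tokens (``subject SubClassOf object``);
    existential restrictions give 5 (``subject SubClassOf relation some
    object``).
    """
    if axiom.kind == "subclass":
        return Sentence((_token(axiom.subject), "SubClassOf", _token(axiom.object)))
    return Sentence(
        (
            _token(axiom.subject),
            "SubClassOf",
            axiom.relation,
            "some",
            _token(axiom.object),
        )
    )


def _label_sentence(class_id: str, label: str) -> Sentence | None:
    tokens = tuple(label.lower().split())
    if not tokens:
        return None
    return Sentence((_token(class_id), "label") + tokens)


def build_corpus(
    ontology: Ontology,
    annotations: Sequence[AnnotationRecord],
    include_metadata: bool = True,
    include_inferred: bool = True,
) -> Corpus:
    """Assemble the training corpus from one ontology and its annotations.

    Sentence order is deterministic: axioms (sorted), then class-label
    metadata (sorted by class id), then associations (sorted), so the
    corpus is invariant under permutation of the annotation input.

    Raises
    ------
    ValueError
        If any annotation references a class id absent from ``ontology``
        (all offenders are listed).
    """
    unknown = sorted({a.class_id for a in annotations} - set(ontology.classes))
    if unknown:
        raise ValueError(
            "annotations reference unknown class ids: " + ", ".join(unknown)
        )

    sentences: list[Sentence] = []
    counts = {"axiom": 0, "metadata": 0, "association": 0}

    axiom_sentences = {
        render_axiom(axiom)
        for axiom in ontology.axioms
        if include_inferred or axiom.provenance == "asserted"
    }
    for sentence in sorted(axiom_sentences, key=lambda s: s.tokens):
        sentences.append(sentence)
        counts["axiom"] += 1

    if include_metadata:
        for cid in ontology.class_ids:
            label = ontology.classes[cid].label
            if label and (sentence := _label_sentence(cid, label)):
                sentences.append(sentence)
                counts["metadata"] += 1

    for record in sorted(
        annotations, key=lambda r: (r.gene_id, r.class_id, r.source_tag)
    ):
        sentences.append(
            Sentence((record.gene_id, ASSOCIATION_RELATION, _token(record.class_id)))
        )
        counts["association"] += 1

    return Corpus(sentences, counts)


# ---------------------------------------------------------------------------
# I/O: GAF-like annotation TSV and one-sentence-per-line corpus files


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a GAF-like TSV (columns gene_id, class_id, source_tag; header
    required; ``#`` comments allowed)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "class_id", "source_tag"}
    if missing := required - set(frame.columns):
        raise ValueError(f"{path}: missing annotation columns: {sorted(missing)}")
    return [
        AnnotationRecord(row.gene_id, row.class_id, row.source_tag)
        for row in frame.itertuples(index=False)
    ]


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.gene_id, r.class_id, r.source_tag) for r in records],
        columns=["gene_id", "class_id", "source_tag"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{sentence}\n" for sentence in corpus.sentences), encoding="utf-8"
    )


def read_corpus(path: str | Path) -> list[list[str]]:
    """Read a corpus file back as token lists (category tallies are not
    recoverable from the flat file)."""
    with open(path, encoding="utf-8") as handle:
        return [line.split() for line in handle if line.strip()]
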