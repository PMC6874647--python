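"""Ontology ingestion, merging, and structural subclass reasoning.

Ontologies (GO-, MP-, CMPO-style vocabularies) are read from OBO 1.2 files
or from a bounded subset of OWL functional syntax, represented as a set of
classes plus a set of axioms, and closed under transitivity of the plain
subclass relation.  Only named-class subclass axioms and single existential
restrictions (``A SubClassOf r some B``) are modelled; this covers the
dominant axiom shape in the annotation ontologies the pipeline consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyClass",
    "Axiom",
    "Ontology",
    "OntologyParseError",
    "OntologyValidationError",
    "parse_ontology",
    "parse_obo",
    "parse_owl_functional",
    "infer_subclass_closure",
    "merge_ontologies",
    "write_obo",
]


class OntologyParseError(ValueError):
    """Raised when an input file cannot be interpreted in its declared format."""


class OntologyValidationError(ValueError):
    """Raised when a structurally invalid ontology is constructed or required."""


def normalize_curie(identifier: str) -> str:
    """Canonicalize a class identifier to CURIE colon form.

    Underscore form (``GO_0005634``) and full OBO PURLs are accepted on
    input; ``GO:0005634`` is canonical in memory.
    """
    identifier = identifier.strip()
    if identifier.startswith("<") and identifier.endswith(">"):
        identifier = identifier[1:-1]
    if "/" in identifier:  # IRI: keep the final path fragment
        identifier = identifier.rsplit("/", 1)[-1]
    if "#" in identifier:
        identifier = identifier.rsplit("#", 1)[-1]
    if ":" not in identifier and "_" in identifier:
        prefix, _, local = identifier.partition("_")
        identifier = f"{prefix}:{local}"
    return identifier


@dataclass(frozen=True)
class OntologyClass:
    """A named ontology class (term)."""

    id: str
    label: str | None = None
    definition: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyValidationError("class id must be non-empty")
        if self.id.count(":") != 1:
            raise OntologyValidationError(
                f"class id {self.id!r} must contain exactly one prefix separator"
            )


@dataclass(frozen=True)
class Axiom:
    """A subclass axiom between named classes.

    ``kind`` is ``"subclass"`` (``subject SubClassOf object``) or
    ``"subclass-existential"`` (``subject SubClassOf relation some object``).
    Provenance does not participate in equality: an inferred axiom is the
    same logical statement as its asserted counterpart.
    """

    kind: str
    subject: str
    object: str
    relation: str | None = None
    provenance: str = field(default="asserted", compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("subclass", "subclass-existential"):
            raise OntologyValidationError(f"unknown axiom kind {self.kind!r}")
        if self.kind == "subclass" and self.relation is not None:
            raise OntologyValidationError("plain subclass axiom carries no relation")
        if self.kind == "subclass-existential" and not self.relation:
            raise OntologyValidationError("existential axiom requires a relation")
        if self.provenance not in ("asserted", "inferred"):
            raise OntologyValidationError(f"unknown provenance {self.provenance!r}")


class Ontology:
    """A set of classes plus a set of subclass axioms over them."""

    def __init__(
        self,
        classes: Iterable[OntologyClass],
        axioms: Iterable[Axiom] = (),
        source_tag: str = "UNNAMED",
    ) -> None:
        self.classes: dict[str, OntologyClass] = {}
        for cls in classes:
            if cls.id in self.classes:
                raise OntologyValidationError(f"duplicate class id {cls.id!r}")
            self.classes[cls.id] = cls
        self.axioms: set[Axiom] = set()
        self.source_tag = source_tag
        for axiom in axioms:
            self.add_axiom(axiom)

    def add_axiom(self, axiom: Axiom) -> None:
        for endpoint in (axiom.subject, axiom.object):
            if endpoint not in self.classes:
                raise OntologyValidationError(
                    f"axiom endpoint {endpoint!r} is not a declared class "
                    f"in ontology {self.source_tag!r}"
                )
        self.axioms.add(axiom)

    @property
    def class_ids(self) -> list[str]:
        return sorted(self.classes)

    def subclass_axioms(self, include_inferred: bool = True) -> list[Axiom]:
        """Plain subclass axioms in deterministic order."""
        return sorted(
            (
                a
                for a in self.axioms
                if a.kind == "subclass"
                and (include_inferred or a.provenance == "asserted")
            ),
            key=lambda a: (a.subject, a.object),
        )

    def subclass_graph(self) -> nx.DiGraph:
        """Directed graph with an edge subject -> object per plain subclass axiom."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self.classes)
        graph.add_edges_from(
            (a.subject, a.object) for a in self.axioms if a.kind == "subclass"
        )
        return graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self.classes == other.classes and self.axioms == other.axioms

    def __repr__(self) -> str:
        return (
            f"Ontology(source_tag={self.source_tag!r}, "
            f"n_classes={len(self.classes)}, n_axioms={len(self.axioms)})"
        )


# ---------------------------------------------------------------------------
# Parsing


def parse_ontology(path: str | Path, format: str | None = None) -> Ontology:
    """Parse an ontology file into an :class:`Ontology`.

    Parameters
    ----------
    path
        File in OBO 1.2 or OWL functional syntax.
    format
        ``"obo"`` or ``"owl-functional"``; inferred from the extension
        (``.obo`` vs ``.owl``/``.ofn``) when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"ontology file not found: {path}")
    if format is None:
        format = "obo" if path.suffix == ".obo" else "owl-functional"
    if format == "obo":
        return parse_obo(path)
    if format == "owl-functional":
        return parse_owl_functional(path)
    raise ValueError(f"unknown ontology format {format!r}")


def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2 file (term stanzas: id, name, def, is_a, relationship)."""
    path = Path(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise OntologyParseError(f"malformed OBO file {path}: {exc}") from exc

    classes: list[OntologyClass] = []
    declared: set[str] = set()
    for node, data in graph.nodes(data=True):
        node_id = normalize_curie(node)
        definition = data.get("def")
        if definition:
            match = re.match(r'"(.*)"', definition)
            definition = match.group(1) if match else definition
        classes.append(
            OntologyClass(id=node_id, label=data.get("name"), definition=definition)
        )
        declared.add(node_id)

    source_tag = path.stem.upper()
    ontology = Ontology(classes, source_tag=source_tag)
    for child, parent, key in graph.edges(keys=True):
        child, parent = normalize_curie(child), normalize_curie(parent)
        if key == "is_a":
            ontology.add_axiom(Axiom("subclass", child, parent))
        else:
            ontology.add_axiom(
                Axiom("subclass-existential", child, parent, relation=key)
            )
    return ontology


_OWL_DECLARATION = re.compile(r"Declaration\s*\(\s*Class\s*\(\s*(\S+?)\s*\)\s*\)")
_OWL_SUBCLASS = re.compile(r"SubClassOf\s*\(\s*(\S+)\s+(\S+?)\s*\)")
_OWL_SUBCLASS_EXIST = re.compile(
    r"SubClassOf\s*\(\s*(\S+)\s+ObjectSomeValuesFrom\s*\(\s*(\S+)\s+(\S+?)\s*\)\s*\)"
)
_OWL_LABEL = re.compile(
    r"AnnotationAssertion\s*\(\s*rdfs:label\s+(\S+)\s+\"(.*?)\"(?:\^\^\S+)?\s*\)"
)


def parse_owl_functional(path: str | Path) -> Ontology:
    """Parse the supported OWL functional-syntax subset.

    Recognized: ``Declaration(Class(..))``, ``SubClassOf`` between named
    classes, ``SubClassOf`` with a single ``ObjectSomeValuesFrom`` filler,
    and ``rdfs:label`` annotation assertions.  Every other axiom line is
    skipped and counted in a single warning.
    """
    path = Path(path)
    declarations: list[str] = []
    labels: dict[str, str] = {}
    axioms: list[tuple[str, str, str, str | None]] = []
    skipped = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "//", "Prefix(", "Ontology(")) or line == ")":
                continue
            if match := _OWL_DECLARATION.fullmatch(line):
                declarations.append(normalize_curie(match.group(1)))
            elif match := _OWL_SUBCLASS_EXIST.fullmatch(line):
                sub, rel, obj = match.groups()
                axioms.append(
                    (
                        "subclass-existential",
                        normalize_curie(sub),
                        normalize_curie(obj),
                        normalize_curie(rel).replace(":", "_")
                        if "/" in rel or rel.startswith("<")
                        else rel,
                    )
                )
            elif match := _OWL_SUBCLASS.fullmatch(line):
                sub, obj = match.groups()
                axioms.append(("subclass", normalize_curie(sub), normalize_curie(obj), None))
            elif match := _OWL_LABEL.fullmatch(line):
                labels[normalize_curie(match.group(1))] = match.group(2)
            elif line.startswith(("Declaration(", "SubClassOf(", "AnnotationAssertion(")):
                raise OntologyParseError(
                    f"{path}:{lineno}: cannot parse axiom line: {line[:80]}"
                )
            else:
                skipped += 1
    if skipped:
        logger.warning("%s: skipped %d unsupported OWL axiom(s)", path, skipped)
    if not declarations and not axioms:
        raise OntologyParseError(f"{path}: no OWL declarations or axioms found")

    classes = [
        OntologyClass(id=cid, label=labels.get(cid)) for cid in dict.fromkeys(declarations)
    ]
    ontology = Ontology(classes, source_tag=path.stem.upper())
    for kind, sub, obj, rel in axioms:
        ontology.add_axiom(Axiom(kind, sub, obj, relation=rel))
    return ontology


# ---------------------------------------------------------------------------
# Reasoning and merging


def infer_subclass_closure(ontology: Ontology) -> Ontology:
    """Close the plain subclass relation under transitivity.

    Returns a copy whose axiom set additionally contains every transitively
    entailed plain subclass axiom, marked ``inferred``.  Reflexive axioms
    are never added; asserted axioms are unchanged.  Existential
    restrictions are not propagated.

    Raises
    ------
    OntologyValidationError
        If the plain-subclass graph contains a cycle (listed in the message).
    """
    graph = ontology.subclass_graph()
    if not nx.is_directed_acyclic_graph(graph):
        cycle = [edge[0] for edge in nx.find_cycle(graph)]
        raise OntologyValidationError(
            "subclass cycle detected: " + " -> ".join(cycle + cycle[:1])
        )
    closed = Ontology(ontology.classes.values(), ontology.axioms, ontology.source_tag)
    closure = nx.transitive_closure_dag(graph)
    for subject, object_ in closure.edges():
        if subject != object_:
            closed.axioms.add(Axiom("subclass", subject, object_, provenance="inferred"))
    return closed


def merge_ontologies(parts: list[Ontology], source_tag: str = "MERGED") -> Ontology:
    """Union of classes (keyed by id, first label wins) and axioms."""
    if not parts:
        raise ValueError("merge_ontologies requires a non-empty list")
    classes: dict[str, OntologyClass] = {}
    for part in parts:
        for cid, cls in part.classes.items():
            if cid not in classes:
                classes[cid] = cls
            elif cls.label and classes[cid].label and cls.label != classes[cid].label:
                logger.warning(
                    "conflicting labels for %s: keeping %r, ignoring %r",
                    cid,
                    classes[cid].label,
                    cls.label,
                )
    merged = Ontology(classes.values(), source_tag=source_tag)
    for part in parts:
        for axiom in part.axioms:
            merged.add_axiom(replace(axiom))
    return merged


# ---------------------------------------------------------------------------
# Writing (used by the synthetic-data generator and for round-trip checks)


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write an ontology as an OBO 1.2 document (asserted axioms only)."""
    path = Path(path)
    is_a: dict[str, list[str]] = {}
    rels: dict[str, list[tuple[str, str]]] = {}
    for axiom in sorted(
        (a for a in ontology.axioms if a.provenance == "asserted"),
        key=lambda a: (a.subject, a.relation or "", a.object),
    ):
        if axiom.kind == "subclass":
            is_a.setdefault(axiom.subject, []).append(axiom.object)
        else:
            rels.setdefault(axiom.subject, []).append((axiom.relation, axiom.object))
    lines = ["format-version: 1.2", f"ontology: {ontology.source_tag.lower()}", ""]
    for cid in ontology.class_ids:
        cls = ontology.classes[cid]
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        if cls.label:
            lines.append(f"name: {cls.label}")
        if cls.definition:
            lines.append(f'def: "{cls.definition}" []')
        for parent in is_a.get(cid, ()):
            lines.append(f"is_a: {parent}")
        for relation, obj in rels.get(cid, ()):
            lines.append(f"relationship: {relation} {obj}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
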