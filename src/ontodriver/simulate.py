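"""Self-contained synthetic datasets with the statistical structure the
pipeline assumes.

The generator emits everything the pipeline consumes — three DAG
ontologies (OBO), per-source gene annotations, a driver label table, a
driver-enriched interaction network, a mutation count table, and variant
tables with shifted pathogenicity scores — with a *planted* driver
signature: driver genes draw their annotations preferentially from a
designated ontology subtree per cancer type, so the signal must flow
through the corpus -> embedding -> classifier chain to be recovered.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classifier import LabelMatrix
from .corpus import AnnotationRecord, write_annotations
from .ontology import Axiom, Ontology, OntologyClass, write_obo
from .stats import DEFAULT_TOOL_ORIENTATIONS, InteractionNetwork, VariantRecord

__all__ = [
    "SyntheticConfig",
    "generate_ontology",
    "designated_subtrees",
    "generate_gene_data",
    "generate_network",
    "generate_mutation_data",
    "generate_variants",
    "write_variants_tsv",
    "simulate",
]

SOURCE_TAGS = ("CMPO", "GO", "MP")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    ``signal_strength`` is the probability that each annotation of a
    driver gene is drawn from its cancer type's designated subtree
    (0 gives the null dataset); ``complementary_signal`` restricts each
    type's signal to a single ontology so that the three sources carry
    complementary information.
    """

    n_classes_per_ontology: int = 20
    dag_branching: int = 2
    n_genes: int = 500
    n_cancer_types: int = 3
    driver_fraction: float = 0.2
    signal_strength: float = 0.9
    annotations_per_gene: int = 6
    source_presence: float = 0.7
    complementary_signal: bool = False
    second_type_probability: float = 0.2
    p_within: float = 0.5
    p_background: float = 0.01
    variant_shift: dict[str, float] = field(
        default_factory=lambda: {tool: 2.0 for tool in DEFAULT_TOOL_ORIENTATIONS}
    )
    variants_per_group: int = 200
    mutation_rate_driver: float = 3e-3
    mutation_rate_background: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.driver_fraction,
            self.source_presence,
            self.p_within,
            self.p_background,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.p_within < self.p_background:
            raise ValueError("p_within must be >= p_background")
        if self.n_classes_per_ontology < 2:
            raise ValueError("need at least two classes per ontology")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# Ontology


def _class_id(source_tag: str, i: int) -> str:
    return f"{source_tag}:{i:07d}"


def generate_ontology(
    config: SyntheticConfig, source_tag: str, stream: int = 0
) -> Ontology:
    """Rooted DAG: a complete ``dag_branching``-ary tree of plain subclass
    axioms over ``n_classes_per_ontology`` classes, plus one existential
    ("part_of") axiom on ~10% of non-root classes."""
    n = config.n_classes_per_ontology
    b = config.dag_branching
    rng = _rng(config, stream)
    classes = [
        OntologyClass(
            id=_class_id(source_tag, i),
            label=f"{source_tag.lower()} term {i}",
        )
        for i in range(1, n + 1)
    ]
    ontology = Ontology(classes, source_tag=source_tag)
    for i in range(2, n + 1):  # complete b-ary tree: parent of i is (i-2)//b + 1
        parent = (i - 2) // b + 1
        ontology.add_axiom(
            Axiom("subclass", _class_id(source_tag, i), _class_id(source_tag, parent))
        )
    n_existential = max(0, int(round(0.1 * (n - 1))))
    non_root = np.arange(2, n + 1)
    chosen = rng.choice(non_root, size=min(n_existential, non_root.size), replace=False)
    for i in sorted(int(x) for x in chosen):
        target = int(rng.integers(1, n + 1))
        if target == i:
            target = 1
        ontology.add_axiom(
            Axiom(
                "subclass-existential",
                _class_id(source_tag, i),
                _class_id(source_tag, target),
                relation="part_of",
            )
        )
    return ontology


def designated_subtrees(ontology: Ontology, n_subtrees: int) -> list[set[str]]:
    """Per-cancer-type signal subtrees.

    Levels of the subclass tree are scanned from the root down; the first
    level with at least ``n_subtrees`` nodes supplies the subtree roots,
    and each subtree is that root plus all its subclass descendants.
    """
    graph = ontology.subclass_graph()  # edges child -> parent
    roots = [node for node in graph.nodes if graph.out_degree(node) == 0]
    children: dict[str, list[str]] = {node: [] for node in graph.nodes}
    for child, parent in graph.edges():
        children[parent].append(child)
    level = sorted(roots)
    while level and len(level) < n_subtrees:
        level = sorted(c for node in level for c in children[node])
    if len(level) < n_subtrees:
        raise ValueError(
            f"ontology {ontology.source_tag} has no level with {n_subtrees} nodes"
        )

    def descendants(node: str) -> set[str]:
        out = {node}
        stack = [node]
        while stack:
            for child in children[stack.pop()]:
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    return [descendants(level[i]) for i in range(n_subtrees)]


# ---------------------------------------------------------------------------
# Genes, labels, annotations


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def generate_gene_data(
    ontologies: dict[str, Ontology], config: SyntheticConfig, stream: int = 10
) -> tuple[dict[str, list[AnnotationRecord]], LabelMatrix]:
    """Assign driver labels and draw per-source annotations.

    A fraction ``driver_fraction`` of genes becomes a driver for one
    (occasionally two) cancer types.  Each annotation of a driver gene is
    drawn from the type's designated subtree with probability
    ``signal_strength`` and uniformly otherwise; non-driver annotations
    are uniform over non-root classes.
    """
    rng = _rng(config, stream)
    tags = sorted(ontologies)
    genes = [_gene_id(i) for i in range(1, config.n_genes + 1)]
    types = [f"cancer_type_{t + 1}" for t in range(config.n_cancer_types)]

    subtrees = {
        tag: designated_subtrees(ontologies[tag], config.n_cancer_types) for tag in tags
    }
    pools: dict[str, list[str]] = {}
    for tag in tags:
        graph = ontologies[tag].subclass_graph()
        roots = {c for c in graph.nodes if graph.out_degree(c) == 0}
        pools[tag] = sorted(set(ontologies[tag].classes) - roots)

    indicator = np.zeros((len(genes), len(types)), dtype=bool)
    primary_type = np.full(len(genes), -1, dtype=int)
    for i in range(len(genes)):
        if rng.random() < config.driver_fraction:
            t = int(rng.integers(config.n_cancer_types))
            indicator[i, t] = True
            primary_type[i] = t
            if config.n_cancer_types > 1 and rng.random() < config.second_type_probability:
                extra = int(rng.integers(config.n_cancer_types - 1))
                if extra >= t:
                    extra += 1
                indicator[i, extra] = True

    annotations: dict[str, list[AnnotationRecord]] = {tag: [] for tag in tags}
    for i, gene in enumerate(genes):
        present = [tag for tag in tags if rng.random() < config.source_presence]
        if not present:
            present = [tags[int(rng.integers(len(tags)))]]
        base, remainder = divmod(config.annotations_per_gene, len(present))
        counts = {
            tag: base + (1 if j < remainder else 0) for j, tag in enumerate(present)
        }
        for tag in present:
            pool = pools[tag]
            signal_here = primary_type[i] >= 0 and (
                not config.complementary_signal
                or tags[primary_type[i] % len(tags)] == tag
            )
            subtree = (
                sorted(subtrees[tag][primary_type[i]]) if signal_here else None
            )
            seen: set[str] = set()
            for _ in range(counts[tag]):
                if subtree and rng.random() < config.signal_strength:
                    cls = subtree[int(rng.integers(len(subtree)))]
                else:
                    cls = pool[int(rng.integers(len(pool)))]
                if cls in seen:  # keep records unique per (gene, class, source)
                    continue
                seen.add(cls)
                annotations[tag].append(AnnotationRecord(gene, cls, tag))

    labels = LabelMatrix(genes, types, indicator)
    return annotations, labels


# ---------------------------------------------------------------------------
# Network, mutations, variants


def generate_network(
    labels: LabelMatrix, config: SyntheticConfig, stream: int = 20
) -> InteractionNetwork:
    """Erdos-Renyi background at ``p_background`` with driver-driver pairs
    upgraded to ``p_within``."""
    rng = _rng(config, stream)
    genes = labels.gene_ids
    driver = labels.indicator.any(axis=1)
    iu, ju = np.triu_indices(len(genes), k=1)
    p = np.where(driver[iu] & driver[ju], config.p_within, config.p_background)
    keep = rng.random(p.size) < p
    edges = [(genes[int(a)], genes[int(b)]) for a, b in zip(iu[keep], ju[keep])]
    return InteractionNetwork(genes, edges)


def generate_mutation_data(
    labels: LabelMatrix,
    config: SyntheticConfig,
    stream: int = 30,
    elevated: set[str] | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-gene somatic mutation counts and gene lengths.

    Lengths are log-uniform between 500 bp and 50 kb; counts are Poisson
    with per-base rate ``mutation_rate_driver`` for genes in ``elevated``
    (default: the labelled driver genes) and ``mutation_rate_background``
    otherwise.
    """
    rng = _rng(config, stream)
    if elevated is None:
        driver = labels.indicator.any(axis=1)
    else:
        driver = np.array([g in elevated for g in labels.gene_ids])
    lengths = np.exp(rng.uniform(np.log(500), np.log(50_000), size=len(labels.gene_ids)))
    lengths = lengths.astype(int)
    rates = np.where(driver, config.mutation_rate_driver, config.mutation_rate_background)
    counts = rng.poisson(rates * lengths)
    return (
        {g: int(c) for g, c in zip(labels.gene_ids, counts)},
        {g: int(l) for g, l in zip(labels.gene_ids, lengths)},
    )


def generate_variants(
    labels: LabelMatrix,
    candidates: set[str] | None,
    config: SyntheticConfig,
    stream: int = 40,
) -> list[VariantRecord]:
    """Variant tables with driver-shifted pathogenicity scores.

    Scores are Normal(0, 1) for variants in non-driver genes and
    Normal(delta_tool, 1) in driver/candidate genes, with the sign flipped
    for lower-is-worse tools; 90% of variants are coding; allele frequency
    is missing for 30% and otherwise a rare/common uniform mixture.
    """
    rng = _rng(config, stream)
    candidates = candidates or set()
    driver_side = sorted(
        set(g for g, d in zip(labels.gene_ids, labels.indicator.any(axis=1)) if d)
        | candidates
    )
    background = sorted(set(labels.gene_ids) - set(driver_side))
    if not driver_side or not background:
        raise ValueError("need both driver-side and background genes for variants")

    tools = sorted(config.variant_shift)
    records: list[VariantRecord] = []
    counter = 0
    for group, shifted in ((driver_side, True), (background, False)):
        for _ in range(config.variants_per_group):
            counter += 1
            gene = group[int(rng.integers(len(group)))]
            scores = {}
            for tool in tools:
                delta = config.variant_shift[tool] if shifted else 0.0
                value = rng.normal(delta, 1.0)
                if DEFAULT_TOOL_ORIENTATIONS.get(tool) == "lower_worse":
                    value = -value
                scores[tool] = float(value)
            coding = bool(rng.random() < 0.9)
            if rng.random() < 0.3:
                af = None
            elif rng.random() < 0.5:
                af = float(rng.uniform(0.0, 0.01))
            else:
                af = float(rng.uniform(0.0, 0.5))
            records.append(
                VariantRecord(
                    gene_id=gene,
                    variant_id=f"var{counter:06d}",
                    coding_flag=coding,
                    allele_frequency=af,
                    scores=scores,
                )
            )
    return records


def write_variants_tsv(records: list[VariantRecord], path: str | Path) -> None:
    tools = sorted({tool for r in records for tool in r.scores})
    lines = ["\t".join(["gene_id", "variant_id", "coding", "allele_frequency"] + tools)]
    for r in records:
        row = [
            r.gene_id,
            r.variant_id,
            str(bool(r.coding_flag)),
            "" if r.allele_frequency is None else f"{r.allele_frequency:.6g}",
        ]
        row += ["" if tool not in r.scores else f"{r.scores[tool]:.6g}" for tool in tools]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# One-call simulation writing every artifact


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate the full synthetic dataset and write every file format the
    pipeline consumes.  Returns the manifest (also written as
    ``manifest.json``) recording config, seeds, paths and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ontologies = {
        tag: generate_ontology(config, tag, stream=i)
        for i, tag in enumerate(SOURCE_TAGS)
    }
    annotations, labels = generate_gene_data(ontologies, config)
    network = generate_network(labels, config)
    mutation_counts, gene_lengths = generate_mutation_data(labels, config)
    variants = generate_variants(labels, None, config)

    paths: dict[str, str] = {}
    for tag, ontology in ontologies.items():
        path = outdir / f"{tag.lower()}.obo"
        write_obo(ontology, path)
        paths[f"ontology_{tag.lower()}"] = str(path)
    for tag, records in annotations.items():
        path = outdir / f"annotations_{tag.lower()}.tsv"
        write_annotations(records, path)
        paths[f"annotations_{tag.lower()}"] = str(path)
    labels.to_tsv(outdir / "labels.tsv")
    paths["labels"] = str(outdir / "labels.tsv")
    network.to_tsv(outdir / "network.tsv")
    paths["network"] = str(outdir / "network.tsv")

    mutation_path = outdir / "mutations.tsv"
    with open(mutation_path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tmutation_count\tgene_length\n")
        for gene in labels.gene_ids:
            handle.write(f"{gene}\t{mutation_counts[gene]}\t{gene_lengths[gene]}\n")
    paths["mutations"] = str(mutation_path)

    variants_path = outdir / "variants.tsv"
    write_variants_tsv(variants, variants_path)
    paths["variants"] = str(variants_path)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "paths": paths,
        "checksums": {name: _sha256(Path(p)) for name, p in paths.items()},
        "n_genes": len(labels.gene_ids),
        "n_drivers": int(labels.indicator.any(axis=1).sum()),
        "cancer_types": labels.cancer_types,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
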