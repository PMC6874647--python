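"""Validation statistics for predicted driver genes.

Three tests back a driver-gene prediction:

1. **Mutation-frequency comparison** — per-gene somatic mutation count
   divided by gene length, compared between predicted-driver and
   non-driver genes with a one-tailed Welch t-test.
2. **Network-module permutation test** — the number of candidate genes
   directly connected to a known driver in an interaction network,
   against a null built by repeatedly sampling equally many random nodes
   (default 10,000 draws).  Both the empirical permutation p-value and a
   one-sample t-style p-value against the null draws are reported.
3. **Pathogenicity-score enrichment** — per prediction tool, a one-tailed
   Mann-Whitney U test that coding, rare variants in candidate genes are
   scored more deleterious than variants in comparison genes, with the
   tail direction set by each tool's score orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "MutationStats",
    "InteractionNetwork",
    "VariantRecord",
    "TestResult",
    "PermutationConfig",
    "DEFAULT_TOOL_ORIENTATIONS",
    "mutation_frequency",
    "read_mutation_table",
    "welch_t_test_one_tailed",
    "mann_whitney_one_tailed",
    "connection_count",
    "network_permutation_test",
    "filter_coding_variants",
    "filter_rare_variants",
    "pathogenicity_enrichment",
    "read_variants_tsv",
    "read_variants_vcf",
]

#: Score-orientation convention per pathogenicity tool: whether a lower or
#: a higher raw score means a more damaging variant.
DEFAULT_TOOL_ORIENTATIONS: dict[str, str] = {
    "SIFT": "lower_worse",
    "FATHMM": "lower_worse",
    "PolyPhen-2": "higher_worse",
    "MutationAssessor": "higher_worse",
    "MutationTaster": "higher_worse",
    "CADD": "higher_worse",
    "VEST3": "higher_worse",
}


@dataclass(frozen=True)
class MutationStats:
    gene_id: str
    mutation_count: int
    gene_length: int
    frequency: float


@dataclass(frozen=True)
class VariantRecord:
    gene_id: str
    variant_id: str
    coding_flag: bool | None = None
    allele_frequency: float | None = None
    scores: Mapping[str, float] = field(default_factory=dict)


@dataclass
class TestResult:
    """Outcome of one validation test."""

    test_name: str
    statistic: float
    p_value: float
    direction: str
    n_group_a: int
    n_group_b: int
    null_summary: dict[str, float] | None = None
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "null_summary": self.null_summary,
            **self.extra,
        }


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    sample_size: int | None = None  # default: number of candidate genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be positive")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError("sample_size must be positive")


# ---------------------------------------------------------------------------
# Mutation frequency


def mutation_frequency(
    mutation_counts: Mapping[str, int], gene_lengths: Mapping[str, int]
) -> list[MutationStats]:
    """Per-gene somatic mutation frequency: count / gene length (bases)."""
    records: list[MutationStats] = []
    for gene in sorted(mutation_counts):
        count = int(mutation_counts[gene])
        if count < 0:
            raise ValueError(f"negative mutation count for {gene!r}")
        length = gene_lengths.get(gene)
        if length is None or length <= 0:
            raise ValueError(f"missing or non-positive gene length for {gene!r}")
        records.append(MutationStats(gene, count, int(length), count / length))
    return records


def read_mutation_table(path: str | Path) -> list[MutationStats]:
    """TSV with columns gene_id, mutation_count, gene_length."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if missing := {"gene_id", "mutation_count", "gene_length"} - set(frame.columns):
        raise ValueError(f"{path}: missing mutation-table columns: {sorted(missing)}")
    return mutation_frequency(
        dict(zip(frame["gene_id"], frame["mutation_count"])),
        dict(zip(frame["gene_id"], frame["gene_length"])),
    )


# ---------------------------------------------------------------------------
# Welch t-test


def welch_t_test_one_tailed(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "a_greater"
) -> TestResult:
    """One-tailed Welch two-sample t-test (unequal variances).

    Uses the Welch statistic with Welch-Satterthwaite degrees of freedom;
    ``alternative`` is ``"a_greater"`` or ``"a_less"``.
    """
    if alternative not in ("a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            logger.warning("both groups constant and equal; p set to 0.5")
            return TestResult(
                "welch_t", 0.0, 0.5, alternative, a.size, b.size
            )
        raise ValueError("zero variance in both groups with unequal means")
    se = math.sqrt(va / a.size + vb / b.size)
    t_stat = (a.mean() - b.mean()) / se
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = t_dist.sf(t_stat, df) if alternative == "a_greater" else t_dist.cdf(t_stat, df)
    return TestResult(
        "welch_t",
        float(t_stat),
        float(p),
        alternative,
        a.size,
        b.size,
        extra={"df": float(df)},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)


def mann_whitney_one_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "a_greater",
    method: str = "auto",
) -> TestResult:
    """One-tailed Mann-Whitney U test with midrank ties.

    With ``method="auto"``: exact p by enumeration of all label
    assignments when ``n_a + n_b <= 12`` and there are no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    ``method`` may force either path (``"exact"`` requires tie-free data).
    """
    if alternative not in ("a_greater", "a_less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = _mann_whitney_u(a, b)
    u = u_a if alternative == "a_greater" else a.size * b.size - u_a

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n, m = a.size, b.size
    use_exact = (
        method == "exact" if method != "auto" else (n + m <= 12 and not has_ties)
    )
    if use_exact and has_ties:
        raise ValueError("exact method requires tie-free data")
    if use_exact:
        # exact: U for group a under every choice of its positions
        ranks = rankdata(pooled)
        count = 0
        total = 0
        for positions in combinations(range(n + m), n):
            u_perm = sum(ranks[list(positions)]) - n * (n + 1) / 2
            if alternative == "a_less":
                u_perm = n * m - u_perm
            if u_perm >= u:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        mu = n * m / 2.0
        counts = np.unique(pooled, return_counts=True)[1]
        tie_term = (counts**3 - counts).sum()
        total_n = n + m
        sigma2 = n * m / 12.0 * (total_n + 1 - tie_term / (total_n * (total_n - 1)))
        if sigma2 <= 0:
            logger.warning("all pooled values tied; p set to 0.5")
            return TestResult(
                "mann_whitney_u", u_a, 0.5, alternative, n, m, extra={"method": 0.0}
            )
        z = (u - mu - 0.5) / math.sqrt(sigma2)
        p = float(norm.sf(z))
        method = "normal"
    return TestResult(
        "mann_whitney_u",
        u_a,
        float(p),
        alternative,
        n,
        m,
        extra={"method": 1.0 if method == "exact" else 0.0},
    )


# ---------------------------------------------------------------------------
# Interaction network and permutation test


class InteractionNetwork:
    """Undirected gene interaction network (no self-loops)."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> None:
        self.nodes: set[str] = set(nodes)
        self.edges: set[frozenset[str]] = set()
        self.adjacency: dict[str, set[str]] = {node: set() for node in self.nodes}
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: ({u!r}, {v!r})")
            self.edges.add(frozenset((u, v)))
            self.adjacency[u].add(v)
            self.adjacency[v].add(u)

    @classmethod
    def from_tsv(
        cls, path: str | Path, score_threshold: float | None = None
    ) -> "InteractionNetwork":
        """Two gene-id columns per edge; an optional third score column is
        ignored unless ``score_threshold`` is given."""
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
        cols = list(frame.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: edge list needs two columns")
        if score_threshold is not None and len(cols) >= 3:
            frame = frame[frame[cols[2]].astype(float) >= score_threshold]
        edges = list(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str)))
        nodes = {g for edge in edges for g in edge}
        return cls(nodes, edges)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(tuple(sorted(e)) for e in self.edges)
        pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def connection_count(
    network: InteractionNetwork, sampled: Iterable[str], known_drivers: Iterable[str]
) -> int:
    """Number of sampled genes with at least one edge to a known driver.

    Adjacency, not membership: a sampled gene that is itself a driver but
    has no driver neighbour contributes 0.
    """
    drivers = set(known_drivers)
    count = 0
    for gene in sampled:
        if gene not in network.nodes:
            raise ValueError(f"sampled gene {gene!r} absent from network")
        if network.adjacency[gene] & drivers:
            count += 1
    return count


def network_permutation_test(
    network: InteractionNetwork,
    candidates: Iterable[str],
    known_drivers: Iterable[str],
    config: PermutationConfig | None = None,
) -> TestResult:
    """Permutation test for candidate-driver connectivity.

    The observed statistic is the number of candidate genes adjacent to a
    known driver.  The null resamples ``sample_size`` nodes uniformly
    without replacement ``n_permutations`` times.  ``p_value`` is the
    empirical permutation p-value ``(1 + #{null >= observed}) /
    (1 + n_permutations)``; ``extra["t_test_p"]`` additionally reports the
    one-sample t-style p of the null draws against the observed value.
    """
    config = config or PermutationConfig()
    candidates = sorted(set(candidates))
    drivers = set(known_drivers)
    sample_size = config.sample_size or len(candidates)
    node_list = sorted(network.nodes)
    if sample_size > len(node_list):
        raise ValueError(
            f"sample_size {sample_size} exceeds network size {len(node_list)}"
        )
    observed = connection_count(network, candidates, drivers)

    driver_adjacent = np.array(
        [bool(network.adjacency[node] & drivers) for node in node_list]
    )
    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_permutations, dtype=np.int64)
    # argpartition over random keys = uniform sample without replacement per row
    block = 2000
    pos = 0
    while pos < config.n_permutations:
        size = min(block, config.n_permutations - pos)
        keys = rng.random((size, len(node_list)))
        idx = np.argpartition(keys, sample_size - 1, axis=1)[:, :sample_size]
        null[pos : pos + size] = driver_adjacent[idx].sum(axis=1)
        pos += size
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if config.n_permutations > 1 else 0.0
    empirical_p = float((1 + int((null >= observed).sum())) / (1 + config.n_permutations))
    if null_sd > 0:
        t_stat = (observed - null_mean) / (null_sd / math.sqrt(config.n_permutations))
        t_p = float(t_dist.sf(t_stat, config.n_permutations - 1))
    else:
        t_stat = math.inf if observed > null_mean else 0.0
        t_p = 0.0 if observed > null_mean else 1.0
    return TestResult(
        "network_permutation",
        float(observed),
        empirical_p,
        "candidates_more_connected",
        len(candidates),
        config.n_permutations,
        null_summary={"mean": null_mean, "sd": null_sd},
        extra={"t_test_p": t_p, "t_statistic": float(t_stat)},
    )


# ---------------------------------------------------------------------------
# Variant filters and pathogenicity enrichment


def filter_coding_variants(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep variants inside coding regions; a missing flag counts as
    non-coding (logged)."""
    missing = sum(1 for v in variants if v.coding_flag is None)
    if missing:
        logger.info("filter_coding_variants: %d record(s) without a coding flag dropped", missing)
    return [v for v in variants if v.coding_flag is True]


def filter_rare_variants(
    variants: Sequence[VariantRecord], af_threshold: float = 0.01
) -> list[VariantRecord]:
    """Keep rare variants: population allele frequency below the threshold
    or absent (novel variants count as rare)."""
    if not 0.0 < af_threshold < 1.0:
        raise ValueError("af_threshold must lie in (0, 1)")
    return [
        v
        for v in variants
        if v.allele_frequency is None or v.allele_frequency < af_threshold
    ]


def pathogenicity_enrichment(
    variants: Sequence[VariantRecord],
    candidate_genes: Iterable[str],
    comparison_genes: Iterable[str],
    orientations: Mapping[str, str] | None = None,
) -> dict[str, TestResult]:
    """Per-tool Mann-Whitney test that candidate-gene variants are scored
    more deleterious than comparison-gene variants.

    ``orientations`` maps each tool to ``"higher_worse"`` or
    ``"lower_worse"``; the one-tailed alternative follows the orientation
    (``lower_worse`` tools test ``a_less`` on raw scores).  Variants are
    expected to be pre-filtered to coding (and typically rare) records.
    """
    orientations = dict(DEFAULT_TOOL_ORIENTATIONS if orientations is None else orientations)
    cand = set(candidate_genes)
    comp = set(comparison_genes)
    if cand & comp:
        raise ValueError("candidate and comparison gene sets must be disjoint")

    tools = sorted({tool for v in variants for tool in v.scores})
    results: dict[str, TestResult] = {}
    for tool in tools:
        a = [v.scores[tool] for v in variants if v.gene_id in cand and tool in v.scores]
        b = [v.scores[tool] for v in variants if v.gene_id in comp and tool in v.scores]
        if len(a) < 2 or len(b) < 2:
            logger.warning(
                "tool %s skipped: %d candidate / %d comparison scored variants",
                tool,
                len(a),
                len(b),
            )
            continue
        orientation = orientations.get(tool, "higher_worse")
        alternative = "a_less" if orientation == "lower_worse" else "a_greater"
        result = mann_whitney_one_tailed(a, b, alternative)
        result.test_name = f"pathogenicity_enrichment[{tool}]"
        result.direction = f"candidates_more_pathogenic ({orientation})"
        results[tool] = result
    return results


def read_variants_tsv(
    path: str | Path,
    gene_column: str = "gene_id",
    variant_column: str = "variant_id",
    coding_column: str = "coding",
    af_column: str = "allele_frequency",
    score_columns: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read an annotated multi-column variant TSV.

    ``score_columns`` maps tool name -> column name; by default every
    known tool name present as a column is used.  Empty cells denote
    missing values.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    if score_columns is None:
        score_columns = {t: t for t in DEFAULT_TOOL_ORIENTATIONS if t in frame.columns}
    records: list[VariantRecord] = []
    for _, row in frame.iterrows():
        coding: bool | None = None
        if coding_column in frame.columns and not pd.isna(row[coding_column]):
            value = row[coding_column]
            coding = bool(value) if isinstance(value, (bool, np.bool_)) else str(value).strip().lower() in (
                "1",
                "true",
                "yes",
                "exonic",
                "coding",
            )
        af = None
        if af_column in frame.columns and not pd.isna(row[af_column]):
            af = float(row[af_column])
        scores = {
            tool: float(row[col])
            for tool, col in score_columns.items()
            if col in frame.columns and not pd.isna(row[col])
        }
        records.append(
            VariantRecord(
                gene_id=str(row[gene_column]),
                variant_id=str(row[variant_column]) if variant_column in frame.columns else "",
                coding_flag=coding,
                allele_frequency=af,
                scores=scores,
            )
        )
    return records


def read_variants_vcf(
    path: str | Path,
    gene_key: str = "GENE",
    coding_key: str = "CODING",
    af_key: str = "AF_POP",
    score_keys: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read variants from a VCF 4.x file.

    Per-record fields come from INFO: ``gene_key`` names the gene symbol
    key, ``coding_key`` a flag/coding-region key, ``af_key`` the
    population allele frequency, and ``score_keys`` maps tool name ->
    INFO key (default: every known tool name used as its own key).
    Records without the gene key are skipped with a log message.
    """
    from cyvcf2 import VCF

    if score_keys is None:
        score_keys = {tool: tool for tool in DEFAULT_TOOL_ORIENTATIONS}
    records: list[VariantRecord] = []
    skipped = 0
    for variant in VCF(str(path)):
        gene = variant.INFO.get(gene_key)
        if gene is None:
            skipped += 1
            continue
        coding_raw = variant.INFO.get(coding_key)
        if coding_raw is None:
            coding: bool | None = None
        elif isinstance(coding_raw, (bool, int)):
            coding = bool(coding_raw)
        else:
            coding = str(coding_raw).strip().lower() in (
                "1",
                "true",
                "yes",
                "exonic",
                "coding",
            )
        af_raw = variant.INFO.get(af_key)
        af = float(af_raw) if af_raw is not None else None
        scores = {}
        for tool, key in score_keys.items():
            value = variant.INFO.get(key)
            if value is not None:
                scores[tool] = float(value)
        variant_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        records.append(
            VariantRecord(
                gene_id=str(gene),
                variant_id=str(variant_id),
                coding_flag=coding,
                allele_frequency=af,
                scores=scores,
            )
        )
    if skipped:
        logger.info("read_variants_vcf: %d record(s) without %s skipped", skipped, gene_key)
    return records
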