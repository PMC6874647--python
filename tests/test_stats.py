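"""Validation statistics: Welch t, Mann-Whitney U, network permutation
test, variant filters and pathogenicity enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ontodriver.stats import (
    InteractionNetwork,
    PermutationConfig,
    VariantRecord,
    connection_count,
    filter_coding_variants,
    filter_rare_variants,
    mann_whitney_one_tailed,
    mutation_frequency,
    network_permutation_test,
    pathogenicity_enrichment,
    read_mutation_table,
    read_variants_tsv,
    welch_t_test_one_tailed,
)
from ontodriver.simulate import write_variants_tsv


class TestMutationFrequency:
    def test_count_over_length(self):
        records = mutation_frequency({"A": 30}, {"A": 1500})
        assert records[0].frequency == pytest.approx(0.02)

    def test_zero_count(self):
        assert mutation_frequency({"A": 0}, {"A": 100})[0].frequency == 0.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="A"):
            mutation_frequency({"A": 1}, {"A": 0})
        with pytest.raises(ValueError, match="B"):
            mutation_frequency({"B": 1}, {})

    def test_table_reader(self, tmp_path):
        path = tmp_path / "mut.tsv"
        path.write_text("gene_id\tmutation_count\tgene_length\nA\t10\t1000\n")
        records = read_mutation_table(path)
        assert records[0].frequency == pytest.approx(0.01)


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(0.5)

    def test_worked_example(self):
        r = welch_t_test_one_tailed([3, 4, 5], [1, 2, 3], "a_greater")
        assert r.statistic == pytest.approx(2.449, abs=1e-3)
        assert r.extra["df"] == pytest.approx(4.0)
        assert r.p_value == pytest.approx(0.0353, abs=2e-4)

    def test_one_tailed_complementarity(self):
        a, b = [3.0, 4.1, 5.0], [1.0, 2.2, 3.0]
        p_gt = welch_t_test_one_tailed(a, b, "a_greater").p_value
        p_lt = welch_t_test_one_tailed(a, b, "a_less").p_value
        assert p_gt + p_lt == pytest.approx(1.0)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test_one_tailed([1.0], [1.0, 2.0])

    def test_matches_scipy_reference(self):
        """Statistic and one-tailed p agree with scipy's Welch test to 1e-9
        on 100 random inputs."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(0, 1, rng.integers(3, 30))
            ours = welch_t_test_one_tailed(a, b, "a_greater")
            ref = sps.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestMannWhitney:
    def test_exact_worked_example(self):
        r = mann_whitney_one_tailed([4, 5, 6], [1, 2, 3], "a_greater")
        assert r.statistic == 9.0
        assert r.p_value == pytest.approx(1 / 20)

    def test_tied_identical_groups(self):
        r = mann_whitney_one_tailed([1, 2, 3], [1, 2, 3], "a_greater")
        assert r.statistic == pytest.approx(4.5)  # n*m/2 with ties
        assert r.p_value >= 0.5
        assert mann_whitney_one_tailed([1, 2, 3], [1, 2, 3], "a_less").p_value >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def test_exact_matches_enumeration_all_small_sizes(self):
        """Exact path equals full enumeration over label assignments for
        every n_a, n_b <= 6 (tie-free input)."""
        rng = np.random.default_rng(5)
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = pooled[:n_a], pooled[n_a:]
                r = mann_whitney_one_tailed(a, b, "a_greater")
                ranks = sps.rankdata(np.concatenate([a, b]))
                u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
                hits = sum(
                    sum(ranks[list(pos)]) - n_a * (n_a + 1) / 2 >= u_obs
                    for pos in itertools.combinations(range(n_a + n_b), n_a)
                )
                expected = hits / len(
                    list(itertools.combinations(range(n_a + n_b), n_a))
                )
                assert r.p_value == pytest.approx(expected)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.permutation(np.arange(12.0))[:5]
            b = np.setdiff1d(np.arange(12.0), a)[:6]
            ours = mann_whitney_one_tailed(a, b, "a_greater")
            ref = sps.mannwhitneyu(a, b, alternative="greater", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_normal_paths_agree(self):
        """Normal approximation within 0.01 of the exact p for tie-free
        inputs with n_a = n_b = 6."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            pooled = rng.normal(size=12)
            a, b = pooled[:6], pooled[6:]
            exact = mann_whitney_one_tailed(a, b, "a_greater", method="exact")
            approx = mann_whitney_one_tailed(a, b, "a_greater", method="normal")
            assert approx.p_value == pytest.approx(exact.p_value, abs=0.01)


class TestNetwork:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            InteractionNetwork({"a"}, [("a", "a")])

    def test_connection_count_examples(self):
        net = InteractionNetwork(
            {"d1", "a", "b", "c", "d"}, [("d1", "a"), ("d1", "b")]
        )
        assert connection_count(net, {"a", "b"}, {"d1"}) == 2
        assert connection_count(net, {"c", "d"}, {"d1"}) == 0

    def test_isolated_driver_contributes_zero(self):
        net = InteractionNetwork({"d1", "d2", "a"}, [("d1", "a")])
        # d2 is a driver but isolated: adjacency, not membership
        assert connection_count(net, {"d2"}, {"d1", "d2"}) == 0

    def test_sampled_gene_outside_network_rejected(self):
        net = InteractionNetwork({"a"}, [])
        with pytest.raises(ValueError):
            connection_count(net, {"zz"}, set())

    def test_edge_tsv_round_trip(self, tmp_path):
        net = InteractionNetwork({"a", "b", "c"}, [("a", "b"), ("b", "c")])
        path = tmp_path / "net.tsv"
        net.to_tsv(path)
        loaded = InteractionNetwork.from_tsv(path)
        assert loaded.edges == net.edges


class TestNetworkPermutationTest:
    def test_toy_graph_null_mean_matches_enumeration(self):
        """Nodes {a,b,c,d}, edges d1-a and d1-b, sample size 2: exact null
        mean over all C(5,2)=10 pairs, empirical within 3 SE."""
        net = InteractionNetwork(
            {"d1", "a", "b", "c", "d"}, [("d1", "a"), ("d1", "b")]
        )
        exact = np.mean(
            [
                connection_count(net, pair, {"d1"})
                for pair in itertools.combinations(sorted(net.nodes), 2)
            ]
        )
        r = network_permutation_test(
            net, {"a", "b"}, {"d1"}, PermutationConfig(10_000, sample_size=2, seed=0)
        )
        se = r.null_summary["sd"] / np.sqrt(10_000)
        assert abs(r.null_summary["mean"] - exact) <= 3 * se

    def test_no_driver_adjacent_nodes(self):
        net = InteractionNetwork({"a", "b", "c"}, [("a", "b")])
        r = network_permutation_test(
            net, {"c"}, set(), PermutationConfig(500, seed=1)
        )
        assert r.statistic == 0
        assert r.null_summary["mean"] == 0
        assert r.p_value == 1.0

    def test_observed_above_all_null_gives_minimum_p(self):
        # star: d1 connected to a,b; candidates {a,b}, sample_size 1
        net = InteractionNetwork({"d1", "a", "b"}, [("d1", "a"), ("d1", "b")])
        r = network_permutation_test(
            net, {"a", "b"}, {"d1"}, PermutationConfig(1000, sample_size=1, seed=2)
        )
        # observed 2 can never be reached by single-node samples
        assert r.p_value == pytest.approx(1 / 1001)

    def test_sample_size_larger_than_network_rejected(self):
        net = InteractionNetwork({"a", "b"}, [])
        with pytest.raises(ValueError):
            network_permutation_test(
                net, {"a"}, set(), PermutationConfig(10, sample_size=5)
            )

    def test_null_mean_matches_enumeration_on_random_graphs(self):
        """Empirical null mean within 3 SE of the exhaustive mean on random
        graphs with <= 8 nodes and sample sizes <= 3."""
        rng = np.random.default_rng(31)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            net = InteractionNetwork(nodes, edges)
            drivers = set(rng.choice(nodes, 2, replace=False))
            size = int(rng.integers(1, 4))
            exact = np.mean(
                [
                    connection_count(net, combo, drivers)
                    for combo in itertools.combinations(nodes, size)
                ]
            )
            r = network_permutation_test(
                net,
                set(nodes[:size]),
                drivers,
                PermutationConfig(10_000, sample_size=size, seed=trial),
            )
            se = max(r.null_summary["sd"], 1e-9) / np.sqrt(10_000)
            assert abs(r.null_summary["mean"] - exact) <= 3 * se + 1e-12


class TestVariantFilters:
    def _variant(self, **kw):
        base = dict(gene_id="g", variant_id="v", coding_flag=True, allele_frequency=None)
        base.update(kw)
        return VariantRecord(**base)

    def test_coding_filter(self):
        kept = filter_coding_variants(
            [
                self._variant(variant_id="exonic", coding_flag=True),
                self._variant(variant_id="intronic", coding_flag=False),
                self._variant(variant_id="unknown", coding_flag=None),
            ]
        )
        assert [v.variant_id for v in kept] == ["exonic"]

    def test_rare_filter(self):
        kept = filter_rare_variants(
            [
                self._variant(variant_id="rare", allele_frequency=0.005),
                self._variant(variant_id="common", allele_frequency=0.05),
                self._variant(variant_id="novel", allele_frequency=None),
            ]
        )
        assert [v.variant_id for v in kept] == ["rare", "novel"]

    def test_rare_threshold_validated(self):
        with pytest.raises(ValueError):
            filter_rare_variants([], af_threshold=0.0)


class TestPathogenicityEnrichment:
    def test_lower_worse_direction(self):
        variants = [
            VariantRecord("cand", f"v{i}", True, None, {"SIFT": s})
            for i, s in enumerate([0.01, 0.02, 0.015])
        ] + [
            VariantRecord("other", f"w{i}", True, None, {"SIFT": s})
            for i, s in enumerate([0.8, 0.9, 0.85])
        ]
        results = pathogenicity_enrichment(variants, {"cand"}, {"other"})
        assert results["SIFT"].p_value == pytest.approx(1 / 20)

    def test_absent_tool_absent_from_output(self):
        variants = [
            VariantRecord("cand", "v1", True, None, {"CADD": 1.0}),
            VariantRecord("cand", "v2", True, None, {"CADD": 2.0}),
            VariantRecord("other", "w1", True, None, {"CADD": 0.5}),
            VariantRecord("other", "w2", True, None, {"CADD": 0.1}),
        ]
        results = pathogenicity_enrichment(variants, {"cand"}, {"other"})
        assert set(results) == {"CADD"}

    def test_undersized_tool_skipped(self):
        variants = [
            VariantRecord("cand", "v1", True, None, {"CADD": 1.0}),
            VariantRecord("other", "w1", True, None, {"CADD": 0.5}),
            VariantRecord("other", "w2", True, None, {"CADD": 0.1}),
        ]
        assert pathogenicity_enrichment(variants, {"cand"}, {"other"}) == {}

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            pathogenicity_enrichment([], {"a"}, {"a"})

    def test_planted_shift_detected(self):
        """Shift of 2 SD in 200 variants/group yields p < 0.001."""
        rng = np.random.default_rng(8)
        variants = [
            VariantRecord("cand", f"v{i}", True, None, {"CADD": float(rng.normal(2, 1))})
            for i in range(200)
        ] + [
            VariantRecord("other", f"w{i}", True, None, {"CADD": float(rng.normal(0, 1))})
            for i in range(200)
        ]
        results = pathogenicity_enrichment(variants, {"cand"}, {"other"})
        assert results["CADD"].p_value < 1e-3


def test_variant_tsv_round_trip(tmp_path):
    records = [
        VariantRecord("g1", "v1", True, 0.004, {"SIFT": 0.01, "CADD": 3.2}),
        VariantRecord("g2", "v2", False, None, {"CADD": -1.0}),
    ]
    path = tmp_path / "variants.tsv"
    write_variants_tsv(records, path)
    loaded = read_variants_tsv(path)
    assert [v.gene_id for v in loaded] == ["g1", "g2"]
    assert loaded[0].coding_flag is True
    assert loaded[1].coding_flag is False
    assert loaded[0].allele_frequency == pytest.approx(0.004)
    assert loaded[1].allele_frequency is None
    assert loaded[0].scores["SIFT"] == pytest.approx(0.01)
    assert "SIFT" not in loaded[1].scores


def test_variant_vcf_reader(tmp_path):
    """Scores, AF, gene and coding flag parsed from INFO keys of a VCF."""
    from ontodriver.stats import read_variants_vcf

    vcf = tmp_path / "variants.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
        '##INFO=<ID=CODING,Number=1,Type=String,Description="coding">\n'
        '##INFO=<ID=AF_POP,Number=1,Type=Float,Description="pop AF">\n'
        '##INFO=<ID=SIFT,Number=1,Type=Float,Description="score">\n'
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="score">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\trs1\tA\tT\t.\t.\tGENE=G00001;CODING=exonic;AF_POP=0.004;SIFT=0.01;CADD=3.5\n"
        "1\t200\t.\tG\tC\t.\t.\tGENE=G00002;CODING=intronic;CADD=-0.5\n"
        "1\t300\trs3\tC\tA\t.\t.\tAF_POP=0.2\n"
    )
    records = read_variants_vcf(vcf)
    assert len(records) == 2  # record without GENE skipped
    first, second = records
    assert first.gene_id == "G00001" and first.variant_id == "rs1"
    assert first.coding_flag is True and second.coding_flag is False
    assert first.allele_frequency == pytest.approx(0.004)
    assert second.allele_frequency is None
    assert first.scores == {"SIFT": pytest.approx(0.01), "CADD": pytest.approx(3.5)}
    assert second.scores == {"CADD": pytest.approx(-0.5)}
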