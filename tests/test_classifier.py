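"""Classifier metrics, training-set assembly, and cross-validation."""

import numpy as np
import pytest

from ontodriver.classifier import (
    DriverGeneClassifier,
    LabelMatrix,
    ModelConfig,
    assemble_training_set,
    cross_validate,
    f_score,
    predict_candidates,
    roc_auc,
    train_models,
)
from ontodriver.embedding import GeneFeatureMatrix

FAST = ModelConfig(hidden_layers=(16,), epochs=40, batch_size=8)


def _features(n_genes, p=6, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return GeneFeatureMatrix(genes, rng.normal(size=(n_genes, p)), "test")


def _labels(features, positive_by_type):
    genes = features.gene_ids
    types = sorted(positive_by_type)
    indicator = np.zeros((len(genes), len(types)), dtype=bool)
    for j, t in enumerate(types):
        for g in positive_by_type[t]:
            indicator[genes.index(g), j] = True
    return LabelMatrix(list(genes), types, indicator)


class TestFScore:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(5, 0, 0, 1.0), (0, 3, 2, 0.0), (2, 1, 1, 2 / 3), (0, 0, 0, 0.0)],
    )
    def test_confusion_count_examples(self, tp, fp, fn, expected):
        assert f_score(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f_score(-1, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_partial_ranking(self):
        # positives 0.9, 0.4; negatives 0.6, 0.2: 3 of 4 pairs won
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [True, True, False, False]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_matches_pair_counting_oracle(self):
        """AUC equals exhaustive P(s+ > s-) + 0.5 P(s+ = s-) over pairs."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestAssembleTrainingSet:
    def test_balanced_and_reproducible(self):
        features = _features(40)
        labels = _labels(
            features, {"t1": [f"g{i:03d}" for i in range(10)], "t2": ["g015"]}
        )
        ts = assemble_training_set(features, labels, "t1", seed=3)
        assert len(ts.negatives) == len(ts.positives) == 10
        ts2 = assemble_training_set(features, labels, "t1", seed=3)
        assert ts.negatives == ts2.negatives

    def test_other_type_drivers_never_negatives(self):
        features = _features(40)
        labels = _labels(
            features, {"t1": [f"g{i:03d}" for i in range(10)], "t2": ["g015"]}
        )
        for seed in range(10):
            ts = assemble_training_set(features, labels, "t1", seed=seed)
            assert "g015" not in ts.negatives

    def test_errors(self):
        features = _features(12)
        labels = _labels(features, {"t1": [f"g{i:03d}" for i in range(8)]})
        with pytest.raises(ValueError, match="unknown cancer type"):
            assemble_training_set(features, labels, "zzz", seed=0)
        # only 4 non-drivers for 8 positives
        with pytest.raises(ValueError, match="non-driver"):
            assemble_training_set(features, labels, "t1", seed=0)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    genes = [f"g{i:03d}" for i in range(120)]
    X = rng.normal(size=(120, 6))
    positives = genes[:30]
    X[:30] += 2.0  # mean-shifted positive class
    features = GeneFeatureMatrix(list(genes), X, "test")
    labels = _labels(features, {"t1": positives})
    return features, labels


class TestCrossValidate:
    def test_each_gene_tested_exactly_once(self, separable):
        features, labels = separable
        report = cross_validate(features, labels, FAST, k=5, seed=0)
        folds = report.per_type()[0].fold_metrics
        assert len(folds) == 5

    def test_folds_stratified(self):
        # fold positive counts differ by <= 1 by construction of the splitter
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 23 + [0] * 23)
        X = np.zeros((46, 1))
        counts = [
            int(y[test].sum())
            for _, test in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y)
        ]
        assert max(counts) - min(counts) <= 1

    def test_separable_data_high_auc(self, separable):
        features, labels = separable
        report = cross_validate(features, labels, FAST, k=5, seed=0)
        assert report.overall.auc > 0.9
        assert 0 <= report.overall.f_score <= 1

    def test_insufficient_positives_named_in_error(self, separable):
        features, labels = separable
        with pytest.raises(ValueError, match="t1"):
            cross_validate(features, labels, FAST, k=40, seed=0)

    def test_summary_lists_all_types_and_overall(self, separable):
        features, labels = separable
        report = cross_validate(features, labels, FAST, k=5, seed=0)
        assert list(report.summary().index) == ["t1", "overall"]


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(9)
    genes = [f"g{i:03d}" for i in range(100)]
    X = rng.normal(size=(100, 5))
    X[:25] += 2.5
    features = GeneFeatureMatrix(list(genes), X, "test")
    # only genes 0..14 labelled; 15..24 share the driver signature
    labels = _labels(features, {"t1": genes[:15]})
    models = train_models(features, labels, FAST, seed=0)
    return models, features, labels


class TestPredictCandidates:
    def test_known_drivers_excluded(self, fitted):
        models, features, labels = fitted
        candidates = predict_candidates(models, features, labels, threshold=0.5)
        names = [g for g, _ in candidates["t1"]]
        assert not set(names) & set(labels.positives("t1"))

    def test_signature_genes_recovered_and_sorted(self, fitted):
        models, features, labels = fitted
        candidates = predict_candidates(models, features, labels, threshold=0.5)
        names = [g for g, _ in candidates["t1"]]
        assert set(features.gene_ids[15:25]) & set(names)
        scores = [s for _, s in candidates["t1"]]
        assert scores == sorted(scores, reverse=True)

    def test_high_threshold_empties_list(self, fitted):
        models, features, labels = fitted
        candidates = predict_candidates(models, features, labels, threshold=1.1)
        assert candidates["t1"] == []

    def test_feature_width_mismatch_rejected(self, fitted):
        models, features, labels = fitted
        narrow = GeneFeatureMatrix(features.gene_ids, features.matrix[:, :3], "test")
        with pytest.raises(ValueError, match="features"):
            predict_candidates(models, narrow, labels)


class TestLabelMatrix:
    def test_tsv_round_trip(self, tmp_path):
        features = _features(6)
        labels = _labels(features, {"t1": ["g000", "g001"], "t2": ["g001"]})
        path = tmp_path / "labels.tsv"
        labels.to_tsv(path)
        loaded = LabelMatrix.from_tsv(path, features.gene_ids)
        np.testing.assert_array_equal(loaded.indicator, labels.indicator)

    def test_non_drivers_are_all_false_rows(self):
        features = _features(5)
        labels = _labels(features, {"t1": ["g000"], "t2": ["g001"]})
        assert labels.non_drivers() == ["g002", "g003", "g004"]


def test_label_shuffle_null_auc(union_features, default_dataset):
    """With driver labels randomly permuted, pooled CV AUC sits near 0.5."""
    _, _, labels = default_dataset
    for rep in range(3):
        rng = np.random.default_rng(100 + rep)
        perm = rng.permutation(len(labels.gene_ids))
        shuffled = LabelMatrix(
            labels.gene_ids, labels.cancer_types, labels.indicator[perm]
        )
        report = DriverGeneClassifier(union_features, shuffled, FAST).cross_validate(
            k=10, seed=rep
        )
        assert 0.4 <= report.overall.auc <= 0.6


def test_model_checkpoint_round_trip(tmp_path, fitted):
    """JSON checkpoints reproduce scores exactly after reload."""
    from ontodriver.classifier import load_models, save_models

    models, features, _ = fitted
    path = tmp_path / "models.json"
    save_models(models, path)
    loaded = load_models(path)
    for cancer_type in models:
        np.testing.assert_allclose(
            loaded[cancer_type].predict_proba(features.matrix),
            models[cancer_type].predict_proba(features.matrix),
        )
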