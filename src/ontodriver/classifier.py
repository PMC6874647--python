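"""Per-cancer-type driver-gene classification.

One binary feedforward network is trained per cancer type on a balanced
set: the type's known driver genes as positives and an equal-sized random
sample of non-driver genes (genes that are a driver for *no* type) as
negatives.  Evaluation is stratified k-fold cross-validation; per-type
metrics are pooled over the concatenated held-out scores, and an "overall"
result micro-averages pooled predictions across types (a per-type macro
mean is reported alongside).

The module follows the model/results convention: build a
:class:`DriverGeneClassifier` from a feature matrix and a label matrix,
call :meth:`~DriverGeneClassifier.cross_validate` or
:meth:`~DriverGeneClassifier.fit`, and read metrics off the returned
:class:`CVReport` (``summary()`` prints the per-type table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .embedding import GeneFeatureMatrix
from .nn import FeedforwardNet

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMatrix",
    "TrainingSet",
    "ModelConfig",
    "CVResult",
    "CVReport",
    "DriverGeneClassifier",
    "assemble_training_set",
    "cross_validate",
    "train_models",
    "predict_candidates",
    "save_models",
    "load_models",
    "f_score",
    "roc_auc",
]


@dataclass
class LabelMatrix:
    """Gene x cancer-type driver indicator.

    A gene may be a driver for several types; a gene whose row is all
    false is a non-driver.
    """

    gene_ids: list[str]
    cancer_types: list[str]
    indicator: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.shape != (len(self.gene_ids), len(self.cancer_types)):
            raise ValueError("indicator shape must be |genes| x |types|")
        self._row = {g: i for i, g in enumerate(self.gene_ids)}

    def is_positive(self, gene_id: str, cancer_type: str) -> bool:
        if gene_id not in self._row:
            return False
        return bool(self.indicator[self._row[gene_id], self.cancer_types.index(cancer_type)])

    def positives(self, cancer_type: str) -> list[str]:
        col = self.cancer_types.index(cancer_type)
        return [g for g, i in zip(self.gene_ids, range(len(self.gene_ids))) if self.indicator[i, col]]

    def non_drivers(self) -> list[str]:
        """Genes that are positive for no cancer type."""
        mask = ~self.indicator.any(axis=1)
        return [g for g, keep in zip(self.gene_ids, mask) if keep]

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, t)
            for i, g in enumerate(self.gene_ids)
            for j, t in enumerate(self.cancer_types)
            if self.indicator[i, j]
        ]
        pd.DataFrame(rows, columns=["gene_id", "cancer_type"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, universe: Sequence[str], cancer_types: Sequence[str] | None = None
    ) -> "LabelMatrix":
        """Read one (gene_id, cancer_type) row per positive pair; the gene
        universe (rows) is supplied by the caller, typically the feature
        matrix."""
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if missing := {"gene_id", "cancer_type"} - set(frame.columns):
            raise ValueError(f"{path}: missing label columns: {sorted(missing)}")
        types = (
            list(cancer_types)
            if cancer_types is not None
            else sorted(frame["cancer_type"].unique())
        )
        universe = list(universe)
        indicator = np.zeros((len(universe), len(types)), dtype=bool)
        row = {g: i for i, g in enumerate(universe)}
        for record in frame.itertuples(index=False):
            if record.gene_id in row and record.cancer_type in types:
                indicator[row[record.gene_id], types.index(record.cancer_type)] = True
        return cls(universe, types, indicator)


@dataclass
class TrainingSet:
    cancer_type: str
    positives: list[str]
    negatives: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("training set must be balanced")


@dataclass(frozen=True)
class ModelConfig:
    """Feedforward-net configuration: ReLU hidden layers, one sigmoid
    output unit, cross-entropy loss, RMSprop optimizer."""

    hidden_layers: tuple[int, ...] = (128, 64)
    epochs: int = 150
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0


# ---------------------------------------------------------------------------
# Metrics


def f_score(tp: int, fp: int, fn: int) -> float:
    """F1 from confusion counts; 0 when there are no true positives."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0:
        if fp == 0 and fn == 0:
            logger.warning("f_score called with tp=fp=fn=0; returning 0 by convention")
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve as the pairwise ranking probability
    P(score+ > score-) + 0.5 * P(score+ = score-), via midranks."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class CVResult:
    """Cross-validation metrics for one cancer type (or "overall")."""

    cancer_type: str
    fold_metrics: list[dict] = field(default_factory=list)
    f_score: float = float("nan")
    auc: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    macro_f_score: float | None = None
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVReport:
    """Per-type :class:`CVResult` list plus the pooled "overall" result."""

    results: list[CVResult]

    @property
    def overall(self) -> CVResult:
        return next(r for r in self.results if r.cancer_type == "overall")

    def per_type(self) -> list[CVResult]:
        return [r for r in self.results if r.cancer_type != "overall"]

    def summary(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "cancer_type": r.cancer_type,
                    "f_score": r.f_score,
                    "auc": r.auc,
                    "n_folds": len(r.fold_metrics),
                }
                for r in self.results
            ]
        )
        return frame.set_index("cancer_type")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([r.to_dict() for r in self.results], indent=2), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# Training-set assembly and cross-validation


def assemble_training_set(
    features: GeneFeatureMatrix, labels: LabelMatrix, cancer_type: str, seed: int
) -> TrainingSet:
    """Balanced positives/negatives for one cancer type.

    Positives are the feature-bearing known drivers of the type; negatives
    are an equal-size uniform sample (without replacement) of
    feature-bearing genes that are drivers for no type.
    """
    if cancer_type not in labels.cancer_types:
        raise ValueError(f"unknown cancer type {cancer_type!r}")
    with_features = set(features.gene_ids)
    positives = sorted(g for g in labels.positives(cancer_type) if g in with_features)
    if not positives:
        raise ValueError(f"no feature-bearing positives for {cancer_type!r}")
    pool = sorted(g for g in labels.non_drivers() if g in with_features)
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} non-driver genes available for {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    negatives = sorted(rng.choice(pool, size=len(positives), replace=False).tolist())
    return TrainingSet(cancer_type, positives, negatives, seed)


@dataclass
class _FittedModel:
    net: FeedforwardNet
    mean: np.ndarray
    std: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba((X - self.mean) / self.std)


def _fit_one(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int
) -> _FittedModel:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    net = FeedforwardNet(
        n_features=X.shape[1],
        hidden_layers=config.hidden_layers,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=seed,
    )
    net.fit((X - mean) / std, y)
    return _FittedModel(net, mean, std)


def _type_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def cross_validate(
    features: GeneFeatureMatrix,
    labels: LabelMatrix,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the per-type classifiers.

    Per type, a balanced set is assembled, split into k stratified folds,
    and the network is trained on k-1 folds and scored on the held-out
    fold; metrics are pooled over held-out scores.  The "overall" entry
    micro-averages pooled predictions across types.
    """
    config = config or ModelConfig()
    shortages = [
        t
        for t in labels.cancer_types
        if sum(g in set(features.gene_ids) for g in labels.positives(t)) < k
    ]
    if shortages:
        raise ValueError(
            f"cancer types with fewer than {k} feature-bearing positives: {shortages}"
        )

    row = {g: i for i, g in enumerate(features.gene_ids)}
    results: list[CVResult] = []
    all_scores: list[np.ndarray] = []
    all_truth: list[np.ndarray] = []
    for t_index, cancer_type in enumerate(labels.cancer_types):
        ts_seed = _type_seed(seed, t_index)
        ts = assemble_training_set(features, labels, cancer_type, ts_seed)
        genes = ts.positives + ts.negatives
        X = features.matrix[[row[g] for g in genes]]
        y = np.array([1.0] * len(ts.positives) + [0.0] * len(ts.negatives))

        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=ts_seed)
        pooled_scores = np.empty(len(genes))
        fold_metrics: list[dict] = []
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            model = _fit_one(X[train_idx], y[train_idx], config, _type_seed(ts_seed, fold))
            scores = model.predict_proba(X[test_idx])
            pooled_scores[test_idx] = scores
            y_test = y[test_idx]
            pred = scores >= 0.5
            tp = int(np.sum(pred & (y_test == 1)))
            fp = int(np.sum(pred & (y_test == 0)))
            fn = int(np.sum(~pred & (y_test == 1)))
            fold_metrics.append(
                {
                    "fold": fold,
                    "precision": tp / (tp + fp) if tp + fp else 0.0,
                    "recall": tp / (tp + fn) if tp + fn else 0.0,
                    "f_score": f_score(tp, fp, fn),
                    "auc": roc_auc(scores, y_test == 1),
                }
            )

        pred = pooled_scores >= 0.5
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        fpr, tpr, _ = roc_curve(y, pooled_scores)
        precision, recall, _ = precision_recall_curve(y, pooled_scores)
        results.append(
            CVResult(
                cancer_type=cancer_type,
                fold_metrics=fold_metrics,
                f_score=f_score(tp, fp, fn),
                auc=roc_auc(pooled_scores, y == 1),
                roc_points=list(zip(fpr.tolist(), tpr.tolist())),
                pr_points=list(zip(recall.tolist(), precision.tolist())),
            )
        )
        all_scores.append(pooled_scores)
        all_truth.append(y)

    scores = np.concatenate(all_scores)
    truth = np.concatenate(all_truth)
    pred = scores >= 0.5
    tp = int(np.sum(pred & (truth == 1)))
    fp = int(np.sum(pred & (truth == 0)))
    fn = int(np.sum(~pred & (truth == 1)))
    fpr, tpr, _ = roc_curve(truth, scores)
    precision, recall, _ = precision_recall_curve(truth, scores)
    results.append(
        CVResult(
            cancer_type="overall",
            fold_metrics=[],
            f_score=f_score(tp, fp, fn),
            auc=roc_auc(scores, truth == 1),
            roc_points=list(zip(fpr.tolist(), tpr.tolist())),
            pr_points=list(zip(recall.tolist(), precision.tolist())),
            macro_f_score=float(np.mean([r.f_score for r in results])),
            macro_auc=float(np.mean([r.auc for r in results])),
        )
    )
    return CVReport(results)


def train_models(
    features: GeneFeatureMatrix,
    labels: LabelMatrix,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict[str, _FittedModel]:
    """Fit one model per cancer type on its full balanced training set."""
    config = config or ModelConfig()
    row = {g: i for i, g in enumerate(features.gene_ids)}
    models: dict[str, _FittedModel] = {}
    for t_index, cancer_type in enumerate(labels.cancer_types):
        ts_seed = _type_seed(seed, t_index)
        ts = assemble_training_set(features, labels, cancer_type, ts_seed)
        genes = ts.positives + ts.negatives
        X = features.matrix[[row[g] for g in genes]]
        y = np.array([1.0] * len(ts.positives) + [0.0] * len(ts.negatives))
        models[cancer_type] = _fit_one(X, y, config, ts_seed)
    return models


def predict_candidates(
    models: Mapping[str, _FittedModel],
    features: GeneFeatureMatrix,
    labels: LabelMatrix,
    threshold: float = 0.5,
) -> dict[str, list[tuple[str, float]]]:
    """Novel candidate drivers per cancer type.

    ``candidates(t)`` = genes scoring >= threshold for type t, minus the
    genes already labelled positive for t, sorted by descending score.
    """
    candidates: dict[str, list[tuple[str, float]]] = {}
    for cancer_type, model in models.items():
        if model.mean.shape[0] != features.p:
            raise ValueError(
                f"model for {cancer_type!r} expects {model.mean.shape[0]} features, "
                f"matrix has {features.p}"
            )
        scores = model.predict_proba(features.matrix)
        hits = [
            (gene, float(score))
            for gene, score in zip(features.gene_ids, scores)
            if score >= threshold and not labels.is_positive(gene, cancer_type)
        ]
        hits.sort(key=lambda pair: (-pair[1], pair[0]))
        candidates[cancer_type] = hits
    return candidates


def save_models(models: Mapping[str, _FittedModel], path: str | Path) -> None:
    """Serialize fitted per-type models as a portable JSON checkpoint
    (layer weights, biases, and feature-standardization statistics)."""
    payload = {}
    for cancer_type, model in models.items():
        payload[cancer_type] = {
            "hidden_layers": list(model.net.hidden_layers),
            "weights": [w.tolist() for w in model.net.weights],
            "biases": [b.tolist() for b in model.net.biases],
            "mean": model.mean.tolist(),
            "std": model.std.tolist(),
        }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_models(path: str | Path) -> dict[str, _FittedModel]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    models: dict[str, _FittedModel] = {}
    for cancer_type, entry in payload.items():
        weights = [np.asarray(w) for w in entry["weights"]]
        biases = [np.asarray(b) for b in entry["biases"]]
        net = FeedforwardNet(
            n_features=weights[0].shape[0],
            hidden_layers=tuple(entry["hidden_layers"]),
        )
        net.weights = weights
        net.biases = biases
        models[cancer_type] = _FittedModel(
            net, np.asarray(entry["mean"]), np.asarray(entry["std"])
        )
    return models


class DriverGeneClassifier:
    """Model object bundling features, labels, and configuration.

    Examples
    --------
    >>> clf = DriverGeneClassifier(features, labels)          # doctest: +SKIP
    >>> report = clf.cross_validate(k=10, seed=0)             # doctest: +SKIP
    >>> report.summary()                                      # doctest: +SKIP
    >>> clf.fit(seed=0).predict_candidates(threshold=0.5)     # doctest: +SKIP
    """

    def __init__(
        self,
        features: GeneFeatureMatrix,
        labels: LabelMatrix,
        config: ModelConfig | None = None,
    ) -> None:
        self.features = features
        self.labels = labels
        self.config = config or ModelConfig()
        self.models_: dict[str, _FittedModel] | None = None

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVReport:
        return cross_validate(self.features, self.labels, self.config, k=k, seed=seed)

    def fit(self, seed: int = 0) -> "DriverGeneClassifier":
        self.models_ = train_models(self.features, self.labels, self.config, seed=seed)
        return self

    def predict_candidates(self, threshold: float = 0.5) -> dict[str, list[tuple[str, float]]]:
        if self.models_ is None:
            raise RuntimeError("call fit() before predict_candidates()")
        return predict_candidates(self.models_, self.features, self.labels, threshold)
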