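"""Classification protocol: metrics, splits, the bagged random forest,
cross-validation and the 2D feature embedding.

Conventions: the positive class (label 1) is caveolae / isotropic blobs,
the negative class (label 0) is non-caveolar. Sensitivity = TP / (TP + FN)
is the true-positive rate for caveolae; specificity = TN / (TN + FP) the
true-negative rate for the non-caveolar class;
accuracy = (TP + TN) / (TP + TN + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, N_FEATURES


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class ClassificationReport:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def metrics_from_counts(counts: ConfusionCounts) -> ClassificationReport:
    """Accuracy / sensitivity / specificity, exact rational arithmetic.

    Raises when a metric is undefined (no positives evaluated -> sensitivity,
    no negatives -> specificity).
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples: all counts zero")
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive samples evaluated (TP + FN = 0)")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no negative samples evaluated (TN + FP = 0)")
    acc = Fraction(counts.tp + counts.tn, counts.total)
    sens = Fraction(counts.tp, counts.tp + counts.fn)
    spec = Fraction(counts.tn, counts.tn + counts.fp)
    return ClassificationReport(counts, float(acc), float(sens), float(spec))


def confusion_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN against the 1 = positive / 0 = negative convention."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def report_from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> ClassificationReport:
    return metrics_from_counts(confusion_from_predictions(y_true, y_pred))


# ---------------------------------------------------------------------------
# Dataset splits
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    mode: str = "mixed"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split id sets must be pairwise disjoint")

    @property
    def m_train(self) -> int:
        return len(self.train_ids)


def make_split_mixed(
    ids: Sequence, labels: Sequence[int], n_test: int = 200, n_val: int = 100, seed: int = 0
) -> DatasetSplit:
    """Class-stratified random split; the remainder after drawing the test and
    validation sets is the training set (1414 / 100 / 200 on the 1714-blob
    balanced dataset at the defaults)."""
    ids = np.asarray(ids, dtype=object)
    labels = np.asarray(labels, dtype=int)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have equal length")
    if n_test + n_val > len(ids):
        raise ValueError(f"requested {n_test}+{n_val} exceeds dataset size {len(ids)}")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        frac = len(cls_idx) / len(ids)
        n_test_c = int(round(n_test * frac))
        n_val_c = int(round(n_val * frac))
        if n_test_c + n_val_c > len(cls_idx):
            raise ValueError(f"class {cls}: not enough samples to draw {n_test_c}+{n_val_c}")
        perm = rng.permutation(cls_idx)
        test_idx.extend(perm[:n_test_c])
        val_idx.extend(perm[n_test_c:n_test_c + n_val_c])
    test_set, val_set = set(test_idx), set(val_idx)
    train_idx = [i for i in range(len(ids)) if i not in test_set and i not in val_set]
    return DatasetSplit(
        train_ids=list(ids[train_idx]),
        val_ids=list(ids[sorted(val_set)]),
        test_ids=list(ids[sorted(test_set)]),
        mode="mixed",
        seed=seed,
    )


def make_split_cellwise(
    ids: Sequence, cell_ids: Sequence, test_cell: str, val_cell: str
) -> DatasetSplit:
    """Cell-segregated split: membership determined solely by cell_id, so no
    blob of the held-out cells leaks into training."""
    if test_cell == val_cell:
        raise ValueError("test and validation cells must differ")
    ids = np.asarray(ids, dtype=object)
    cells = np.asarray([str(c) for c in cell_ids], dtype=object)
    present = set(cells)
    for c in (test_cell, val_cell):
        if str(c) not in present:
            raise ValueError(f"unknown cell id {c!r}; dataset has {sorted(present)}")
    test = cells == str(test_cell)
    val = cells == str(val_cell)
    train = ~(test | val)
    return DatasetSplit(
        train_ids=list(ids[train]), val_ids=list(ids[val]), test_ids=list(ids[test]),
        mode="cell_wise",
    )


# ---------------------------------------------------------------------------
# Random forest on the 28 features
# ---------------------------------------------------------------------------

class CaveolaeRandomForest(BaseEstimator, ClassifierMixin):
    """Bagged random forest (100 trees) over the frozen 28-feature order.

    A thin, order-checked wrapper around scikit-learn's
    :class:`~sklearn.ensemble.RandomForestClassifier`: each tree is trained
    on a bootstrap resample and prediction is the majority vote. The fitted
    model records the feature-name order and refuses to predict on a matrix
    declared in a different order.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, **rf_kwargs):
        self.n_trees = n_trees
        self.seed = seed
        self.rf_kwargs = rf_kwargs

    def fit(self, X: np.ndarray, y: Sequence[int],
            feature_names: Optional[Sequence[str]] = None) -> "CaveolaeRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        names = tuple(feature_names) if feature_names is not None else FEATURE_NAMES
        if names != FEATURE_NAMES:
            raise ValueError("feature order does not match the frozen 28-feature order")
        self.feature_names_ = names
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, bootstrap=True, random_state=self.seed, **self.rf_kwargs
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def _check_X(self, X, feature_names):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) feature matrix, got {X.shape}")
        if feature_names is not None and tuple(feature_names) != self.feature_names_:
            raise ValueError("feature order does not match the order this model was trained on")
        return X

    def predict(self, X, feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        return self.forest_.predict(self._check_X(X, feature_names))

    def predict_proba(self, X, feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        return self.forest_.predict_proba(self._check_X(X, feature_names))

    def save(self, path) -> None:
        check_is_fitted(self, "forest_")
        joblib.dump({"forest": self.forest_, "feature_names": self.feature_names_,
                     "n_trees": self.n_trees, "seed": self.seed}, path)

    @classmethod
    def load(cls, path) -> "CaveolaeRandomForest":
        payload = joblib.load(path)
        model = cls(n_trees=payload["n_trees"], seed=payload["seed"])
        model.forest_ = payload["forest"]
        model.feature_names_ = tuple(payload["feature_names"])
        model.classes_ = model.forest_.classes_
        return model


def train_rf(X: np.ndarray, y: Sequence[int], n_trees: int = 100, seed: int = 0) -> CaveolaeRandomForest:
    """Convenience wrapper: fit a :class:`CaveolaeRandomForest`."""
    return CaveolaeRandomForest(n_trees=n_trees, seed=seed).fit(X, y)


@dataclass
class CrossValidationResult:
    pooled: ClassificationReport
    per_fold: list[ClassificationReport] = field(default_factory=list)
    seed: int = 0
    k: int = 10

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "pooled": self.pooled.to_dict(),
            "per_fold": [r.to_dict() for r in self.per_fold],
            "mean_fold_accuracy": float(np.mean([r.accuracy for r in self.per_fold])),
        }


def cross_validate(
    X: np.ndarray, y: Sequence[int], k: int = 10, n_trees: int = 100, seed: int = 0,
    return_predictions: bool = False,
):
    """Stratified k-fold cross-validation of the random forest.

    Confusion counts are pooled over all folds (every blob is tested exactly
    once); per-fold reports are also returned. With
    ``return_predictions=True`` additionally returns the out-of-fold
    prediction vector, aligned with the input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_fold = []
    oof = np.full(len(y), -1, dtype=int)
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = CaveolaeRandomForest(n_trees=n_trees, seed=seed + fold_i).fit(
            X[train_idx], y[train_idx]
        )
        pred = model.predict(X[test_idx])
        oof[test_idx] = pred
        fold_counts = confusion_from_predictions(y[test_idx], pred)
        per_fold.append(metrics_from_counts(fold_counts))
        pooled = pooled + fold_counts
    result = CrossValidationResult(
        pooled=metrics_from_counts(pooled), per_fold=per_fold, seed=seed, k=k
    )
    if return_predictions:
        return result, oof
    return result


def embed_features_2d(
    X: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2D t-SNE embedding of a feature matrix (standardized first).

    Deterministic per seed; intended for visualizing how separable the
    classes are in each feature space.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("embedding requires at least 3 samples")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        import warnings

        warnings.warn("constant feature columns present; they carry no embedding signal",
                      stacklevel=2)
    Xs = StandardScaler().fit_transform(X)
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(Xs)
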