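"""Effective-siRNA classification and SVM-RFE feature selection.

Activity-labeled 19-mers are thresholded into positive (effective) and
negative (ineffective) classes, a linear maximum-margin classifier is
trained on standardized features, and recursive feature elimination ranks
features by squared weight, keeping the subset that maximizes stratified
cross-validation accuracy.

The quadratic program behind the margin classifier is delegated to
scikit-learn's linear-kernel SVC; dataset construction, cross-validation
and the RFE loop live here.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .sequence_codec import normalize_sequence


@dataclass(frozen=True)
class LabeledRecord:
    """One training siRNA: sequence, normalized activity and derived label."""

    record_id: str
    sequence: str
    activity: float
    label: int = 0  # +1 effective, -1 ineffective, 0 unassigned

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError(f"activity {self.activity} outside [0, 1]")
        if self.label not in (-1, 0, 1):
            raise ValueError("label must be -1, 0 or +1")


@dataclass
class LabeledDataset:
    """A thresholded dataset with its cutoffs and exclusion count."""

    records: list[LabeledRecord]
    cutoffs: tuple[float, float]
    n_excluded: int

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


def make_datasets(records, cutoff_sets=((0.3, 0.7), (0.4, 0.6), (0.5, 0.5))):
    """Threshold activities into labeled datasets, one per (low, high) pair.

    activity >= high -> +1; activity <= low -> -1; records in the open
    interval (low, high) are excluded. Touching cutoffs (low == high) label
    every record. A dataset whose positive or negative class comes out
    empty raises.
    """
    records = [
        LabeledRecord(r.record_id, normalize_sequence(r.sequence), r.activity)
        for r in records
    ]
    datasets = []
    for low, high in cutoff_sets:
        if not 0.0 <= low <= high <= 1.0:
            raise ValueError(f"invalid cutoffs ({low}, {high}): need 0 <= low <= high <= 1")
        if low == high:
            labeled = [
                LabeledRecord(r.record_id, r.sequence, r.activity,
                              1 if r.activity >= high else -1)
                for r in records
            ]
            excluded = 0
        else:
            labeled = []
            excluded = 0
            for r in records:
                if r.activity >= high:
                    labeled.append(LabeledRecord(r.record_id, r.sequence, r.activity, 1))
                elif r.activity <= low:
                    labeled.append(LabeledRecord(r.record_id, r.sequence, r.activity, -1))
                else:
                    excluded += 1
        labels = [r.label for r in labeled]
        if 1 not in labels or -1 not in labels:
            raise ValueError(f"cutoffs ({low}, {high}) leave a class empty")
        datasets.append(LabeledDataset(records=labeled, cutoffs=(low, high),
                                       n_excluded=excluded))
    return datasets


@dataclass
class MarginModel:
    """A trained linear maximum-margin classifier on standardized features.

    ``weights``/``bias`` are expressed in the *original* feature coordinates
    (standardization folded in), so the decision value is w.x + b.
    """

    weights: np.ndarray
    bias: float
    feature_names: tuple[str, ...] | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.weights):
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {len(self.weights)}"
            )
        return X @ self.weights + self.bias


def train(X, y, C: float = 1.0, feature_names=None) -> MarginModel:
    """Fit a linear maximum-margin classifier with per-column standardization.

    Standardization statistics come from the training data only and are
    folded back into the returned weight vector, so callers apply the model
    to raw features. Deterministic given (X, y, C).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires two classes")
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
    svc = SVC(kernel="linear", C=C)
    svc.fit((X - scaler.mean_) / scale, y)
    w_std = svc.coef_.ravel()
    weights = w_std / scale
    bias = float(svc.intercept_[0] - np.dot(w_std, scaler.mean_ / scale))
    return MarginModel(weights=weights, bias=bias,
                       feature_names=tuple(feature_names) if feature_names else None)


def predict(model: MarginModel, X):
    """Labels and margins; a margin of exactly 0 is called negative."""
    margins = model.decision(np.asarray(X, dtype=float))
    labels = np.where(margins > 0, 1, -1)
    return labels, margins


def _fold_indices(y, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _index_hash(idx: np.ndarray) -> str:
    return hashlib.sha256(np.sort(np.asarray(idx)).tobytes()).hexdigest()[:16]


def cross_validate(X, y, folds: int = 5, seed: int = 0, C: float = 1.0,
                   columns=None, fold_splits=None):
    """Mean held-out accuracy of the margin classifier over stratified folds.

    ``columns`` restricts training and evaluation to a feature subset;
    ``fold_splits`` reuses a precomputed fold assignment so different
    subsets are compared on identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cols = np.arange(X.shape[1]) if columns is None else np.asarray(columns)
    splits = fold_splits if fold_splits is not None else _fold_indices(y, folds, seed)
    accs = []
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a fold's training split contains one class")
        model = train(X[np.ix_(train_idx, cols)], y[train_idx], C=C)
        labels, _ = predict(model, X[np.ix_(test_idx, cols)])
        accs.append(float(np.mean(labels == y[test_idx])))
    return float(np.mean(accs))


@dataclass
class RFEResult:
    """Outcome of recursive feature elimination.

    ``ranking`` lists all feature indices in elimination order (first
    eliminated first; survivors of the final step close the list in weight
    order). ``fold_train_hashes`` records a digest of each fold's training
    indices — bookkeeping that CV accuracies never trained on held-out data.
    """

    ranking: list[int]
    selected: list[int]
    cv_accuracy_path: list[float]
    n_features_path: list[int]
    fold_train_hashes: list[str] = field(default_factory=list)


def svm_rfe(X, y, step_fraction: float = 0.1, folds: int = 5, seed: int = 0,
            C: float = 1.0) -> RFEResult:
    """Recursive feature elimination around the linear margin classifier.

    At each step the classifier is refit on the surviving features, features
    are ranked by squared weight, and the lowest ``step_fraction`` (at least
    one) are eliminated; stratified CV accuracy of each surviving set is
    recorded on folds fixed once from ``seed``. The selected subset is the
    surviving set whose CV accuracy is maximal, ties resolved toward the
    smaller set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("RFE needs at least two features")
    if not 0.0 < step_fraction < 1.0:
        raise ValueError("step_fraction must lie in (0, 1)")
    splits = _fold_indices(y, folds, seed)
    hashes = [_index_hash(tr) for tr, _ in splits]
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    acc_path, n_path, snapshots = [], [], []
    while surviving:
        acc = cross_validate(X, y, folds=folds, seed=seed, C=C,
                             columns=surviving, fold_splits=splits)
        acc_path.append(acc)
        n_path.append(len(surviving))
        snapshots.append(list(surviving))
        if len(surviving) == 1:
            break
        model = train(X[:, surviving], y, C=C)
        order = np.argsort(model.weights ** 2, kind="stable")
        n_drop = max(1, int(math.floor(step_fraction * len(surviving))))
        n_drop = min(n_drop, len(surviving) - 1)
        dropped = [surviving[i] for i in order[:n_drop]]
        eliminated.extend(dropped)
        surviving = [f for f in surviving if f not in set(dropped)]
    # best accuracy; ties -> latest step = smallest surviving set
    best_step = max(range(len(acc_path)), key=lambda i: (acc_path[i], i))
    final_model = train(X[:, surviving], y, C=C)
    final_order = np.argsort(final_model.weights ** 2, kind="stable")
    ranking = eliminated + [surviving[i] for i in final_order]
    assert sorted(ranking) == list(range(X.shape[1]))
    return RFEResult(
        ranking=ranking,
        selected=sorted(snapshots[best_step]),
        cv_accuracy_path=acc_path,
        n_features_path=n_path,
        fold_train_hashes=hashes,
    )
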