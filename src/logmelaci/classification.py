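"""Two-layer fine-grained recognition and the evaluation metrics.

The recognition framework routes hierarchically: a first-layer classifier
separates bird species, then a per-species second-layer classifier assigns
the diel period (dawn / noon / night) of that species' vocalisation.  Both
layers are pluggable scikit-learn classifiers (1-nearest-neighbour by
default) fitted on fixed-length recording features: per-coefficient mean and
standard deviation of the second-order MFCC matrices (13 coefficients x
{static, delta, delta-delta} x {mean, std} = 78 values).

Evaluation uses one-vs-rest confusion counts per class and

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

macro-averaged by default (micro pools counts; micro accuracy is the plain
fraction of correct predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .features import MFCCMatrix

__all__ = [
    "FeatureVector",
    "ConfusionCounts",
    "MetricsResult",
    "pool_features",
    "split_train_val",
    "TwoLayerClassifier",
    "train_two_layer",
    "predict_two_layer",
    "confusion_counts",
    "metrics",
]


@dataclass
class FeatureVector:
    """Fixed-length pooled recording features with a pooling description."""

    values: np.ndarray
    pooling_spec: str = "mean+std over coeffs/delta/delta2 rows"


def pool_features(m: MFCCMatrix) -> FeatureVector:
    """Pool a variable-length MFCC matrix into a fixed-length vector.

    Concatenates per-row (mean, std) of the static, delta and delta-delta
    matrices: 13 coefficients give a length-78 vector.
    """
    if m.coeffs.size == 0:
        raise ValueError("cannot pool an empty MFCC matrix")
    parts = []
    for mat in (m.coeffs, m.delta, m.delta2):
        if mat is None:
            raise ValueError("pooling requires coeffs, delta and delta2")
        parts.append(np.mean(mat, axis=1))
        parts.append(np.std(mat, axis=1))
    return FeatureVector(np.concatenate(parts))


def _as_matrix(X) -> np.ndarray:
    if len(X) and isinstance(X[0], FeatureVector):
        return np.vstack([fv.values for fv in X])
    return np.asarray(X, dtype=float)


def split_train_val(X, y, train_fraction: float = 0.8, seed: int = 0):
    """Stratified train/validation split at the given fraction (default 8:2).

    ``y`` may be an (n,) label array or an (n, 2) array of (species, period)
    pairs, in which case stratification is on the joint label.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    strat = y if y.ndim == 1 else np.array(["||".join(row) for row in y.astype(str)])
    labels, counts = np.unique(strat, return_counts=True)
    lonely = labels[counts < 2]
    if len(lonely):
        raise ValueError(f"classes with a single sample cannot be split: {list(lonely)}")
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, train_size=train_fraction, stratify=strat, random_state=seed
    )
    return (X_tr, y_tr), (X_va, y_va)


class TwoLayerClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical species-then-period classifier.

    ``fit(X, y)`` takes an (n, 2) label array: column 0 the species, column 1
    the diel period.  Layer 1 is fitted on species over all samples; one
    layer-2 model per species is fitted on that species' periods.  ``predict``
    routes each sample through layer 1 and then the matching layer-2 model
    (a layer-1 error therefore consults the wrong species' period model;
    :meth:`predict_with_route` exposes which model ran).

    Parameters
    ----------
    base_estimator : sklearn classifier, optional
        Cloned for every layer; default 1-nearest-neighbour.
    """

    def __init__(self, base_estimator=None, random_state: int | None = None):
        self.base_estimator = base_estimator
        self.random_state = random_state

    def _make(self):
        base = self.base_estimator
        if base is None:
            base = KNeighborsClassifier(n_neighbors=1)
        est = clone(base)
        if "random_state" in est.get_params():
            est.set_params(random_state=self.random_state)
        return est

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (species, period) labels")
        species, periods = y[:, 0], y[:, 1]
        for sp in np.unique(species):
            cells, counts = np.unique(periods[species == sp], return_counts=True)
            thin = [f"({sp}, {c})" for c, n in zip(cells, counts) if n < 2]
            if thin:
                raise ValueError(f"cells with fewer than 2 samples: {thin}")
        self.layer1_ = self._make().fit(X, species)
        self.layer2_ = {}
        for sp in np.unique(species):
            mask = species == sp
            self.layer2_[sp] = self._make().fit(X[mask], periods[mask])
        self.classes_ = np.unique(["|".join(row) for row in y])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_with_route(self, X):
        """Predict (species, period) and report which layer-2 model ran."""
        if not hasattr(self, "layer1_"):
            raise RuntimeError("fit the classifier first")
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted with {self.n_features_in_}"
            )
        species = self.layer1_.predict(X)
        periods = np.empty(len(X), dtype=object)
        for sp in np.unique(species):
            mask = species == sp
            periods[mask] = self.layer2_[sp].predict(X[mask])
        pairs = np.column_stack([species, periods.astype(str)])
        return pairs, list(species)  # routing = the layer-2 model identity used

    def predict(self, X):
        return self.predict_with_route(X)[0]


def train_two_layer(dataset, base_estimator=None, random_state=None) -> TwoLayerClassifier:
    """Fit a :class:`TwoLayerClassifier` on (FeatureVector, species, period) triples."""
    X = _as_matrix([fv for fv, _, _ in dataset])
    y = np.array([[sp, per] for _, sp, per in dataset])
    return TwoLayerClassifier(base_estimator, random_state).fit(X, y)


def predict_two_layer(model: TwoLayerClassifier, x):
    """Route a single feature vector; returns (species, period, layer2_model_used)."""
    vec = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    pairs, route = model.predict_with_route(vec[None, :])
    return pairs[0, 0], pairs[0, 1], route[0]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class."""

    per_class: dict  # label -> (tp, fp, fn, tn)
    n_samples: int

    @property
    def n_classes(self) -> int:
        return len(self.per_class)


class MetricsResult(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_counts(pred, truth) -> ConfusionCounts:
    """One-vs-rest confusion counts over the union of observed labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    per_class = {}
    for label in sorted(set(pred) | set(truth)):
        p = pred == label
        t = truth == label
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        tn = int(np.sum(~p & ~t))
        per_class[label] = (tp, fp, fn, tn)
    return ConfusionCounts(per_class, len(pred))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; contributing 0")
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, averaging: str = "macro") -> MetricsResult:
    """Accuracy/precision/recall/F1 from confusion counts.

    macro: per-class values averaged, F1 from the averaged precision and
    recall.  micro: counts pooled first; micro accuracy is the fraction of
    exactly correct predictions (pooled TP / n_samples).
    """
    if c.n_samples < 1:
        raise ValueError("need at least one sample")
    if averaging == "macro":
        accs, precs, recs = [], [], []
        for label, (tp, fp, fn, tn) in c.per_class.items():
            accs.append(_safe_div(tp + tn, tp + fp + fn + tn, f"accuracy[{label}]"))
            precs.append(_safe_div(tp, tp + fp, f"precision[{label}]"))
            recs.append(_safe_div(tp, tp + fn, f"recall[{label}]"))
        acc, prec, rec = map(np.mean, (accs, precs, recs))
    elif averaging == "micro":
        tp = sum(v[0] for v in c.per_class.values())
        fp = sum(v[1] for v in c.per_class.values())
        fn = sum(v[2] for v in c.per_class.values())
        acc = tp / c.n_samples
        prec = _safe_div(tp, tp + fp, "micro precision")
        rec = _safe_div(tp, tp + fn, "micro recall")
    else:
        raise ValueError("averaging must be 'macro' or 'micro'")
    f1 = _safe_div(2 * prec * rec, prec + rec, "F1")
    return MetricsResult(float(acc), float(prec), float(rec), float(f1))
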