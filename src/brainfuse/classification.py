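"""Preset neural-network classifiers and the evaluation metric suite.

The five presets mirror the MATLAB Classification Learner naming
conventions: narrow [10], medium [25], wide [100], bilayered [10, 10],
trilayered [10, 10, 10] hidden units, ReLU activations, softmax output.
Metrics are derived from the confusion matrix with the standard
definitions (sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
FNR = 100 - sensitivity) plus a macro one-vs-rest AUC.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .datasets import FeatureMatrix, LabelVector

__all__ = ["ClassifierSpec", "MetricsReport", "make_classifier_preset",
           "compute_metrics", "evaluate_classifier", "PRESET_LAYOUTS"]

PRESET_LAYOUTS = {
    "narrow": [10],
    "medium": [25],
    "wide": [100],
    "bilayered": [10, 10],
    "trilayered": [10, 10, 10],
}


@dataclass
class ClassifierSpec:
    name: str
    hidden_layout: list[int]
    activation: str = "relu"
    max_iterations: int = 400
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.hidden_layout):
            raise ValueError("hidden widths must be >= 1")


@dataclass
class MetricsReport:
    """Confusion matrix plus percentage metrics (macro and per class)."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    fnr: float
    precision: float
    auc: float
    per_class: dict = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "fnr": self.fnr,
            "precision": self.precision,
            "auc": self.auc,
            "per_class": {k: list(map(float, v))
                          for k, v in self.per_class.items()},
            "wall_time_s": self.wall_time_s,
        }


def make_classifier_preset(name: str, max_iterations: int = 400,
                           seed: int = 0) -> ClassifierSpec:
    """Map a preset name to its concrete hidden-layer layout."""
    if name not in PRESET_LAYOUTS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_LAYOUTS)}")
    return ClassifierSpec(name=name, hidden_layout=list(PRESET_LAYOUTS[name]),
                          max_iterations=max_iterations, seed=seed)


def compute_metrics(confusion, auc: float = float("nan")) -> MetricsReport:
    """Derive the metric suite from a K x K confusion matrix
    (rows = truth, columns = prediction); percentages on [0, 100]."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if (cm < 0).any():
        raise ValueError("confusion entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty (zero total)")
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0) * 100.0
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0) * 100.0
    fnr = 100.0 - sens
    return MetricsReport(
        confusion=cm,
        accuracy=float(tp.sum() / total * 100.0),
        sensitivity=float(sens.mean()),
        fnr=float(fnr.mean()),
        precision=float(prec.mean()),
        auc=float(auc),
        per_class={"sensitivity": sens, "precision": prec, "fnr": fnr,
                   "tp": tp, "fp": fp, "fn": fn,
                   "tn": total - tp - fp - fn},
    )


def _build_mlp(spec: ClassifierSpec, seed: int):
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=tuple(spec.hidden_layout),
                      activation=spec.activation,
                      max_iter=spec.max_iterations,
                      random_state=int(seed) % (2 ** 31)))


def _macro_auc(y_true, proba, classes) -> float:
    try:
        if len(classes) == 2:
            return float(roc_auc_score(y_true, proba[:, 1]))
        return float(roc_auc_score(y_true, proba, multi_class="ovr",
                                   average="macro", labels=classes))
    except ValueError:
        return float("nan")


def _parse_protocol(protocol):
    if isinstance(protocol, dict):
        if "holdout_ratio" in protocol:
            return ("holdout", float(protocol["holdout_ratio"]))
        if "k_folds" in protocol:
            return ("kfold", int(protocol["k_folds"]))
        raise ValueError(f"unrecognised protocol {protocol!r}")
    if isinstance(protocol, str):
        kind, _, val = protocol.partition(":")
        if kind == "holdout":
            return ("holdout", float(val or 0.5))
        if kind in ("kfold", "k_folds"):
            return ("kfold", int(val or 10))
    raise ValueError(f"unrecognised protocol {protocol!r}")


def evaluate_classifier(features, labels, spec: ClassifierSpec,
                        protocol="holdout:0.5", seed: int = 0) -> MetricsReport:
    """Train/evaluate an MLP preset under a hold-out or k-fold protocol.

    Hold-out uses a seeded stratified split with the given training
    ratio. k-fold pools the out-of-fold predictions of all folds into a
    single confusion matrix and score set (leave-one-out, k = n, is the
    degenerate case). AUC is macro one-vs-rest on predicted class
    probabilities.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    classes = np.unique(y)
    kind, val = _parse_protocol(protocol)
    t0 = time.perf_counter()

    if kind == "holdout":
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=val, random_state=int(seed) % (2 ** 31),
            stratify=y)
        clf = _build_mlp(spec, seed)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        proba = clf.predict_proba(Xte)
        y_eval = yte
    else:
        k = val
        n = len(y)
        if k < 2 or k > n:
            raise ValueError("k must lie in [2, n_samples]")
        min_class = np.bincount(np.searchsorted(classes, y)).min()
        if k <= min_class:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=int(seed) % (2 ** 31))
        else:
            splitter = KFold(n_splits=k, shuffle=True,
                             random_state=int(seed) % (2 ** 31))
        pred = np.empty(n, dtype=y.dtype)
        proba = np.zeros((n, len(classes)))
        for tr, te in splitter.split(X, y):
            clf = _build_mlp(spec, seed)
            clf.fit(X[tr], y[tr])
            pred[te] = clf.predict(X[te])
            p = clf.predict_proba(X[te])
            cols = np.searchsorted(classes, clf.classes_)
            proba[np.ix_(te, cols)] = p
        y_eval = y

    cm = confusion_matrix(y_eval, pred, labels=classes)
    report = compute_metrics(cm, auc=_macro_auc(y_eval, proba, classes))
    report.wall_time_s = time.perf_counter() - t0
    return report
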