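"""Extreme learning machine: random fixed hidden layer, closed-form output.

The hidden layer is a seeded Gaussian projection followed by a sigmoid;
output weights are the ridge-regularised least-squares solution against
one-hot targets. Used both as a stand-alone classifier and as the
wrapper-selection fitness (hold-out accuracy of a candidate feature
subset).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .datasets import FeatureMatrix, LabelVector

__all__ = ["ELMClassifier", "elm_fitness"]


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer network with random weights and ridge output.

    Parameters
    ----------
    n_hidden : width of the random sigmoid hidden layer.
    alpha : ridge regularisation of the output least-squares solve.
    random_state : seed for the hidden projection.
    """

    def __init__(self, n_hidden: int = 100, alpha: float = 1e-2,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        d = X.shape[1]
        self.hidden_w_ = rng.normal(0.0, 1.0 / np.sqrt(d),
                                    size=(d, self.n_hidden))
        self.hidden_b_ = rng.normal(0.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        Y = np.eye(len(self.classes_))[y_idx]
        A = H.T @ H + self.alpha * np.eye(self.n_hidden)
        self.beta_ = np.linalg.solve(A, H.T @ Y)
        self.n_features_in_ = d
        return self

    def _hidden(self, X):
        Z = (X - self.mean_) / self.scale_
        return 1.0 / (1.0 + np.exp(-(Z @ self.hidden_w_ + self.hidden_b_)))

    def decision_function(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X)
        return self._hidden(X) @ self.beta_

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def predict_proba(self, X):
        s = self.decision_function(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)


def _as_xy(features, labels):
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    return X, y


def elm_fitness(features, labels, mask=None, hidden: int = 100,
                seed: int = 0, ridge: float = 1e-2) -> float:
    """Hold-out accuracy of an ELM on the masked feature columns.

    A seeded stratified 70:30 split is drawn, the ELM (seeded hidden
    projection) is fit on the training part, and the hold-out accuracy is
    returned — fully deterministic given ``seed``.
    """
    X, y = _as_xy(features, labels)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no columns")
        X = X[:, mask]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes present")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=0.3, random_state=int(seed) % (2 ** 31), stratify=y)
    clf = ELMClassifier(n_hidden=hidden, alpha=ridge,
                        random_state=int(seed) % (2 ** 31))
    clf.fit(Xtr, ytr)
    return float((clf.predict(Xte) == yte).mean())
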