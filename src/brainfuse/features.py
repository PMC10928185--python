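"""Deep-feature extraction from named network taps.

``extract_features`` reads the activation at a tap ("gap" for the
modified ResNet, "decoder_conv_last" for the autoencoder) for every
sample, in dataset order. Spatial (convolutional) taps are reduced by
global average pooling over the spatial dimensions before flattening, so
the feature width equals the tap's channel count regardless of input
resolution. The two Transformer classes wrap the train-then-extract
workflow in sklearn estimator form.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .architectures import build_modified_resnet50, build_stacked_autoencoder
from .datasets import FeatureMatrix, ImageDataset
from .nn.training import TrainConfig, TrainedModel, train_network

__all__ = ["extract_features", "ResNetFeatureExtractor",
           "SAEFeatureExtractor"]


def _images_of(data) -> np.ndarray:
    if isinstance(data, ImageDataset):
        return data.images
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError("expected an ImageDataset or (n, H, W, C) array")
    return arr


def extract_features(model: TrainedModel, data, tap: str = "gap",
                     batch_size: int = 32) -> FeatureMatrix:
    """One feature row per sample from the named tap, in dataset order."""
    spec = model.spec
    if tap not in spec.named_taps:
        raise ValueError(
            f"unknown tap {tap!r}; model exposes {sorted(spec.named_taps)}")
    images = _images_of(data)
    rows = []
    for start in range(0, len(images), batch_size):
        _, taps, _ = model.network.forward(images[start:start + batch_size],
                                           train=False, taps=(tap,))
        act = taps[tap]
        if act.ndim == 4:                       # conv tap: GAP then flatten
            act = act.mean(axis=(2, 3))
        rows.append(act.reshape(act.shape[0], -1))
    values = np.concatenate(rows, axis=0)
    names = [f"{tap}_{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values=values, feature_names=names)


class _ExtractorBase(TransformerMixin, BaseEstimator):
    tap: str

    def transform(self, X):
        check_is_fitted(self, "model_")
        return extract_features(self.model_, X, tap=self.tap).values

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "model_")
        width = self.model_.spec.tap_width(self.tap)
        return np.array([f"{self.tap}_{i}" for i in range(width)])


class ResNetFeatureExtractor(_ExtractorBase):
    """Modified ResNet-50 trained on labelled images; emits GAP features.

    ``width_scale`` scales every channel count; at 1.0 the GAP feature
    width is 1024 (desk-scale defaults use 0.25 -> 256 features).
    """

    tap = "gap"

    def __init__(self, width_scale: float = 0.25, max_epochs: int = 5,
                 minibatch: int = 32, learning_rate: float = 1e-2,
                 momentum: float = 0.9, l2_weight: float = 1e-4,
                 optimizer: str = "sgdm", random_state: int = 0):
        self.width_scale = width_scale
        self.max_epochs = max_epochs
        self.minibatch = minibatch
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2_weight = l2_weight
        self.optimizer = optimizer
        self.random_state = random_state

    def fit(self, X, y=None):
        images = _images_of(X)
        if y is None and isinstance(X, ImageDataset):
            y = X.labels.labels
        y = np.asarray(y)
        n_classes = int(y.max()) + 1
        h, w, c = images.shape[1:]
        self.spec_ = build_modified_resnet50((h, w, c), n_classes,
                                             self.width_scale)
        cfg = TrainConfig(optimizer=self.optimizer,
                          max_epochs=self.max_epochs,
                          minibatch=self.minibatch,
                          learning_rate=self.learning_rate,
                          momentum=self.momentum,
                          l2_weight=self.l2_weight)
        self.model_ = train_network(self.spec_, images, y, cfg,
                                    seed=self.random_state)
        self.history_ = self.model_.history
        return self


class SAEFeatureExtractor(_ExtractorBase):
    """Stacked autoencoder trained by reconstruction; emits the pooled
    last-decoder-conv features (width ``feature_dim``, default 1236)."""

    tap = "decoder_conv_last"

    def __init__(self, bottlenecks=(100, 50), feature_dim: int = 1236,
                 max_epochs: int = 3, minibatch: int = 32,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 random_state: int = 0):
        self.bottlenecks = bottlenecks
        self.feature_dim = feature_dim
        self.max_epochs = max_epochs
        self.minibatch = minibatch
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    def fit(self, X, y=None):
        images = _images_of(X)
        h, w, c = images.shape[1:]
        self.spec_ = build_stacked_autoencoder((h, w, c),
                                               tuple(self.bottlenecks),
                                               self.feature_dim)
        cfg = TrainConfig(optimizer=self.optimizer,
                          max_epochs=self.max_epochs,
                          minibatch=self.minibatch,
                          learning_rate=self.learning_rate)
        self.model_ = train_network(self.spec_, images, None, cfg,
                                    seed=self.random_state)
        self.history_ = self.model_.history
        return self
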