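"""Parallel-pooling feature fusion.

Each deep-feature vector is pooled independently along the feature axis
(window 2, stride 2 by default, so a width-W vector becomes ceil(W/2))
and the pooled vectors are concatenated: widths 1024 and 1236 fuse to
512 + 618 = 1130. Vectors whose length does not align with the window
are first mean-padded (extended with their own arithmetic mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import FeatureMatrix

__all__ = ["FusionConfig", "mean_pad", "pool1d", "fuse_features",
           "ParallelPooling"]


@dataclass
class FusionConfig:
    window: int = 2
    stride: int = 2
    mode: str = "max"                      # max | mean
    pad_policy: str = "mean_pad_to_even"   # mean_pad_to_even | none

    def __post_init__(self):
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")
        if self.mode not in ("max", "mean"):
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        if self.pad_policy not in ("mean_pad_to_even", "none"):
            raise ValueError(f"unknown pad policy {self.pad_policy!r}")


def mean_pad(v, target_len: int) -> np.ndarray:
    """Extend ``v`` to ``target_len`` by appending its arithmetic mean."""
    v = np.asarray(v, dtype=float)
    if target_len < v.shape[-1]:
        raise ValueError("target_len must not be shorter than the vector")
    extra = target_len - v.shape[-1]
    if extra == 0:
        return v.copy()
    fill = np.broadcast_to(v.mean(axis=-1, keepdims=True),
                           v.shape[:-1] + (extra,))
    return np.concatenate([v, fill], axis=-1)


def _padded_length(length: int, cfg: FusionConfig) -> int:
    """Smallest window-aligned length >= ``length`` under the pad policy."""
    if cfg.pad_policy == "none":
        if cfg.window > length:
            raise ValueError("window larger than the vector")
        return length
    target = max(length, cfg.window)
    over = (target - cfg.window) % cfg.stride
    if over:
        target += cfg.stride - over
    return target


def pool1d(v, cfg: FusionConfig | None = None) -> np.ndarray:
    """Pool a feature vector (or each row of a matrix) along features."""
    cfg = cfg or FusionConfig()
    v = np.asarray(v, dtype=float)
    length = v.shape[-1]
    if length < 1:
        raise ValueError("cannot pool an empty vector")
    target = _padded_length(length, cfg)
    vp = mean_pad(v, target)
    win = sliding_window_view(vp, cfg.window, axis=-1)[..., ::cfg.stride, :]
    return win.max(axis=-1) if cfg.mode == "max" else win.mean(axis=-1)


def pooled_width(length: int, cfg: FusionConfig | None = None) -> int:
    cfg = cfg or FusionConfig()
    return (_padded_length(length, cfg) - cfg.window) // cfg.stride + 1


def _values(x):
    return x.values if isinstance(x, FeatureMatrix) else np.asarray(x, float)


def fuse_features(fv1, fv2, cfg: FusionConfig | None = None) -> FeatureMatrix:
    """Pool both matrices row-wise and concatenate (fv1 part first)."""
    cfg = cfg or FusionConfig()
    a, b = _values(fv1), _values(fv2)
    if a.shape[0] != b.shape[0]:
        raise ValueError("sample counts differ between the two matrices")
    parts, names = [], []
    for tag, m in (("fv1", a), ("fv2", b)):
        if m.shape[1] == 0:
            continue
        pooled = pool1d(m, cfg)
        parts.append(pooled)
        names += [f"{tag}_pool_{i}" for i in range(pooled.shape[1])]
    if not parts:
        raise ValueError("both inputs are empty")
    return FeatureMatrix(values=np.concatenate(parts, axis=1),
                         feature_names=names)


class ParallelPooling(TransformerMixin, BaseEstimator):
    """sklearn transformer applying :func:`pool1d` to each row.

    Compose two of these in a FeatureUnion (or call :func:`fuse_features`)
    to realise the parallel-pooling fusion of two extractor outputs.
    """

    def __init__(self, window: int = 2, stride: int = 2, mode: str = "max",
                 pad_policy: str = "mean_pad_to_even"):
        self.window = window
        self.stride = stride
        self.mode = mode
        self.pad_policy = pad_policy

    def _cfg(self) -> FusionConfig:
        return FusionConfig(self.window, self.stride, self.mode,
                            self.pad_policy)

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        self.width_out_ = pooled_width(self.n_features_in_, self._cfg())
        return self

    def transform(self, X):
        return pool1d(np.asarray(X, dtype=float), self._cfg())
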