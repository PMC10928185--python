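"""Grad-CAM class-activation mapping for the trained CNN.

Each convolutional feature map A^k at the chosen layer is weighted by
the spatial mean of the class-score gradient a_k^c = (1/N) sum_ij
dy^c / dA^k_ij, and the weighted sum is passed through a ReLU:
M = ReLU(sum_k a_k^c A^k). The raw map keeps the tap's spatial shape;
an optional bilinear upsampling to input resolution is min-max
normalised for display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn.training import TrainedModel

__all__ = ["Heatmap", "gradcam_weights", "gradcam_map", "explain_image",
           "save_heatmap_overlay"]


@dataclass
class Heatmap:
    map: np.ndarray                 # H' x W' non-negative raw map
    class_index: int
    score: float
    upsampled: np.ndarray | None = None


def gradcam_weights(gradients) -> np.ndarray:
    """Global average of each of K gradient grids -> K channel weights."""
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 3 or g.shape[0] < 1 or g.shape[1] * g.shape[2] < 1:
        raise ValueError("gradients must be a non-empty (K, H, W) stack")
    return g.mean(axis=(1, 2))


def gradcam_map(activations, weights, class_index: int = 0,
                score: float = 0.0, upsample_to=None) -> Heatmap:
    """ReLU of the weight-combined activation maps."""
    A = np.asarray(activations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if A.ndim != 3 or w.shape != (A.shape[0],):
        raise ValueError("activations (K, H, W) and weights (K,) must match")
    raw = np.maximum(np.tensordot(w, A, axes=1), 0.0)
    up = None
    if upsample_to is not None:
        zoom = (upsample_to[0] / raw.shape[0], upsample_to[1] / raw.shape[1])
        up = ndimage.zoom(raw, zoom, order=1)
        hi = up.max()
        if hi > 0:
            up = (up - up.min()) / (hi - up.min())
    return Heatmap(map=raw, class_index=int(class_index), score=float(score),
                   upsampled=up)


def deepest_spatial_conv(spec, min_size: int = 4) -> str:
    """Name of the deepest conv layer whose feature maps are at least
    ``min_size`` x ``min_size`` — a sensible CAM layer at any input
    resolution (small inputs shrink the default deep tap to 1 x 1)."""
    best = None
    for ls in spec.layers:
        if ls.kind == "conv" and len(ls.out_shape) == 3:
            if ls.out_shape[1] >= min_size and ls.out_shape[2] >= min_size:
                best = ls.name
    if best is None:
        best = spec.named_taps.get("cam", spec.layers[-1].name)
    return best


def explain_image(model: TrainedModel, image, class_index: int | None = None,
                  layer: str = "cam") -> Heatmap:
    """Grad-CAM heatmap of one image at a convolutional layer.

    ``layer`` is either a named tap ("cam" points at the last conv of
    the third added residual block) or any conv layer name in the spec;
    it must resolve to a spatial activation. The class score is the
    pre-softmax logit of ``class_index`` (predicted class if omitted).
    """
    spec = model.spec
    tap_name = spec.named_taps.get(layer, layer)
    try:
        tap_spec = spec.get(tap_name)
    except KeyError:
        raise ValueError(f"unknown tap or layer {layer!r}") from None
    if len(tap_spec.out_shape) != 3:
        raise ValueError(f"tap {layer!r} is not a convolutional layer")
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        batch = image[None]
    else:
        raise ValueError("image must be H x W x C")

    net = model.network
    logits, _, ctx = net.forward(batch, train=False)
    logits = logits[0]
    if class_index is None:
        class_index = int(logits.argmax())
    if not 0 <= class_index < logits.shape[0]:
        raise ValueError("class index out of range")
    dout = np.zeros((1, logits.shape[0]))
    dout[0, class_index] = 1.0
    _, captured = net.backward(ctx, dout, capture=(tap_name,))
    act = ctx["acts"][tap_name]
    grads = captured.get(tap_name)
    if grads is None:
        grads = np.zeros_like(act)
    A = act[0]
    G = grads[0]
    weights = gradcam_weights(G)
    h, w = image.shape[:2]
    hm = gradcam_map(A, weights, class_index=class_index,
                     score=float(logits[class_index]), upsample_to=(h, w))
    return hm


def save_heatmap_overlay(image, heatmap: Heatmap, path, alpha: float = 0.45):
    """Write a PNG of the image with the upsampled heatmap overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    image = np.asarray(image, dtype=float)
    base = image[..., 0] if image.ndim == 3 else image
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(base, cmap="gray", vmin=0, vmax=1)
    overlay = heatmap.upsampled
    if overlay is None:
        zoom = (base.shape[0] / heatmap.map.shape[0],
                base.shape[1] / heatmap.map.shape[1])
        overlay = ndimage.zoom(heatmap.map, zoom, order=1)
    ax.imshow(overlay, cmap="jet", alpha=alpha)
    ax.set_axis_off()
    ax.set_title(f"class {heatmap.class_index}  score {heatmap.score:.2f}",
                 fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
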