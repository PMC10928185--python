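"""Builders for the two deep feature extractors.

``build_modified_resnet50`` constructs a ResNet-50 backbone (stem + four
bottleneck stages) extended with three additional stride-1 residual blocks
of four convolutions each (alternating 1x1 / 3x3 kernels), one extra 3x3
stride-1 convolution after the first added block, and a global-average-
pooling head tapped as ``"gap"``. The added-block channel plan ends at
1024 channels at ``width_scale=1`` so the GAP feature vector is 1024 wide.

``build_stacked_autoencoder`` constructs a convolutional encoder (5
stride-2 convs), two stacked dense bottlenecks (default widths 100 and
50), and a mirrored decoder of 5 upsampling convs whose last conv is
tapped as ``"decoder_conv_last"`` with a pooled/flattened width equal to
``feature_dim`` (default 1236).
"""

from __future__ import annotations

import numpy as np

from .nn.network import LayerSpec, NetworkSpec

__all__ = [
    "build_modified_resnet50",
    "build_stacked_autoencoder",
    "sae_layer_forward",
    "audit_spec",
]

# per-stack regularisation constants of the two dense bottleneck stacks:
# (L2 weight penalty, sparsity penalty weight, target sparsity proportion)
_STACK_REGS = [(0.004, 4.0, 0.15), (0.002, 4.0, 0.10)]


def _w(c: int, scale: float) -> int:
    return max(1, int(round(c * scale)))


class _Builder:
    def __init__(self, input_shape):
        h, w, c = input_shape
        self.layers = [LayerSpec("input", "input", (), (c, h, w))]
        self.shape = (c, h, w)
        self.top = "input"

    def add(self, name, kind, out_shape, attrs=None, inputs=None):
        inputs = (self.top,) if inputs is None else tuple(inputs)
        self.layers.append(LayerSpec(name, kind, inputs, tuple(out_shape),
                                     attrs or {}))
        self.top = name
        self.shape = tuple(out_shape)
        return name

    def conv(self, name, out_ch, kernel, stride, attrs=None, inputs=None):
        c, h, w = self.shape if inputs is None else self._shape_of(inputs[0])
        p = kernel // 2
        oh = (h + 2 * p - kernel) // stride + 1
        ow = (w + 2 * p - kernel) // stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("input too small for the downsampling plan")
        a = {"in_channels": c, "out_channels": out_ch,
             "kernel": kernel, "stride": stride}
        a.update(attrs or {})
        return self.add(name, "conv", (out_ch, oh, ow), a, inputs)

    def _shape_of(self, name):
        for ls in self.layers:
            if ls.name == name:
                return ls.out_shape
        raise KeyError(name)


def _bn_relu(b: _Builder, name: str, relu: bool = True):
    b.add(f"{name}_bn", "bn", b.shape)
    if relu:
        b.add(f"{name}_relu", "act", b.shape, {"activation": "relu"})


def _bottleneck(b: _Builder, prefix: str, inner: int, out: int, stride: int,
                role: str, kernels=(1, 3, 1)):
    """Standard 3-conv bottleneck residual block with identity/projection skip."""
    entry = b.top
    in_shape = b.shape
    widths = [inner, inner, out]
    for i, (k, ch) in enumerate(zip(kernels, widths), start=1):
        s = stride if i == 1 else 1
        b.conv(f"{prefix}_conv{i}", ch, k, s, {"block": prefix, "role": role})
        b.add(f"{prefix}_conv{i}_bn", "bn", b.shape)
        if i < len(kernels):
            b.add(f"{prefix}_conv{i}_relu", "act", b.shape,
                  {"activation": "relu"})
    body = b.top
    body_shape = b.shape
    if in_shape != body_shape:
        b.conv(f"{prefix}_proj", out, 1, stride,
               {"block": prefix, "role": role, "projection": True},
               inputs=(entry,))
        b.add(f"{prefix}_proj_bn", "bn", b.shape)
        skip = b.top
    else:
        skip = entry
    b.add(f"{prefix}_add", "add", body_shape, inputs=(body, skip))
    b.add(f"{prefix}_relu", "act", body_shape, {"activation": "relu"})


def _added_block(b: _Builder, prefix: str, out: int):
    """Added residual block: 4 convs alternating 1x1 and 3x3, stride 1."""
    entry = b.top
    in_shape = b.shape
    for i, k in enumerate((1, 3, 1, 3), start=1):
        b.conv(f"{prefix}_conv{i}", out, k, 1,
               {"block": prefix, "role": "added"})
        b.add(f"{prefix}_conv{i}_bn", "bn", b.shape)
        if i < 4:
            b.add(f"{prefix}_conv{i}_relu", "act", b.shape,
                  {"activation": "relu"})
    body = b.top
    body_shape = b.shape
    if in_shape != body_shape:
        b.conv(f"{prefix}_proj", out, 1, 1,
               {"block": prefix, "role": "added", "projection": True},
               inputs=(entry,))
        b.add(f"{prefix}_proj_bn", "bn", b.shape)
        skip = b.top
    else:
        skip = entry
    b.add(f"{prefix}_add", "add", body_shape, inputs=(body, skip))
    b.add(f"{prefix}_relu", "act", body_shape, {"activation": "relu"})


def build_modified_resnet50(input_shape=(224, 224, 3), n_classes: int = 4,
                            width_scale: float = 1.0) -> NetworkSpec:
    """Modified ResNet-50 spec with three extra residual blocks and a
    1024-wide (at ``width_scale=1``) global-average-pooling feature tap."""
    h, w, c = input_shape
    if h < 32 or w < 32:
        raise ValueError("input must be at least 32x32")
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    if n_classes < 2:
        raise ValueError("need at least two classes")

    b = _Builder(input_shape)
    b.conv("stem_conv", _w(64, width_scale), 7, 2, {"role": "stem"})
    _bn_relu(b, "stem_conv")
    cc, hh, ww = b.shape
    oh, ow = (hh + 2 - 3) // 2 + 1, (ww + 2 - 3) // 2 + 1
    b.add("stem_pool", "maxpool", (cc, oh, ow),
          {"kernel": 3, "stride": 2, "pad": 1})

    stage_plan = [  # (n_blocks, inner, out, first stride)
        (3, 64, 256, 1),
        (4, 128, 512, 2),
        (6, 256, 1024, 2),
        (3, 512, 2048, 2),
    ]
    for s, (n_blocks, inner, out, stride) in enumerate(stage_plan, start=2):
        for i in range(n_blocks):
            _bottleneck(b, f"stage{s}_block{i + 1}",
                        _w(inner, width_scale), _w(out, width_scale),
                        stride if i == 0 else 1, role="backbone")

    # three added residual blocks; channel plan ends at 1024 * width_scale
    added_out = _w(1024, width_scale)
    _added_block(b, "added1", added_out)
    # one extra 3x3 stride-1 conv after the first added block
    b.conv("post_added1_conv", added_out, 3, 1, {"role": "post_added"})
    _bn_relu(b, "post_added1_conv")
    _added_block(b, "added2", added_out)
    _added_block(b, "added3", added_out)

    b.add("gap", "gap", (added_out,))
    b.add("fc", "dense", (n_classes,),
          {"in_dim": added_out, "out_dim": n_classes, "activation": "softmax"})

    taps = {"gap": "gap", "cam": "added3_conv4"}
    return NetworkSpec(b.layers, taps, tuple(input_shape), n_classes,
                       width_scale, kind="classifier")


def _pool_plan(feature_dim: int, spatial: int) -> tuple[int, int]:
    """Choose (grid g, channels C) with g*g*C = feature_dim, g | spatial."""
    for g in (4, 3, 2, 1):
        if feature_dim % (g * g) == 0 and spatial % g == 0:
            return g, feature_dim // (g * g)
    raise ValueError(f"no valid pooling plan for feature_dim={feature_dim}")


def build_stacked_autoencoder(input_shape=(32, 32, 1),
                              bottlenecks=(100, 50),
                              feature_dim: int = 1236) -> NetworkSpec:
    """Convolutional stacked autoencoder with dense bottleneck stacks.

    Encoder: 5 stride-2 convs. Bottlenecks: stacked sigmoid dense layers
    (greedy pre-training constants attached per stack). Decoder: 5
    upsampling convs; the last one is tapped as ``decoder_conv_last`` with
    a pooled width of ``feature_dim``. A 1x1 output projection (not
    counted among the decoder convs) produces the reconstruction.
    """
    h, w, c = input_shape
    if not bottlenecks:
        raise ValueError("need at least one bottleneck width")
    if feature_dim < 1:
        raise ValueError("feature_dim must be positive")
    if h % 32 or w % 32 or h < 32 or w < 32:
        raise ValueError(
            "no valid pooling plan: spatial dims must be multiples of 32")
    grid, tap_ch = _pool_plan(feature_dim, h)

    enc_ch = [8, 16, 32, 64, 64]
    b = _Builder(input_shape)
    for i, ch in enumerate(enc_ch, start=1):
        b.conv(f"enc_conv{i}", ch, 3, 2, {"role": "encoder"})
        b.add(f"enc_conv{i}_relu", "act", b.shape, {"activation": "relu"})
    code_shape = b.shape
    flat_dim = int(np.prod(code_shape))
    b.add("enc_flatten", "flatten", (flat_dim,), {"role": "encoder"})

    widths = [flat_dim] + list(bottlenecks)
    for i, hidden in enumerate(bottlenecks, start=1):
        l2, sreg, sprop = _STACK_REGS[min(i - 1, len(_STACK_REGS) - 1)]
        attrs = {"in_dim": widths[i - 1], "out_dim": hidden,
                 "role": "bottleneck", "stack": i, "l2": l2,
                 "sparsity_reg": sreg, "sparsity_prop": sprop,
                 "pretrain_epochs": 5}
        b.add(f"ae{i}_dense", "dense", (hidden,), attrs)
        b.add(f"ae{i}_act", "act", (hidden,),
              {"activation": "sigmoid", "role": "bottleneck",
               "sparsity_reg": sreg, "sparsity_prop": sprop})

    # mirrored dense decoding path
    for i in range(len(bottlenecks), 0, -1):
        out_dim = widths[i - 1]
        b.add(f"ae{i}_decode", "dense", (out_dim,),
              {"in_dim": widths[i], "out_dim": out_dim,
               "mirror": f"ae{i}_dense"})
    b.add("dec_reshape", "reshape", code_shape)

    dec_ch = [64, 32, 16, 8, tap_ch]
    for i, ch in enumerate(dec_ch, start=1):
        cc, hh, ww = b.shape
        b.add(f"dec_up{i}", "upsample", (cc, hh * 2, ww * 2))
        kernel = 3 if i < 5 else 1
        b.conv(f"dec_conv{i}", ch, kernel, 1, {"role": "decoder"})
        b.add(f"dec_conv{i}_relu", "act", b.shape, {"activation": "relu"})

    # feature tap: pool the last decoder conv to grid x grid and flatten
    cc, hh, ww = b.shape
    b.add("tap_pool", "adaptive_pool", (cc, grid, grid), {"grid": grid})
    b.add("tap_flat", "flatten", (feature_dim,))

    # reconstruction head (projection; not a counted decoder conv)
    b.conv("out_conv", c, 1, 1, {"role": "output", "projection": True},
           inputs=("dec_conv5_relu",))
    b.add("out_act", "act", b.shape, {"activation": "sigmoid"})

    taps = {"decoder_conv_last": "tap_flat", "cam": "dec_conv5"}
    return NetworkSpec(b.layers, taps, tuple(input_shape), None, 1.0,
                       kind="autoencoder")


def sae_layer_forward(x, weights, bias, activation: str = "sigmoid"):
    """Single encoder/decoder layer map ``act(W x + b)``.

    ``weights`` has shape (out, in); ``activation`` is one of
    ``{"sigmoid", "relu", "linear"}``.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if weights.shape[1] != x.shape[-1] or weights.shape[0] != bias.shape[0]:
        raise ValueError("incompatible shapes for layer forward pass")
    z = x @ weights.T + bias
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def audit_spec(spec: NetworkSpec) -> dict:
    """Independent structural walk of a spec: conv counts by role/block,
    strides of added blocks, and named-tap widths."""
    convs = [ls for ls in spec.layers if ls.kind == "conv"]
    added = [ls for ls in convs
             if ls.attrs.get("role") == "added" and not ls.attrs.get("projection")]
    blocks: dict[str, list] = {}
    for ls in added:
        blocks.setdefault(ls.attrs["block"], []).append(ls)
    return {
        "n_convs": len(convs),
        "added_blocks": sorted(blocks),
        "convs_per_added_block": {k: len(v) for k, v in blocks.items()},
        "added_strides": sorted({ls.attrs["stride"] for ls in added}),
        "added_kernels": {k: [ls.attrs["kernel"] for ls in v]
                          for k, v in blocks.items()},
        "encoder_convs": sum(1 for ls in convs
                             if ls.attrs.get("role") == "encoder"),
        "decoder_convs": sum(1 for ls in convs
                             if ls.attrs.get("role") == "decoder"),
        "tap_widths": {t: spec.tap_width(t) for t in spec.named_taps},
        "n_parameters": spec.count_parameters(),
    }
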