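"""Declarative layer graphs and their executable instantiation.

A :class:`NetworkSpec` is an ordered list of :class:`LayerSpec` descriptors;
every descriptor references only earlier layers, so the list order is a
topological order. ``named_taps`` marks layers whose activations are read
out for feature extraction ("gap", "decoder_conv_last") or class-activation
mapping. :class:`Network` compiles a spec into parameterised layer objects
and provides forward, backward, and activation-gradient passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import layers as L

__all__ = ["LayerSpec", "NetworkSpec", "Network"]

#: layer kinds carrying trainable weights subject to L2 decay
_DECAYED = {"conv", "dense"}


@dataclass
class LayerSpec:
    """One node of the layer graph.

    ``attrs`` holds kind-specific settings (kernel, stride, units,
    activation ...) plus free-form structural tags such as ``block`` /
    ``role`` used by architecture audits.
    """

    name: str
    kind: str                      # conv|bn|act|maxpool|gap|adaptive_pool|upsample|flatten|reshape|dense|add|input
    inputs: tuple[str, ...]
    out_shape: tuple[int, ...]     # per-sample shape, (C, H, W) or (D,)
    attrs: dict = field(default_factory=dict)


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    named_taps: dict[str, str]
    input_shape: tuple[int, int, int]        # (H, W, C)
    n_classes: int | None = None
    width_scale: float = 1.0
    kind: str = "classifier"                 # classifier | autoencoder

    def __post_init__(self):
        seen: set[str] = set()
        for spec in self.layers:
            for ref in spec.inputs:
                if ref not in seen:
                    raise ValueError(
                        f"layer {spec.name!r} references {ref!r} before definition")
            if spec.name in seen:
                raise ValueError(f"duplicate layer name {spec.name!r}")
            seen.add(spec.name)
        for tag, name in self.named_taps.items():
            if name not in seen:
                raise ValueError(f"tap {tag!r} points at unknown layer {name!r}")

    def get(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def tap_width(self, tag: str) -> int:
        """Flattened width of a named tap's activation."""
        shape = self.get(self.named_taps[tag]).out_shape
        return int(np.prod(shape))

    def count_parameters(self) -> int:
        """Trainable parameter count derived from layer arithmetic."""
        total = 0
        for spec in self.layers:
            a = spec.attrs
            if spec.kind == "conv":
                total += a["out_channels"] * a["in_channels"] * a["kernel"] ** 2
                total += a["out_channels"]
            elif spec.kind == "dense":
                total += a["in_dim"] * a["out_dim"] + a["out_dim"]
            elif spec.kind == "bn":
                total += 2 * spec.out_shape[0]
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [asdict(s) for s in self.layers],
                "named_taps": self.named_taps,
                "input_shape": list(self.input_shape),
                "n_classes": self.n_classes,
                "width_scale": self.width_scale,
                "kind": self.kind,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        layers = [
            LayerSpec(s["name"], s["kind"], tuple(s["inputs"]),
                      tuple(s["out_shape"]), s["attrs"])
            for s in d["layers"]
        ]
        return cls(layers, d["named_taps"], tuple(d["input_shape"]),
                   d["n_classes"], d["width_scale"], d["kind"])


def _make_layer(spec: LayerSpec):
    a = spec.attrs
    if spec.kind == "conv":
        return L.Conv2D(a["in_channels"], a["out_channels"], a["kernel"], a["stride"])
    if spec.kind == "bn":
        return L.BatchNorm2D(spec.out_shape[0])
    if spec.kind == "act":
        return L.Activation(a["activation"])
    if spec.kind == "maxpool":
        return L.MaxPool2D(a["kernel"], a["stride"], a.get("pad", 0))
    if spec.kind == "gap":
        return L.GlobalAvgPool()
    if spec.kind == "adaptive_pool":
        return L.AdaptiveAvgPool2D(a["grid"])
    if spec.kind == "upsample":
        return L.Upsample2x()
    if spec.kind == "flatten":
        return L.Flatten()
    if spec.kind == "reshape":
        return L.Reshape(tuple(spec.out_shape))
    if spec.kind == "dense":
        return L.Dense(a["in_dim"], a["out_dim"])
    if spec.kind == "add":
        return L.Add()
    raise ValueError(f"unknown layer kind {spec.kind!r}")


class Network:
    """Executable instantiation of a :class:`NetworkSpec`.

    Parameters are initialised from a seeded generator so two networks
    built from the same spec and seed are bitwise identical.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self._ops = {}
        self.params: dict[str, dict[str, np.ndarray]] = {}
        for ls in spec.layers:
            if ls.kind == "input":
                continue
            op = _make_layer(ls)
            self._ops[ls.name] = op
            self.params[ls.name] = op.init_params(rng)
        self.output_name = spec.layers[-1].name

    # ------------------------------------------------------------------ #
    def forward(self, x: np.ndarray, train: bool = False, taps=()):
        """Run the graph on an NHWC batch.

        Returns ``(output, tap_values, ctx)`` where ``ctx`` carries the
        per-layer caches required by :meth:`backward`.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:                      # single image
            x = x[None]
        acts = {}
        caches = {}
        first = self.spec.layers[0]
        if first.kind != "input":
            raise ValueError("spec must start with an input layer")
        acts[first.name] = x.transpose(0, 3, 1, 2)   # NHWC -> NCHW
        for ls in self.spec.layers[1:]:
            inp = [acts[n] for n in ls.inputs]
            op = self._ops[ls.name]
            if ls.kind == "add":
                y, cache = op.forward(self.params[ls.name], inp, train)
            else:
                y, cache = op.forward(self.params[ls.name], inp[0], train)
            acts[ls.name] = y
            caches[ls.name] = cache
        tap_vals = {t: acts[self.spec.named_taps[t]] for t in taps}
        ctx = {"acts": acts, "caches": caches, "train": train}
        return acts[self.output_name], tap_vals, ctx

    def backward(self, ctx, dout: np.ndarray, capture=(), extra_grads=None):
        """Backpropagate ``dout`` from the output layer.

        Returns ``(param_grads, captured)`` where ``captured`` maps layer
        names to activation gradients (used by Grad-CAM). ``extra_grads``
        lets the caller inject additional loss gradients at interior
        layers (used for sparsity penalties on bottleneck activations).
        """
        grad_map: dict[str, np.ndarray] = {self.output_name: dout}
        if extra_grads:
            for name, g in extra_grads.items():
                grad_map[name] = grad_map.get(name, 0) + g
        param_grads: dict[str, dict[str, np.ndarray]] = {}
        captured: dict[str, np.ndarray] = {}
        for ls in reversed(self.spec.layers[1:]):
            dy = grad_map.pop(ls.name, None)
            if dy is None:
                continue
            if ls.name in capture:
                captured[ls.name] = dy
            op = self._ops[ls.name]
            dx, pg = op.backward(self.params[ls.name], ctx["caches"][ls.name], dy)
            if pg:
                param_grads[ls.name] = pg
            if ls.kind == "add":
                for ref, d in zip(ls.inputs, dx):
                    grad_map[ref] = grad_map.get(ref, 0) + d
            else:
                grad_map[ls.inputs[0]] = grad_map.get(ls.inputs[0], 0) + dx
        name0 = self.spec.layers[0].name
        if name0 in capture and name0 in grad_map:
            captured[name0] = grad_map[name0]
        return param_grads, captured

    # ------------------------------------------------------------------ #
    def trainable(self):
        """Yield (layer_name, param_name, array) for gradient-bearing params."""
        for lname, pdict in self.params.items():
            for pname, arr in pdict.items():
                if pname.startswith("running_"):
                    continue
                yield lname, pname, arr

    def decayed_weights(self):
        """Weight matrices subject to L2 decay (conv/dense kernels)."""
        for ls in self.spec.layers:
            if ls.kind in _DECAYED:
                yield ls.name, self.params[ls.name]["w"]

    # ------------------------------------------------------------------ #
    def save(self, path):
        import pathlib

        path = pathlib.Path(path)
        arrays = {}
        for lname, pdict in self.params.items():
            for pname, arr in pdict.items():
                arrays[f"{lname}::{pname}"] = arr
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path):
        import pathlib

        path = pathlib.Path(path)
        spec = NetworkSpec.from_json(path.with_suffix(".json").read_text())
        net = cls(spec, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            for key in data.files:
                lname, pname = key.split("::")
                net.params[lname][pname] = data[key]
        return net
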