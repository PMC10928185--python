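"""Training loops: SGDM/Adam, cross-entropy for the CNN classifier, and
greedy layer-wise + joint reconstruction training for the autoencoder."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network, NetworkSpec

__all__ = ["TrainConfig", "TrainedModel", "train_network", "sae_loss",
           "softmax_cross_entropy"]


@dataclass
class TrainConfig:
    """Optimiser and protocol settings.

    Defaults follow the reference training recipe: SGDM, minibatch 256,
    initial learning rate 1e-3, with a 50:50 stratified split and k=10
    folds available for evaluation protocols.
    """

    optimizer: str = "sgdm"
    max_epochs: int = 100
    minibatch: int = 256
    learning_rate: float = 1e-3
    momentum: float = 0.9
    l2_weight: float = 0.0
    sparsity_reg: float = 0.0
    sparsity_prop: float = 0.1
    folds: int = 10
    split_ratio: float = 0.5

    def __post_init__(self):
        if self.optimizer not in ("sgdm", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.max_epochs < 1 or self.minibatch < 1:
            raise ValueError("max_epochs and minibatch must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.l2_weight < 0 or self.sparsity_reg < 0:
            raise ValueError("regularisation weights must be non-negative")
        if not 0.0 < self.sparsity_prop < 1.0:
            raise ValueError("sparsity_prop must lie in (0, 1)")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


@dataclass
class TrainedModel:
    """A spec plus its trained weights and per-epoch history."""

    spec: NetworkSpec
    network: Network
    history: list = field(default_factory=list)
    seed: int = 0

    def save(self, path):
        self.network.save(path)

    @classmethod
    def load(cls, path):
        net = Network.load(path)
        return cls(spec=net.spec, network=net, history=[], seed=net.seed)


# --------------------------------------------------------------------- #
# losses


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def _kl_bernoulli(rho: float, rho_hat: np.ndarray) -> float:
    r = np.clip(rho_hat, 1e-8, 1 - 1e-8)
    return float(np.sum(rho * np.log(rho / r)
                        + (1 - rho) * np.log((1 - rho) / (1 - r))))


def sae_loss(inputs, reconstructions, weights=None, cfg: TrainConfig | None = None,
             hidden_activations=None) -> float:
    """Reconstruction objective for the autoencoder.

    The core term is the half mean squared error over the batch,
    ``(1 / 2N) * ||I - dOUT||^2`` with N the batch size. When ``cfg``
    carries nonzero ``l2_weight`` / ``sparsity_reg`` the weight-decay and
    KL-sparsity penalties are added; with both at zero the value is the
    plain reconstruction error.
    """
    inputs = np.asarray(inputs, dtype=float)
    reconstructions = np.asarray(reconstructions, dtype=float)
    if inputs.shape != reconstructions.shape:
        raise ValueError("inputs and reconstructions must share a shape")
    n = inputs.shape[0]
    if n < 1:
        raise ValueError("batch must contain at least one sample")
    loss = float(np.sum((inputs - reconstructions) ** 2)) / (2.0 * n)
    if cfg is not None and cfg.l2_weight > 0 and weights is not None:
        loss += cfg.l2_weight * sum(float(np.sum(w ** 2)) for w in weights)
    if cfg is not None and cfg.sparsity_reg > 0 and hidden_activations is not None:
        for h in hidden_activations:
            rho_hat = np.asarray(h, dtype=float).mean(axis=0)
            loss += cfg.sparsity_reg * _kl_bernoulli(cfg.sparsity_prop, rho_hat)
    return loss


# --------------------------------------------------------------------- #
# optimisers


class _SGDM:
    def __init__(self, net: Network, cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.mu = cfg.momentum
        self.vel = {(l, p): np.zeros_like(a) for l, p, a in net.trainable()}

    def step(self, net: Network, grads):
        for lname, pname, arr in net.trainable():
            g = grads.get(lname, {}).get(pname)
            if g is None:
                continue
            v = self.vel[(lname, pname)]
            v *= self.mu
            v -= self.lr * g
            arr += v


class _Adam:
    def __init__(self, net: Network, cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {(l, p): np.zeros_like(a) for l, p, a in net.trainable()}
        self.v = {(l, p): np.zeros_like(a) for l, p, a in net.trainable()}

    def step(self, net: Network, grads):
        self.t += 1
        for lname, pname, arr in net.trainable():
            g = grads.get(lname, {}).get(pname)
            if g is None:
                continue
            key = (lname, pname)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(net, cfg):
    return _Adam(net, cfg) if cfg.optimizer == "adam" else _SGDM(net, cfg)


def _add_l2(net: Network, grads, l2: float):
    if l2 <= 0:
        return
    for lname, w in net.decayed_weights():
        pg = grads.setdefault(lname, {})
        pg["w"] = pg.get("w", 0) + 2.0 * l2 * w


# --------------------------------------------------------------------- #
# classifier training


def _train_classifier(net: Network, images, labels, cfg: TrainConfig, seed: int):
    rng = np.random.default_rng([int(seed), 17])
    opt = _make_optimizer(net, cfg)
    n = len(labels)
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for start in range(0, n, cfg.minibatch):
            idx = order[start:start + cfg.minibatch]
            xb, yb = images[idx], labels[idx]
            logits, _, ctx = net.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            grads, _ = net.backward(ctx, dlogits)
            _add_l2(net, grads, cfg.l2_weight)
            opt.step(net, grads)
            tot_loss += loss * len(idx)
            tot_correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({"epoch": epoch, "loss": tot_loss / n,
                        "accuracy": tot_correct / n})
    return history


# --------------------------------------------------------------------- #
# autoencoder training


def _train_dense_ae(X, hidden, epochs, lr, l2, sparsity_reg, sparsity_prop, rng):
    """Tied-free two-layer autoencoder (sigmoid code, linear output).

    Used to pre-train each dense bottleneck greedily; returns the encoder
    weights, encoder bias, decoder weights, decoder bias, and the codes.
    """
    n, d = X.shape
    w1 = rng.normal(0, np.sqrt(1.0 / d), size=(d, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0, np.sqrt(1.0 / hidden), size=(hidden, d))
    b2 = np.zeros(d)
    batch = min(64, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            xb = X[order[start:start + batch]]
            m = len(xb)
            a = 1.0 / (1.0 + np.exp(-(xb @ w1 + b1)))
            out = a @ w2 + b2
            dout = (out - xb) / m
            rho_hat = a.mean(axis=0)
            r = np.clip(rho_hat, 1e-8, 1 - 1e-8)
            dkl = sparsity_reg * (-sparsity_prop / r
                                  + (1 - sparsity_prop) / (1 - r)) / m
            da = dout @ w2.T + dkl
            dz = da * a * (1 - a)
            gw2 = a.T @ dout + 2 * l2 * w2
            gw1 = xb.T @ dz + 2 * l2 * w1
            w2 -= lr * gw2
            b2 -= lr * dout.sum(axis=0)
            w1 -= lr * gw1
            b1 -= lr * dz.sum(axis=0)
    codes = 1.0 / (1.0 + np.exp(-(X @ w1 + b1)))
    return w1, b1, w2, b2, codes


def _train_autoencoder(net: Network, images, cfg: TrainConfig, seed: int):
    """Greedy layer-wise pre-training of the dense bottleneck stacks
    followed by joint fine-tuning of the whole encoder-decoder graph."""
    rng = np.random.default_rng([int(seed), 23])
    spec = net.spec

    stacks = [ls for ls in spec.layers
              if ls.kind == "dense" and ls.attrs.get("role") == "bottleneck"]
    mirrors = {ls.attrs["mirror"]: ls for ls in spec.layers
               if ls.kind == "dense" and "mirror" in ls.attrs}
    kl_acts = [ls for ls in spec.layers
               if ls.kind == "act" and ls.attrs.get("role") == "bottleneck"]

    # codes of the (randomly initialised) conv encoder feed the greedy phase
    flat_name = next(ls.name for ls in spec.layers
                     if ls.kind == "flatten" and ls.attrs.get("role") == "encoder")
    _, taps, _ = net.forward(images, train=False, taps=())
    codes = None
    # recompute the flatten activation directly
    _, _, ctx = net.forward(images, train=False)
    codes = ctx["acts"][flat_name]

    for ls in stacks:
        a = ls.attrs
        w1, b1, w2, b2, codes = _train_dense_ae(
            codes, a["out_dim"],
            epochs=a.get("pretrain_epochs", 5),
            lr=cfg.learning_rate,
            l2=a.get("l2", cfg.l2_weight),
            sparsity_reg=a.get("sparsity_reg", cfg.sparsity_reg),
            sparsity_prop=a.get("sparsity_prop", cfg.sparsity_prop),
            rng=rng)
        net.params[ls.name]["w"] = w1
        net.params[ls.name]["b"] = b1
        mirror = mirrors.get(ls.name)
        if mirror is not None:
            net.params[mirror.name]["w"] = w2
            net.params[mirror.name]["b"] = b2

    # joint fine-tuning with reconstruction + weight decay + KL sparsity
    opt = _make_optimizer(net, cfg)
    n = len(images)
    history = []
    target = images.transpose(0, 3, 1, 2)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        tot = 0.0
        for start in range(0, n, cfg.minibatch):
            idx = order[start:start + cfg.minibatch]
            xb = images[idx]
            m = len(idx)
            out, _, ctx = net.forward(xb, train=True)
            resid = out - target[idx]
            loss = float(np.sum(resid ** 2)) / (2.0 * m)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"autoencoder training diverged at epoch {epoch}")
            dout = resid / m
            extra = {}
            for ls in kl_acts:
                a = ctx["acts"][ls.name]
                rho = ls.attrs.get("sparsity_prop", cfg.sparsity_prop)
                reg = ls.attrs.get("sparsity_reg", cfg.sparsity_reg)
                if reg <= 0:
                    continue
                r = np.clip(a.mean(axis=0), 1e-8, 1 - 1e-8)
                extra[ls.name] = np.broadcast_to(
                    reg * (-rho / r + (1 - rho) / (1 - r)) / m, a.shape).copy()
            grads, _ = net.backward(ctx, dout, extra_grads=extra)
            _add_l2(net, grads, cfg.l2_weight)
            opt.step(net, grads)
            tot += loss * m
        history.append({"epoch": epoch, "loss": tot / n})
    return history


# --------------------------------------------------------------------- #


def train_network(spec: NetworkSpec, images, labels=None,
                  cfg: TrainConfig | None = None, seed: int = 0) -> TrainedModel:
    """Train a network described by ``spec`` on an NHWC image batch.

    Classifier specs are trained with softmax cross-entropy; autoencoder
    specs with greedy layer-wise pre-training then joint reconstruction
    fine-tuning. The same ``seed`` yields the same parameters and history.
    """
    cfg = cfg or TrainConfig()
    images = np.asarray(images, dtype=np.float64)
    net = Network(spec, seed=seed)
    if spec.kind == "classifier":
        labels = np.asarray(labels)
        counts = np.bincount(labels)
        if (counts[counts > 0] < 2).any():
            raise ValueError("need at least 2 samples per class")
        history = _train_classifier(net, images, labels, cfg, seed)
    else:
        history = _train_autoencoder(net, images, cfg, seed)
    return TrainedModel(spec=spec, network=net, history=history, seed=seed)
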