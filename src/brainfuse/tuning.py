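"""Jaya-driven hyperparameter initialisation for network training.

Candidate configurations are encoded in [0, 1] per dimension; the
parameter-free Jaya update moves each candidate toward the best scoring
configuration and away from the worst, with greedy acceptance. The
default search space brackets the reference training recipe: optimizer
in {sgdm, adam}, log-uniform learning rate on [1e-4, 1e-2], momentum on
[0.8, 0.99], minibatch in {32, 64, 128, 256}.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .nn.training import TrainConfig
from .selection import jaya_update

__all__ = ["HyperparamSpace", "default_hyperparam_space",
           "tune_hyperparameters_jaya"]


@dataclass
class Dimension:
    name: str                       # TrainConfig field name
    kind: str                       # linear | log | choice
    low: float = 0.0
    high: float = 1.0
    choices: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind in ("linear", "log") and not self.low < self.high:
            raise ValueError(f"bounds for {self.name!r} must be ordered")
        if self.kind == "choice" and not self.choices:
            raise ValueError(f"choice set for {self.name!r} is empty")

    def decode(self, u: float):
        if self.kind == "linear":
            return self.low + u * (self.high - self.low)
        if self.kind == "log":
            return float(np.exp(np.log(self.low)
                                + u * (np.log(self.high) - np.log(self.low))))
        idx = min(int(u * len(self.choices)), len(self.choices) - 1)
        return self.choices[idx]


@dataclass
class HyperparamSpace:
    dimensions: list[Dimension]
    budget: tuple[int, int] = (6, 20)        # (population, iterations)

    def __post_init__(self):
        if not self.dimensions:
            raise ValueError("hyperparameter space is empty")
        if self.budget[0] < 2 or self.budget[1] < 1:
            raise ValueError("budget must be at least (2 candidates, 1 iter)")

    def decode(self, u: np.ndarray, base: TrainConfig) -> TrainConfig:
        updates = {d.name: d.decode(float(v))
                   for d, v in zip(self.dimensions, u)}
        return dataclasses.replace(base, **updates)


def default_hyperparam_space(population: int = 6,
                             iterations: int = 20) -> HyperparamSpace:
    return HyperparamSpace(
        dimensions=[
            Dimension("optimizer", "choice", choices=["sgdm", "adam"]),
            Dimension("learning_rate", "log", 1e-4, 1e-2),
            Dimension("momentum", "linear", 0.8, 0.99),
            Dimension("minibatch", "choice", choices=[32, 64, 128, 256]),
        ],
        budget=(population, iterations),
    )


def tune_hyperparameters_jaya(space: HyperparamSpace, eval_fn,
                              seed: int = 0,
                              base: TrainConfig | None = None) -> TrainConfig:
    """Maximise ``eval_fn(TrainConfig) -> score`` with the Jaya update.

    With budget (P, I) the function is evaluated exactly P + P*I times.
    Returns the best configuration found.
    """
    base = base or TrainConfig()
    rng = np.random.default_rng([int(seed), 31])
    pop, iters = space.budget
    d = len(space.dimensions)
    U = rng.uniform(size=(pop, d))

    def score(u):
        s = float(eval_fn(space.decode(u, base)))
        if not np.isfinite(s):
            raise ValueError("eval_fn returned a non-finite score")
        return s

    fitness = np.array([score(u) for u in U])
    best_i = int(np.argmax(fitness))
    best_u, best_f = U[best_i].copy(), float(fitness[best_i])

    for _ in range(iters):
        ib = int(np.argmax(fitness))
        iw = int(np.argmin(fitness))
        Xb, Xw = U[ib].copy(), U[iw].copy()
        for i in range(pop):
            cand = jaya_update(U[i], Xb, Xw,
                               rng.uniform(size=d), rng.uniform(size=d))
            f = score(cand)
            if f > fitness[i]:
                U[i] = cand
                fitness[i] = f
                if f > best_f:
                    best_u, best_f = cand.copy(), float(f)
    return space.decode(best_u, base)
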