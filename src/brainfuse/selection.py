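"""Hybrid Grey Wolf / Jaya wrapper feature selection.

Phase 1 runs Grey Wolf Optimization over continuous positions in
[0, 1]^d: every wolf is binarised at 0.5 into a feature mask, scored by
ELM hold-out accuracy, and moved toward the three current leaders
(alpha, beta, delta) by the encircling equations, with the exploration
coefficient g decaying linearly from 2 to 0. Phase 2 refines the final
population with the parameter-free Jaya update — step toward the best
candidate and away from the worst — under greedy acceptance. The
best-ever position, binarised, is the selected mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .elm import elm_fitness
from .datasets import FeatureMatrix, LabelVector

__all__ = [
    "WolfPack",
    "SelectionConfig",
    "SelectionResult",
    "gwo_update_position",
    "jaya_update",
    "binarize_position",
    "gwo_select",
    "select_features",
    "GreyWolfJayaSelector",
]


@dataclass
class WolfPack:
    positions: np.ndarray          # (pop, d) in [0, 1]
    fitness: np.ndarray            # (pop,)
    leaders: tuple[int, int, int]  # alpha, beta, delta indices
    g: float
    iteration: int


@dataclass
class SelectionConfig:
    population: int = 50
    gwo_iterations: int = 200
    jaya_iterations: int = 100
    elm_hidden: int = 100
    ridge: float = 1e-2


@dataclass
class SelectionResult:
    mask: np.ndarray
    n_selected: int
    fitness_trace: list[float] = field(default_factory=list)
    best_position: np.ndarray | None = None
    best_fitness: float = -np.inf
    seed: int = 0


def gwo_update_position(Z, Z_alpha, Z_beta, Z_delta, g, rng_draws):
    """Encircling update toward the three leaders, clipped to [0, 1].

    ``rng_draws`` is a sequence of three ``(h1, h2)`` pairs (one per
    leader), each a vector in [0, 1] of the same dimension as ``Z``:
    M = 2 g h1 - g and B = 2 h2, L = |B * Z_leader - Z|,
    Z_i = Z_leader - M * L, and the new position is the mean of the
    three Z_i.
    """
    Z = np.asarray(Z, dtype=float)
    if not 0.0 <= g <= 2.0:
        raise ValueError("g must lie in [0, 2]")
    contributions = []
    for Z_lead, (h1, h2) in zip((Z_alpha, Z_beta, Z_delta), rng_draws):
        Z_lead = np.asarray(Z_lead, dtype=float)
        if Z_lead.shape != Z.shape:
            raise ValueError("leader/position dimension mismatch")
        M = 2.0 * g * np.asarray(h1, dtype=float) - g
        B = 2.0 * np.asarray(h2, dtype=float)
        L = np.abs(B * Z_lead - Z)
        contributions.append(Z_lead - M * L)
    Znew = (contributions[0] + contributions[1] + contributions[2]) / 3.0
    return np.clip(Znew, 0.0, 1.0)


def jaya_update(X, X_best, X_worst, r1, r2):
    """Parameter-free update toward the best and away from the worst:
    X' = X + r1 (X_best - |X|) - r2 (X_worst - |X|), clipped to [0, 1]."""
    X = np.asarray(X, dtype=float)
    X_best = np.asarray(X_best, dtype=float)
    X_worst = np.asarray(X_worst, dtype=float)
    if X_best.shape != X.shape or X_worst.shape != X.shape:
        raise ValueError("dimension mismatch")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    Xn = X + r1 * (X_best - np.abs(X)) - r2 * (X_worst - np.abs(X))
    return np.clip(Xn, 0.0, 1.0)


def binarize_position(position, threshold: float = 0.5) -> np.ndarray:
    """Threshold a continuous position into a mask; guarantees >= 1 column
    by falling back to the largest-position component."""
    position = np.asarray(position, dtype=float)
    mask = position >= threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(position.argmax())] = True
    return mask


class _MaskFitness:
    """Position -> fitness of the binarised mask, memoised per mask.

    The underlying mask fitness (ELM hold-out accuracy with a fixed
    seeded split) is deterministic, so caching is exact.
    """

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[bytes, float] = {}
        self.calls = 0

    def __call__(self, position: np.ndarray) -> float:
        mask = binarize_position(position)
        key = np.packbits(mask).tobytes()
        if key not in self.cache:
            self.calls += 1
            val = float(self.fn(mask))
            if not np.isfinite(val):
                raise ValueError("fitness function returned a non-finite value")
            self.cache[key] = val
        return self.cache[key]


def _default_fitness(features, labels, hidden, seed, ridge=1e-2):
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float)
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    return _MaskFitness(
        lambda mask: elm_fitness(X, y, mask, hidden=hidden, seed=seed,
                                 ridge=ridge))


def gwo_select(features, labels=None, population: int = 50,
               iterations: int = 200, fitness_fn=None, seed: int = 0,
               elm_hidden: int = 100, ridge: float = 1e-2):
    """Grey-Wolf phase over positions in [0, 1]^d.

    ``fitness_fn`` maps a continuous position to a score to maximise; by
    default it is the ELM hold-out accuracy of the position binarised at
    0.5. Returns ``(pack, best_position, best_fitness, trace, fitness)``.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float)
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least two features to select from")
    if population < 3:
        raise ValueError("population must be at least 3 (alpha/beta/delta)")
    rng = np.random.default_rng([int(seed), 5])
    fit = fitness_fn or _default_fitness(features, labels, elm_hidden, seed,
                                         ridge)

    Z = rng.uniform(size=(population, d))
    fitness = np.array([fit(z) for z in Z])
    if not np.isfinite(fitness).all():
        raise ValueError("fitness function returned a non-finite value")

    def leaders_of(f):
        # stable sort -> ties broken by lower wolf index
        order = np.argsort(-f, kind="stable")
        return tuple(int(i) for i in order[:3])

    lead = leaders_of(fitness)
    best_i = lead[0]
    best_pos = Z[best_i].copy()
    best_fit = float(fitness[best_i])
    trace = [best_fit]
    g = 2.0

    for m in range(1, iterations + 1):
        g = 2.0 * (1.0 - m / iterations)
        Za, Zb, Zd = (Z[i].copy() for i in lead)
        for i in range(population):
            draws = [(rng.uniform(size=d), rng.uniform(size=d))
                     for _ in range(3)]
            Z[i] = gwo_update_position(Z[i], Za, Zb, Zd, g, draws)
            fitness[i] = fit(Z[i])
        lead = leaders_of(fitness)
        if fitness[lead[0]] > best_fit:
            best_fit = float(fitness[lead[0]])
            best_pos = Z[lead[0]].copy()
        trace.append(best_fit)

    pack = WolfPack(positions=Z, fitness=fitness, leaders=lead, g=g,
                    iteration=iterations)
    return pack, best_pos, best_fit, trace, fit


def select_features(features, labels, config: SelectionConfig | None = None,
                    seed: int = 0, fitness_fn=None) -> SelectionResult:
    """Two-phase GWO then Jaya wrapper selection; returns the binary mask
    of the best-ever position. The fitness trace is the best-ever value
    per iteration across both phases (non-decreasing)."""
    cfg = config or SelectionConfig()
    pack, best_pos, best_fit, trace, fit = gwo_select(
        features, labels, cfg.population, cfg.gwo_iterations,
        fitness_fn=fitness_fn, seed=seed, elm_hidden=cfg.elm_hidden,
        ridge=cfg.ridge)

    rng = np.random.default_rng([int(seed), 11])
    Z = pack.positions
    fitness = pack.fitness
    pop, d = Z.shape
    for _ in range(cfg.jaya_iterations):
        ib = int(np.argmax(fitness))
        iw = int(np.argmin(fitness))
        Xb, Xw = Z[ib].copy(), Z[iw].copy()
        for i in range(pop):
            cand = jaya_update(Z[i], Xb, Xw,
                               rng.uniform(size=d), rng.uniform(size=d))
            f = fit(cand)
            if f > fitness[i]:           # greedy acceptance
                Z[i] = cand
                fitness[i] = f
                if f > best_fit:
                    best_fit = float(f)
                    best_pos = cand.copy()
        trace.append(best_fit)

    mask = binarize_position(best_pos)
    return SelectionResult(mask=mask, n_selected=int(mask.sum()),
                           fitness_trace=trace, best_position=best_pos,
                           best_fitness=best_fit, seed=int(seed))


class GreyWolfJayaSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector driven by the GWO->Jaya wrapper search.

    ``fit(X, y)`` runs the two-phase search with an ELM hold-out-accuracy
    fitness and stores the binary support mask; ``transform`` keeps the
    selected columns.
    """

    def __init__(self, population: int = 50, gwo_iterations: int = 200,
                 jaya_iterations: int = 100, elm_hidden: int = 100,
                 random_state: int = 0):
        self.population = population
        self.gwo_iterations = gwo_iterations
        self.jaya_iterations = jaya_iterations
        self.elm_hidden = elm_hidden
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cfg = SelectionConfig(population=self.population,
                              gwo_iterations=self.gwo_iterations,
                              jaya_iterations=self.jaya_iterations,
                              elm_hidden=self.elm_hidden)
        self.result_ = select_features(X, y, cfg, seed=self.random_state)
        self.support_ = self.result_.mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_
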