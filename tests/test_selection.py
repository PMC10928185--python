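"""Grey Wolf and Jaya update equations, and the two-phase wrapper search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brainfuse as bf
from brainfuse.selection import (GreyWolfJayaSelector, SelectionConfig,
                                 binarize_position, gwo_select,
                                 gwo_update_position, jaya_update,
                                 select_features)


class TestGwoUpdate:
    def test_hand_computed_scalar_case(self):
        """Z=0.2 with leaders 0.8/0.6/0.4 at g=1, h1=0.75, h2=0.5 -> 0.4."""
        draws = [(np.array([0.75]), np.array([0.5]))] * 3
        out = gwo_update_position(np.array([0.2]), np.array([0.8]),
                                  np.array([0.6]), np.array([0.4]),
                                  1.0, draws)
        np.testing.assert_allclose(out, [0.4])

    def test_g_zero_moves_to_leader_centroid(self, rng):
        Z = rng.uniform(size=6)
        Za, Zb, Zd = (rng.uniform(size=6) for _ in range(3))
        draws = [(rng.uniform(size=6), np.full(6, 0.5)) for _ in range(3)]
        out = gwo_update_position(Z, Za, Zb, Zd, 0.0, draws)
        np.testing.assert_allclose(out, (Za + Zb + Zd) / 3)

    def test_converged_pack_is_fixed_point(self):
        Z = np.array([0.3, 0.7])
        draws = [(np.full(2, 0.9), np.full(2, 0.5))] * 3
        out = gwo_update_position(Z, Z, Z, Z, 1.5, draws)
        np.testing.assert_allclose(out, Z)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gwo_update_position(np.zeros(3), np.zeros(2), np.zeros(3),
                                np.zeros(3), 1.0,
                                [(np.zeros(3), np.zeros(3))] * 3)

    @given(st.floats(0.0, 2.0), st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_coefficient_ranges(self, g, seed):
        """M components stay in [-g, g]; B components stay in [0, 2]."""
        rng = np.random.default_rng(seed)
        h1, h2 = rng.uniform(size=4), rng.uniform(size=4)
        M = 2 * g * h1 - g
        B = 2 * h2
        assert (np.abs(M) <= g + 1e-12).all()
        assert ((B >= 0) & (B <= 2)).all()


class TestJayaUpdate:
    def test_stationary_when_best_equals_worst_equals_x(self, rng):
        X = rng.uniform(size=5)
        out = jaya_update(X, X, X, rng.uniform(size=5), rng.uniform(size=5))
        np.testing.assert_allclose(out, X)

    def test_direct_substitution(self):
        out = jaya_update(np.array([0.5]), np.array([1.0]), np.array([0.0]),
                          np.array([0.5]), np.array([0.5]))
        np.testing.assert_allclose(out, [1.0])

    def test_zero_step(self, rng):
        X = rng.uniform(size=4)
        out = jaya_update(X, rng.uniform(size=4), rng.uniform(size=4),
                          np.zeros(4), np.zeros(4))
        np.testing.assert_allclose(out, X)

    def test_clipped_to_unit_box(self):
        out = jaya_update(np.array([0.9]), np.array([1.0]), np.array([0.0]),
                          np.array([1.0]), np.array([1.0]))
        assert 0.0 <= out[0] <= 1.0


class TestBinarize:
    def test_threshold_and_fallback(self):
        np.testing.assert_array_equal(
            binarize_position(np.array([0.6, 0.4, 0.5])), [True, False, True])
        np.testing.assert_array_equal(
            binarize_position(np.array([0.1, 0.3, 0.2])),
            [False, True, False])


class TestGwoSelect:
    def test_recovers_sphere_optimum(self):
        """Known-optimum recovery on a 5-D sphere peaked at 0.5."""
        X = np.zeros((2, 5))
        hits = 0
        for seed in range(10):
            _, best, _, _, _ = gwo_select(
                X, None, population=20, iterations=50,
                fitness_fn=lambda z: -float(((z - 0.5) ** 2).sum()),
                seed=seed)
            hits += bool(np.all(np.abs(best - 0.5) <= 0.1))
        assert hits >= 8

    def test_zero_iterations_returns_best_of_initial_population(self):
        X = np.zeros((2, 4))
        fn = lambda z: float(z.sum())
        pack, best, best_fit, trace, _ = gwo_select(
            X, None, population=8, iterations=0, fitness_fn=fn, seed=2)
        init = np.random.default_rng([2, 5]).uniform(size=(8, 4))
        expect = init[np.argmax(init.sum(axis=1))]
        np.testing.assert_allclose(best, expect)
        assert len(trace) == 1

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            gwo_select(np.zeros((2, 4)), None, population=2, iterations=1,
                       fitness_fn=lambda z: 0.0)


class TestSelectFeatures:
    def test_trace_is_nondecreasing(self, feature_data):
        fm, lv = feature_data
        res = select_features(fm, lv, SelectionConfig(10, 10, 10), seed=0)
        trace = np.asarray(res.fitness_trace)
        assert (np.diff(trace) >= -1e-12).all()
        assert res.n_selected >= 1

    def test_perfect_column_always_selected(self):
        """d=2 with one perfectly predictive column: enumerate all three
        non-empty masks as the oracle, then check the search agrees."""
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = np.column_stack([y * 4.0 + rng.normal(0, 0.1, 60),
                             rng.normal(size=60)])
        scores = {}
        for mask in [(True, False), (False, True), (True, True)]:
            scores[mask] = bf.elm_fitness(X, y, np.array(mask), seed=1)
        best_mask = max(scores, key=scores.get)
        assert best_mask[0]                        # oracle: column 0 wins
        res = select_features(
            X, y, SelectionConfig(population=6, gwo_iterations=10,
                                  jaya_iterations=5), seed=1)
        assert res.mask[0]

    def test_mask_fitness_in_top_decile_of_bruteforce(self):
        """On d=4 the found mask must rank among the best of all 15 masks."""
        ranks = []
        for seed in range(3):
            fm, lv = bf.make_feature_dataset(120, 3, 2, 1, 1, 2.5, seed=seed)
            X = fm.values
            all_fit = {}
            for bits in itertools.product([0, 1], repeat=4):
                if not any(bits):
                    continue
                all_fit[bits] = bf.elm_fitness(X, lv.labels,
                                               np.array(bits, bool),
                                               seed=seed)
            res = select_features(X, lv.labels,
                                  SelectionConfig(6, 10, 10), seed=seed)
            found = bf.elm_fitness(X, lv.labels, res.mask, seed=seed)
            better = sum(v > found + 1e-12 for v in all_fit.values())
            ranks.append(better / len(all_fit))
        assert np.median(ranks) <= 0.10

    def test_seed_reproducibility(self, feature_data):
        fm, lv = feature_data
        cfg = SelectionConfig(8, 6, 4)
        r1 = select_features(fm, lv, cfg, seed=5)
        r2 = select_features(fm, lv, cfg, seed=5)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.fitness_trace == r2.fitness_trace


def test_sklearn_selector_api(feature_data):
    fm, lv = feature_data
    sel = GreyWolfJayaSelector(population=8, gwo_iterations=6,
                               jaya_iterations=4, random_state=0)
    sel.fit(fm.values, lv.labels)
    Xt = sel.transform(fm.values)
    assert Xt.shape == (300, sel.result_.n_selected)
    np.testing.assert_array_equal(sel.get_support(), sel.result_.mask)
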