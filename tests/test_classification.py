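"""Preset classifiers, confusion-matrix metrics, and protocols."""

import numpy as np
import pytest

import brainfuse as bf
from brainfuse.classification import (compute_metrics, evaluate_classifier,
                                      make_classifier_preset)


class TestPresets:
    @pytest.mark.parametrize("name,layout", [
        ("narrow", [10]), ("medium", [25]), ("wide", [100]),
        ("bilayered", [10, 10]), ("trilayered", [10, 10, 10]),
    ])
    def test_layouts(self, name, layout):
        spec = make_classifier_preset(name)
        assert spec.hidden_layout == layout
        assert spec.activation == "relu"

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_classifier_preset("mlp7")


def brute_force_metrics(y_true, y_pred, k):
    """Per-pair counting oracle for TP/FP/FN/TN and derived rates."""
    out = {}
    for c in range(k):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        sens = 100 * tp / (tp + fn) if tp + fn else 0.0
        prec = 100 * tp / (tp + fp) if tp + fp else 0.0
        out[c] = (sens, prec, 100 - sens)
    acc = 100 * sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    return out, acc


class TestComputeMetrics:
    def test_binary_hand_example(self):
        """TP=9 FN=1 FP=2 TN=8: sens 90, prec 81.81, FNR 10, acc 85."""
        cm = np.array([[9, 1], [2, 8]])
        rep = compute_metrics(cm)
        assert rep.per_class["sensitivity"][0] == pytest.approx(90.0)
        assert rep.per_class["precision"][0] == pytest.approx(81.8181818,
                                                              abs=1e-4)
        assert rep.per_class["fnr"][0] == pytest.approx(10.0)
        assert rep.accuracy == pytest.approx(85.0)

    def test_diagonal_matrix_is_perfect(self):
        rep = compute_metrics(np.diag([5, 3, 7]))
        assert rep.accuracy == 100.0
        assert rep.fnr == 0.0
        assert rep.sensitivity == 100.0

    def test_fnr_complements_sensitivity(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, size=(4, 4))
            cm[np.diag_indices(4)] += 1            # avoid empty rows
            rep = compute_metrics(cm)
            np.testing.assert_allclose(
                rep.per_class["fnr"] + rep.per_class["sensitivity"], 100.0)
            assert rep.fnr == pytest.approx(100.0 - rep.sensitivity)

    def test_matches_counting_oracle_on_random_vectors(self, rng):
        from sklearn.metrics import confusion_matrix

        for _ in range(200):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            cm = confusion_matrix(y_true, y_pred, labels=range(k))
            rep = compute_metrics(cm)
            oracle, acc = brute_force_metrics(y_true, y_pred, k)
            assert rep.accuracy == pytest.approx(acc)
            for c in range(k):
                assert rep.per_class["sensitivity"][c] == pytest.approx(
                    oracle[c][0])
                assert rep.per_class["precision"][c] == pytest.approx(
                    oracle[c][1])

    def test_invariant_to_class_permutation(self, rng):
        cm = rng.integers(1, 20, size=(4, 4))
        perm = rng.permutation(4)
        a = compute_metrics(cm)
        b = compute_metrics(cm[np.ix_(perm, perm)])
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.precision == pytest.approx(b.precision)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            compute_metrics(np.empty((0, 0)))
        with pytest.raises(ValueError):
            compute_metrics(np.array([[1, -1], [0, 1]]))


class TestAuc:
    def test_perfect_and_constant_scorers(self):
        from brainfuse.classification import _macro_auc

        y = np.array([0, 0, 1, 1])
        perfect = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        constant = np.full((4, 2), 0.5)
        assert _macro_auc(y, perfect, np.array([0, 1])) == pytest.approx(1.0)
        assert _macro_auc(y, constant, np.array([0, 1])) == pytest.approx(0.5)


class TestEvaluateClassifier:
    def test_separable_features_reach_high_accuracy(self):
        fm, lv = bf.make_feature_dataset(200, 4, 5, 0, 5, 6.0, seed=1)
        spec = make_classifier_preset("wide")
        rep = evaluate_classifier(fm, lv, spec, protocol="holdout:0.5",
                                  seed=1)
        assert rep.accuracy >= 95.0
        assert rep.auc > 0.99
        assert rep.confusion.sum() == 100          # the held-out half

    def test_leave_one_out_on_twelve_samples(self):
        fm, lv = bf.make_feature_dataset(12, 3, 2, 0, 1, 4.0, seed=0)
        spec = make_classifier_preset("narrow", max_iterations=150)
        rep = evaluate_classifier(fm, lv, spec, protocol={"k_folds": 12},
                                  seed=0)
        assert rep.confusion.sum() == 12
        assert 0.0 <= rep.accuracy <= 100.0

    def test_kfold_pools_all_samples(self):
        fm, lv = bf.make_feature_dataset(60, 3, 3, 0, 2, 4.0, seed=2)
        spec = make_classifier_preset("narrow", max_iterations=150)
        rep = evaluate_classifier(fm, lv, spec, protocol="kfold:5", seed=2)
        assert rep.confusion.sum() == 60

    def test_invalid_protocol_rejected(self):
        fm, lv = bf.make_feature_dataset(30, 3, 2, 0, 1, 3.0, seed=0)
        with pytest.raises(ValueError):
            evaluate_classifier(fm, lv, make_classifier_preset("narrow"),
                                protocol="bootstrap:10")
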