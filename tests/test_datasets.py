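"""Synthetic generators and slice-accounting arithmetic."""

import itertools

import numpy as np
import pytest

import brainfuse as bf
from brainfuse.datasets import (load_features, load_image_dataset,
                                make_feature_dataset, make_modality_images,
                                plan_slice_selection, save_features,
                                save_image_dataset)


class TestSliceAccounting:
    @pytest.mark.parametrize("n_patients,lo,hi,n_mod,per_class,total", [
        (369, 40, 114, 4, 27675, 110700),   # full-cohort accounting
        (1, 40, 114, 1, 75, 75),
        (10, 1, 155, 4, 1550, 6200),
    ])
    def test_counts(self, n_patients, lo, hi, n_mod, per_class, total):
        sc = plan_slice_selection(n_patients, lo, hi, n_mod)
        assert sc.per_class == per_class
        assert sc.total == total
        assert sc.slice_range == (lo, hi)

    def test_matches_bruteforce_enumeration(self):
        n_p, lo, hi, n_m = 7, 3, 11, 4
        tuples = {(p, s, m) for p, s, m in itertools.product(
            range(n_p), range(lo, hi + 1), range(n_m))}
        sc = plan_slice_selection(n_p, lo, hi, n_m)
        assert sc.total == len(tuples)
        assert sc.per_class == len(tuples) // n_m

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            plan_slice_selection(10, 20, 5, 4)


class TestFeatureGenerator:
    def test_shape_balance_and_tags(self):
        fm, lv = make_feature_dataset(200, 4, 5, 5, 40, 3.0, seed=7)
        assert fm.values.shape == (200, 50)
        counts = np.bincount(lv.labels)
        assert counts.max() - counts.min() <= 1
        assert sum(n.startswith("inf_") for n in fm.feature_names) == 5
        assert sum(n.startswith("red_") for n in fm.feature_names) == 5
        assert sum(n.startswith("noise_") for n in fm.feature_names) == 40

    def test_seed_determinism(self):
        a, _ = make_feature_dataset(100, 3, 4, 2, 6, 2.0, seed=11)
        b, _ = make_feature_dataset(100, 3, 4, 2, 6, 2.0, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_class_separation_matches_request(self):
        fm, lv = make_feature_dataset(4000, 4, 5, 0, 0, 3.0, seed=0)
        means = np.array([fm.values[lv.labels == k].mean(axis=0)
                          for k in range(4)])
        dists = [np.linalg.norm(means[i] - means[j])
                 for i in range(4) for j in range(i + 1, 4)]
        assert np.allclose(dists, 3.0, atol=0.25)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_feature_dataset(100, 4, 0, 5, 5)
        with pytest.raises(ValueError):
            make_feature_dataset(5, 4, 3, 0, 0)

    def test_signal_monotone_in_separation(self):
        """ELM hold-out accuracy grows with the class separation."""
        mean_acc = []
        for sep in (0.0, 1.0, 3.0):
            accs = [bf.elm_fitness(*make_feature_dataset(
                160, 4, 3, 0, 5, sep, seed=s), seed=s) for s in range(10)]
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] <= mean_acc[1] <= mean_acc[2]
        assert mean_acc[2] > 0.6               # well above 0.25 chance

    def test_no_signal_null_is_chance(self):
        """With zero separation the ELM sits at chance level 1/K."""
        accs = [bf.elm_fitness(*make_feature_dataset(
            160, 4, 3, 0, 5, 0.0, seed=s), seed=s) for s in range(20)]
        # binomial error of the mean over 20 seeds x 48 held-out samples
        se = np.sqrt(0.25 * 0.75 / (20 * 48))
        assert abs(np.mean(accs) - 0.25) < 6 * se + 0.01


class TestImageGenerator:
    def test_contract(self):
        ds = make_modality_images(10, 32, 32, seed=1)
        assert ds.images.shape == (40, 32, 32, 1)
        assert ds.images.min() >= 0 and ds.images.max() <= 1
        assert np.bincount(ds.labels.labels).tolist() == [10] * 4

    def test_class_means_differ(self):
        ds = make_modality_images(10, 32, 32, seed=1)
        means = [ds.images[ds.labels.labels == k].mean(axis=0)
                 for k in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.linalg.norm(means[i] - means[j]) > 0.5

    def test_determinism_and_size_guard(self):
        a = make_modality_images(3, 32, 32, seed=5)
        b = make_modality_images(3, 32, 32, seed=5)
        np.testing.assert_array_equal(a.images, b.images)
        with pytest.raises(ValueError):
            make_modality_images(3, 8, 8)


class TestSerialisation:
    def test_feature_csv_roundtrip(self, tmp_path):
        fm, lv = make_feature_dataset(30, 3, 2, 1, 2, 2.0, seed=3)
        path = tmp_path / "feats.csv"
        save_features(fm, lv, path)
        fm2, lv2 = load_features(path)
        np.testing.assert_allclose(fm.values, fm2.values)
        np.testing.assert_array_equal(lv.labels, lv2.labels)
        assert fm2.feature_names == fm.feature_names

    def test_image_png_roundtrip(self, tmp_path):
        ds = make_modality_images(2, 32, 32, seed=2)
        save_image_dataset(ds, tmp_path / "imgs")
        ds2 = load_image_dataset(tmp_path / "imgs")
        assert ds2.images.shape == ds.images.shape
        # 8-bit quantisation only
        assert np.abs(ds.images - ds2.images).max() <= 1 / 255 + 1e-9
        np.testing.assert_array_equal(np.sort(ds.labels.labels),
                                      np.sort(ds2.labels.labels))
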