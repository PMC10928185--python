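"""Structural contracts of the two builders, audited by an independent
spec walker, plus the autoencoder layer/loss primitives."""

import numpy as np
import pytest

from brainfuse.architectures import (audit_spec, build_modified_resnet50,
                                     build_stacked_autoencoder,
                                     sae_layer_forward)
from brainfuse.nn.training import TrainConfig, sae_loss


class TestModifiedResNet50:
    def test_default_gap_width_is_1024(self):
        spec = build_modified_resnet50((224, 224, 3), 4, 1.0)
        assert spec.tap_width("gap") == 1024

    def test_three_added_blocks_of_four_stride1_convs(self):
        spec = build_modified_resnet50((224, 224, 3), 4, 1.0)
        audit = audit_spec(spec)
        assert len(audit["added_blocks"]) == 3
        assert set(audit["convs_per_added_block"].values()) == {4}
        assert audit["added_strides"] == [1]
        for kernels in audit["added_kernels"].values():
            assert kernels == [1, 3, 1, 3]

    def test_extra_conv_after_first_added_block(self):
        spec = build_modified_resnet50((64, 64, 3), 4, 0.5)
        names = [ls.name for ls in spec.layers]
        i_block1 = names.index("added1_relu")
        i_extra = names.index("post_added1_conv")
        i_block2 = names.index("added2_conv1")
        assert i_block1 < i_extra < i_block2
        extra = spec.get("post_added1_conv")
        assert extra.attrs["kernel"] == 3 and extra.attrs["stride"] == 1

    @pytest.mark.parametrize("scale,width", [(1.0, 1024), (0.5, 512),
                                             (0.25, 256)])
    def test_gap_width_scales(self, scale, width):
        spec = build_modified_resnet50((64, 64, 3), 4, scale)
        assert spec.tap_width("gap") == width

    def test_parameter_count_monotone_in_width(self):
        counts = [build_modified_resnet50((64, 64, 3), 4, s).count_parameters()
                  for s in (0.1, 0.25, 0.5, 1.0)]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_backbone_is_resnet50_depth(self):
        """1 stem + 16 bottleneck blocks x 3 convs = 49 backbone convs."""
        spec = build_modified_resnet50((224, 224, 3), 4, 1.0)
        backbone = [ls for ls in spec.layers if ls.kind == "conv"
                    and ls.attrs.get("role") in ("stem", "backbone")
                    and not ls.attrs.get("projection")]
        assert len(backbone) == 49

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_modified_resnet50((16, 16, 3), 4, 1.0)
        with pytest.raises(ValueError):
            build_modified_resnet50((64, 64, 3), 4, -1.0)


class TestStackedAutoencoder:
    def test_default_tap_width_is_1236(self):
        spec = build_stacked_autoencoder((32, 32, 1))
        assert spec.tap_width("decoder_conv_last") == 1236

    def test_five_plus_five_conv_layers(self):
        audit = audit_spec(build_stacked_autoencoder((32, 32, 1)))
        assert audit["encoder_convs"] == 5
        assert audit["decoder_convs"] == 5

    def test_bottleneck_widths(self):
        spec = build_stacked_autoencoder((32, 32, 1))
        assert spec.get("ae1_dense").attrs["out_dim"] == 100
        assert spec.get("ae2_dense").attrs["out_dim"] == 50

    def test_reconstruction_shape_equals_input(self):
        spec = build_stacked_autoencoder((32, 32, 1))
        assert spec.layers[-1].out_shape == (1, 32, 32)

    def test_unreachable_pooling_plan_rejected(self):
        with pytest.raises(ValueError):
            build_stacked_autoencoder((48, 48, 1))   # not 5x halvable
        with pytest.raises(ValueError):
            build_stacked_autoencoder((32, 32, 1), bottlenecks=())


class TestSaeLayerForward:
    def test_identity_map(self):
        x = np.array([1.5, -2.0, 0.5])
        out = sae_layer_forward(x, np.eye(3), np.zeros(3), "linear")
        np.testing.assert_allclose(out, x)

    def test_hand_computed_sigmoid(self):
        out = sae_layer_forward([1.0, -1.0], [[1.0, 1.0]], [0.5], "sigmoid")
        np.testing.assert_allclose(out, [1 / (1 + np.exp(-0.5))], atol=1e-4)
        assert abs(out[0] - 0.6225) < 1e-3

    def test_relu_clamps_negative_preactivations(self):
        out = sae_layer_forward([1.0, 1.0], [[-1.0, -2.0], [-0.5, -0.1]],
                                [0.0, 0.0], "relu")
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sae_layer_forward([1.0, 2.0], [[1.0]], [0.0])


class TestSaeLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 6))
        assert sae_loss(x, x) == 0.0

    def test_hand_computed_value(self):
        assert sae_loss(np.array([[2.0]]), np.array([[0.0]])) == 2.0

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 5))
        r = rng.normal(size=(3, 5))
        assert sae_loss(x, x + 2 * r) == pytest.approx(4 * sae_loss(x, x + r))

    def test_matches_elementwise_bruteforce(self, rng):
        for _ in range(5):
            x = rng.normal(size=(7, 11))
            y = rng.normal(size=(7, 11))
            brute = sum((x[i, j] - y[i, j]) ** 2
                        for i in range(7) for j in range(11)) / (2 * 7)
            assert sae_loss(x, y) == pytest.approx(brute, rel=1e-12)

    def test_regularisers_add_penalties(self):
        x = np.ones((2, 3))
        w = [np.full((2, 2), 2.0)]
        cfg = TrainConfig(l2_weight=0.1, sparsity_reg=0.0)
        assert sae_loss(x, x, weights=w, cfg=cfg) == pytest.approx(0.1 * 16.0)
        cfg2 = TrainConfig(sparsity_reg=1.0, sparsity_prop=0.2)
        h = [np.full((2, 4), 0.2)]
        assert sae_loss(x, x, cfg=cfg2, hidden_activations=h) == pytest.approx(
            0.0, abs=1e-12)
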