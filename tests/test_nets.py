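"""Architecture contracts of the three subnetworks (desk-scale width)."""

import numpy as np
import pytest

from nodulecascade import nn
from nodulecascade.autodiff import Tensor, no_grad
from nodulecascade.nets import (BackboneSpec, ClassNetSpec, FineLayer,
                                build_backbone, build_classnet,
                                build_coarse_segnet, build_fine_segnet,
                                init_fourth_channel, load_checkpoint,
                                load_rgb_stem, save_checkpoint)

SPEC = BackboneSpec(width_multiplier=0.125, middle_repeats=2)
CSPEC = ClassNetSpec(width_multiplier=0.125, middle_repeats=2)


@pytest.fixture(scope="module")
def coarse():
    return build_coarse_segnet(SPEC, seed=0)


@pytest.fixture(scope="module")
def classnet():
    return build_classnet(CSPEC, seed=1)


class TestBackbone:
    def test_feature_strides(self):
        bb = build_backbone(SPEC, seed=0)
        with no_grad():
            deep, low = bb(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert deep.shape[2:] == (4, 4)    # stride 16
        assert low.shape[2:] == (16, 16)   # stride 4

    def test_output_stride_8_variant(self):
        bb = build_backbone(BackboneSpec(width_multiplier=0.125,
                                         middle_repeats=1, output_stride=8),
                            seed=0)
        with no_grad():
            deep, _ = bb(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert deep.shape[2:] == (8, 8)

    def test_invalid_output_stride_rejected(self):
        with pytest.raises(ValueError):
            BackboneSpec(output_stride=7)

    def test_no_pooling_layers_anywhere(self, coarse):
        """All down-sampling is via stride-2 separable convolutions."""
        names = [type(m).__name__.lower() for m in coarse.modules()]
        assert not any("maxpool" in n for n in names)
        strided = [m for m in coarse.modules()
                   if isinstance(m, nn.Conv2d) and m.stride == 2]
        assert strided, "expected stride-2 convolutions for down-sampling"
        # every stride-2 conv is either a depthwise stage of a separable
        # conv or a 1x1 residual projection — never a pooling surrogate
        for m in strided:
            assert m.groups == m.cin or m.kernel_size == 1 or m.cin == 3


class TestCoarseSegNet:
    def test_probability_map_contract(self, coarse, rng):
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        probs = coarse.predict(x)
        assert probs.shape == (2, 1, 64, 64)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_single_output_channel(self, coarse):
        assert coarse.head.cout == 1

    def test_inference_is_deterministic(self, coarse, rng):
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        assert np.array_equal(coarse.predict(x), coarse.predict(x))

    def test_shape_law_for_other_input_sizes(self, coarse):
        x = np.zeros((1, 3, 96, 96), np.float32)
        assert coarse.predict(x).shape == (1, 1, 96, 96)


class TestFineLayer:
    def test_fuses_mask_back_to_original_channels(self, rng):
        layer = FineLayer(8)
        layer.init_weights(np.random.default_rng(0))
        deep = Tensor(rng.random((2, 8, 4, 4)).astype(np.float32))
        mask = Tensor(rng.random((2, 1, 64, 64)).astype(np.float32))
        layer.eval()
        with no_grad():
            out = layer(deep, mask)
        assert out.shape == (2, 8, 4, 4)

    def test_concatenated_input_has_extra_channel(self):
        layer = FineLayer(8)
        conv = layer.fuse._seq[0]
        assert conv.cin == 9 and conv.cout == 8

    def test_misaligned_mask_rejected(self, rng):
        layer = FineLayer(8)
        layer.init_weights(np.random.default_rng(0))
        deep = Tensor(rng.random((1, 8, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            layer(deep, Tensor(np.zeros((1, 1, 62, 62), np.float32)))


class TestFineSegNet:
    def test_parameters_copied_bit_for_bit_at_init(self, coarse):
        fine = build_fine_segnet(SPEC, coarse, seed=123)
        shared = coarse.state_dict()
        fine_state = fine.state_dict()
        for name, value in shared.items():
            assert np.array_equal(fine_state[name], value), name

    def test_parameter_count_accounting(self, coarse):
        fine = build_fine_segnet(SPEC, coarse, seed=0)
        fine_layer_params = sum(p.size for p in fine.fine_layer.parameters())
        assert fine.num_parameters() == coarse.num_parameters() + fine_layer_params

    def test_divergence_after_training_step(self, coarse, rng):
        fine = build_fine_segnet(SPEC, coarse, seed=0)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        mask = rng.random((2, 1, 64, 64)).astype(np.float32)
        fine.train()
        out = fine(Tensor(x), Tensor(mask))
        (out ** 2).mean().backward()
        nn.Adam(fine.parameters(), lr=1e-2).step()
        shared = coarse.state_dict()
        fine_state = fine.state_dict()
        assert any(not np.array_equal(fine_state[n], shared[n]) for n in shared)

    def test_forward_contract(self, coarse, rng):
        fine = build_fine_segnet(SPEC, coarse, seed=0)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        mask = rng.random((2, 1, 64, 64)).astype(np.float32)
        out = fine.predict(x, mask)
        assert out.shape == (2, 1, 64, 64)
        assert out.min() >= 0 and out.max() <= 1

    def test_spec_mismatch_rejected(self, coarse):
        other = BackboneSpec(width_multiplier=0.25, middle_repeats=2)
        with pytest.raises(ValueError):
            build_fine_segnet(other, coarse)

    def test_fresh_init_must_be_explicit(self):
        with pytest.raises(ValueError):
            build_fine_segnet(SPEC, None)
        fine = build_fine_segnet(SPEC, None, allow_fresh_init=True)
        assert fine.num_parameters() > 0


class TestClassNet:
    def test_score_contract(self, classnet, rng):
        x = rng.random((3, 4, 64, 64)).astype(np.float32)
        scores = classnet.predict(x)
        assert scores.shape == (3,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_exit_flow_keeps_stride_16_resolution(self, classnet):
        with no_grad():
            feat = classnet.features(np.zeros((1, 4, 64, 64), np.float32))
        # removing the final down-sampling stage leaves 64/16 = 4, twice
        # the 64/32 = 2 of the unmodified topology
        assert feat.shape[2:] == (4, 4)
        undilated = build_classnet(
            ClassNetSpec(width_multiplier=0.125, middle_repeats=2,
                         dilated_exit=False), seed=0)
        with no_grad():
            feat_u = undilated.features(np.zeros((1, 4, 64, 64), np.float32))
        assert feat_u.shape[2] * 2 == feat.shape[2]

    def test_last_two_separable_convs_are_dilated(self, classnet):
        for stage in (classnet.exit_sep1, classnet.exit_sep2):
            dw = stage._seq[0].depthwise
            assert dw.dilation == 2 and dw.padding == 2

    def test_input_channel_toggle(self):
        c3 = build_classnet(ClassNetSpec(input_channels=3,
                                         width_multiplier=0.125,
                                         middle_repeats=1), seed=0)
        assert c3.stem1._seq[0].cin == 3
        c4 = build_classnet(ClassNetSpec(input_channels=4,
                                         width_multiplier=0.125,
                                         middle_repeats=1), seed=0)
        assert c4.stem1._seq[0].cin == 4


class TestFourthChannelInit:
    def test_constant_kernels_replicate(self):
        w = np.ones((2, 3, 3, 3), np.float32)
        assert np.array_equal(init_fourth_channel(w)[:, 3], w[:, 0])

    def test_arithmetic_mean_of_channels(self):
        w = np.zeros((1, 3, 1, 1), np.float32)
        w[0, :, 0, 0] = [1.0, 2.0, 3.0]
        assert init_fourth_channel(w)[0, 3, 0, 0] == pytest.approx(2.0)

    def test_random_kernels_match_mean_oracle(self, rng):
        w = rng.normal(size=(5, 3, 3, 3))
        out = init_fourth_channel(w)
        assert np.abs(out[:, 3] - w.mean(axis=1)).max() < 1e-12
        assert np.array_equal(out[:, :3], w)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            init_fourth_channel(np.zeros((2, 4, 3, 3)))

    def test_classnet_mask_channel_is_rgb_mean_at_build(self, classnet):
        w = classnet.stem1._seq[0].weight.data
        assert np.allclose(w[:, 3], w[:, :3].mean(axis=1), atol=1e-7)

    def test_rgb_reference_weights_load_preserving_rgb(self, classnet, rng):
        rgb = rng.normal(size=(8, 3, 3, 3)).astype(np.float32)
        load_rgb_stem(classnet, rgb)
        w = classnet.stem1._seq[0].weight.data
        assert np.array_equal(w[:, :3], rgb)
        assert np.allclose(w[:, 3], rgb.mean(axis=1), atol=1e-7)


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, coarse, tmp_path, rng):
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        before = coarse.predict(x)
        path = tmp_path / "coarse.npz"
        save_checkpoint(path, coarse, meta={"note": "test"})
        model, meta = load_checkpoint(path)
        assert meta["note"] == "test"
        assert np.array_equal(model.predict(x), before)

    def test_spec_mismatch_refused(self, coarse, tmp_path):
        path = tmp_path / "coarse.npz"
        save_checkpoint(path, coarse)
        with pytest.raises(ValueError):
            load_checkpoint(path, expected_spec=BackboneSpec(
                width_multiplier=0.5, middle_repeats=2))

    def test_classnet_round_trip(self, classnet, tmp_path, rng):
        x = rng.random((2, 4, 64, 64)).astype(np.float32)
        path = tmp_path / "cls.npz"
        save_checkpoint(path, classnet)
        model, _ = load_checkpoint(path, expected_spec=CSPEC)
        assert np.array_equal(model.predict(x), classnet.predict(x))


def test_forward_backward_speed_at_desk_width():
    """A width-0.125 model must run a forward/backward batch of 4 at
    64 x 64 fast enough for desk-scale training (well under a second)."""
    import time
    model = build_coarse_segnet(SPEC, seed=0)
    x = np.random.default_rng(0).random((4, 3, 64, 64), dtype=np.float32)
    out = model(Tensor(x))  # warm-up
    t0 = time.time()
    out = model(Tensor(x))
    (out ** 2).mean().backward()
    assert time.time() - t0 < 1.0
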