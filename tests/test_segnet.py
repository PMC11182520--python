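"""Architecture contracts and perturbations of the segmentation network."""

import numpy as np
import pytest

import refineseg.nn as nn
from refineseg import (NetConfig, SegmentationNet, perturb_feature_drop,
                       perturb_noise)
from refineseg.segnet import PhiBlock


def conv_params(cin, cout, k, bn=True):
    """Independent count: conv weights+bias, optionally BN gamma+beta."""
    n = cin * cout * k * k + cout
    if bn:
        n += 2 * cout
    return n


def expected_segmentation_params(base, depth, n_classes):
    """Layer-by-layer enumeration of encoder + three decoders."""
    chans = [base * 2 ** i for i in range(depth)]
    total = 0
    prev = 1
    for c in chans:                       # encoder: two Phi blocks per stage
        total += conv_params(prev, c, 3) + conv_params(c, c, 3)
        prev = c
    decoder = 0
    for i in range(1, depth):             # per decoder: up, concat, 2 Phi
        skip = chans[depth - 1 - i]
        decoder += conv_params(chans[depth - i] + skip, skip, 3)
        decoder += conv_params(skip, skip, 3)
    decoder += conv_params(chans[0], n_classes, 1, bn=False)
    return total + 3 * decoder


class TestPhiBlock:
    def test_relu_and_shape_contract(self):
        rng = np.random.default_rng(0)
        block = PhiBlock(2, 5, rng)
        out = block(nn.Tensor(rng.normal(size=(1, 2, 6, 7))))
        assert out.shape == (1, 5, 6, 7)
        assert out.data.min() >= 0.0

    def test_zero_input_gives_zero_output_in_train_mode(self):
        """Zero input -> zero convolution (bias starts at 0) -> BN of a
        constant map is zero -> ReLU output is exactly zero."""
        block = PhiBlock(1, 3, np.random.default_rng(1))
        out = block(nn.Tensor(np.zeros((1, 1, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)


class TestEncoder:
    def test_stage_shapes_and_channels(self):
        cfg = NetConfig(n_classes=3, base_channels=8, depth=5, seed=0)
        net = SegmentationNet(cfg)
        pyramid = net.encode(nn.Tensor(np.zeros((1, 1, 64, 64),
                                                dtype=np.float32)))
        sizes = [f.shape[2] for f in pyramid]
        channels = [f.shape[1] for f in pyramid]
        assert sizes == [64, 32, 16, 8, 4]
        assert channels == [8, 16, 32, 64, 128]

    def test_depth2_pools_once(self):
        cfg = NetConfig(base_channels=2, depth=2, seed=0)
        net = SegmentationNet(cfg, use_aux1=False, use_aux2=False)
        pyramid = net.encode(nn.Tensor(np.zeros((1, 1, 16, 16),
                                                dtype=np.float32)))
        assert [f.shape[2] for f in pyramid] == [16, 8]

    def test_indivisible_size_rejected(self):
        cfg = NetConfig(base_channels=2, depth=4, seed=0)
        net = SegmentationNet(cfg, use_aux1=False, use_aux2=False)
        with pytest.raises(ValueError, match="divisible"):
            net.encode(nn.Tensor(np.zeros((1, 1, 20, 20), dtype=np.float32)))

    def test_eval_mode_deterministic(self):
        cfg = NetConfig(base_channels=2, depth=3, seed=0)
        net = SegmentationNet(cfg, use_aux1=False, use_aux2=False)
        net.eval()
        x = nn.Tensor(np.random.default_rng(0)
                      .random((1, 1, 16, 16)).astype(np.float32))
        with nn.no_grad():
            a = net.encode(x)
            b = net.encode(x)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.data, fb.data)


class TestFeatureDrop:
    def test_dropped_fraction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4, 8, 8))
        out = perturb_feature_drop(x, rate=0.25, seed=1)
        zeroed = np.all(out == 0, axis=1).sum()
        assert abs(zeroed - 0.25 * 64) <= 1

    def test_hot_position_dropped_first(self):
        x = np.ones((1, 2, 4, 4))
        x[0, :, 2, 3] = 10.0             # single high-activation position
        out = perturb_feature_drop(x, rate=1 / 16, seed=0)
        assert np.all(out[0, :, 2, 3] == 0)
        assert np.count_nonzero(np.all(out == 0, axis=1)) == 1

    def test_constant_map_drops_seeded_random_subset(self):
        x = np.ones((1, 3, 6, 6))
        a = perturb_feature_drop(x, rate=0.5, seed=3)
        b = perturb_feature_drop(x, rate=0.5, seed=3)
        c = perturb_feature_drop(x, rate=0.5, seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all((a == 0) | (a == 1))

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            perturb_feature_drop(np.zeros((1, 1, 4, 4)), rate=0.0, seed=0)


class TestNoise:
    def test_zero_amplitude_is_identity(self):
        x = np.random.default_rng(1).normal(size=(1, 2, 4, 4))
        for kind in ("uniform", "gaussian"):
            out = perturb_noise(x, kind, amplitude=0.0, seed=0)
            np.testing.assert_array_equal(out, x)

    def test_uniform_noise_bounded(self):
        x = np.random.default_rng(2).normal(size=(1, 2, 8, 8))
        out = perturb_noise(x, "uniform", amplitude=0.3, seed=5)
        assert np.all(np.abs(out - x) <= 0.3 * np.abs(x) + 1e-12)

    def test_noise_mean_zero_monte_carlo(self):
        """Empirical mean of the perturbation over many seeds vanishes
        within 3 standard errors."""
        x = np.full((1, 1, 4, 4), 2.0)
        for kind, se_scale in (("uniform", 2.0 * 0.3 / np.sqrt(3)),
                               ("gaussian", 0.0)):
            diffs = np.concatenate([
                (perturb_noise(x, kind, 0.3, seed=s) - x).ravel()
                for s in range(400)])
            if kind == "uniform":
                se = se_scale / np.sqrt(diffs.size)
                assert abs(diffs.mean()) < 3 * se
            else:                         # sd(x)=0 for a constant map
                assert np.all(diffs == 0)

    def test_gaussian_scales_with_feature_sd(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 4.0, size=(1, 2, 16, 16))
        out = perturb_noise(x, "gaussian", amplitude=0.5, seed=7)
        # expected noise sd = amplitude * sd(x); allow sampling slack
        assert (out - x).std() == pytest.approx(0.5 * x.std(), rel=0.25)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(4).normal(size=(1, 2, 4, 4))
        a = perturb_noise(x, "uniform", 0.3, seed=11)
        b = perturb_noise(x, "uniform", 0.3, seed=11)
        np.testing.assert_array_equal(a, b)


class TestDecodeAndSegment:
    def test_output_shape_and_channels(self):
        cfg = NetConfig(n_classes=4, base_channels=2, depth=3, seed=0)
        net = SegmentationNet(cfg, use_aux1=False, use_aux2=False)
        x = nn.Tensor(np.random.default_rng(0)
                      .random((1, 1, 16, 16)).astype(np.float32))
        main, _, _ = net.segment(x, perturb=False)
        assert main.shape == (1, 4, 16, 16)

    def test_parameter_count_matches_enumeration(self):
        cfg = NetConfig(n_classes=3, base_channels=8, depth=5, seed=0)
        net = SegmentationNet(cfg)
        assert net.n_parameters() == expected_segmentation_params(8, 5, 3)

    def test_parameter_count_small_config(self):
        cfg = NetConfig(n_classes=2, base_channels=4, depth=3, seed=0)
        net = SegmentationNet(cfg)
        assert net.n_parameters() == expected_segmentation_params(4, 3, 2)

    def test_masks_are_softmax_normalised(self):
        cfg = NetConfig(base_channels=2, depth=3, seed=0)
        net = SegmentationNet(cfg)
        x = nn.Tensor(np.random.default_rng(1)
                      .random((2, 1, 16, 16)).astype(np.float32))
        for mask in net.segment(x, perturb=True, seed=0):
            np.testing.assert_allclose(mask.data.sum(axis=1), 1.0,
                                       atol=1e-5)
            assert mask.data.min() >= 0

    def test_identical_decoder_weights_and_no_perturbation_agree(self):
        """With shared weights and perturbations off, the three decoders
        are exactly the same function."""
        cfg = NetConfig(base_channels=2, depth=3, seed=0)
        net = SegmentationNet(cfg)
        state = net.dec_main.state_dict()
        net.dec_aux1.load_state_dict(state)
        net.dec_aux2.load_state_dict(state)
        x = nn.Tensor(np.random.default_rng(2)
                      .random((1, 1, 16, 16)).astype(np.float32))
        main, aux1, aux2 = net.segment(x, perturb=False)
        np.testing.assert_array_equal(main.data, aux1.data)
        np.testing.assert_array_equal(main.data, aux2.data)

    def test_gradients_reach_encoder_and_all_decoders(self):
        from refineseg.losses import total_loss
        cfg = NetConfig(base_channels=2, depth=3, seed=0)
        net = SegmentationNet(cfg)
        x = nn.Tensor(np.random.default_rng(3)
                      .random((1, 1, 16, 16)).astype(np.float32))
        gt = np.random.default_rng(4).integers(0, 3, (1, 16, 16))
        main, aux1, aux2 = net.segment(x, perturb=True, seed=0)
        loss = total_loss(gt, main, aux1, aux2)
        loss.total.backward()
        for part in (net.encoder, net.dec_main, net.dec_aux1, net.dec_aux2):
            grads = [p.grad for p in part.parameters()]
            assert all(g is not None for g in grads)
            assert any(np.abs(g).max() > 0 for g in grads)
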