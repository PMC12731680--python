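"""Network engine: blocks, attention, parameter counts, inference."""

import numpy as np
import pytest

from crackspec.band_selection import BandSubset
from crackspec.core import SpectralCube, WavelengthGrid
from crackspec.errors import ParameterError
from crackspec.nn import (Conv3d, NetworkConfig, ResBlock3d, SimAM3d, UNet3D,
                          build_model, count_trainable_parameters,
                          load_checkpoint, predict_mask, save_checkpoint,
                          simam_energy)
from crackspec.train_eval import focal_dice_loss

SMALL_CFG = NetworkConfig(in_bands=5, encoder_units=2, base_channels=3)


def _identity_bn(bn):
    bn.gamma.data[...] = 1.0
    bn.beta.data[...] = 0.0
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps


class TestResBlock:
    def test_zero_main_branch_reduces_to_relu(self, rng):
        block = ResBlock3d(4, 4, rng=np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        _identity_bn(block.bn1)
        _identity_bn(block.bn2)
        x = rng.standard_normal((2, 4, 3, 6, 6)).astype(np.float32)
        out = block.forward(x, training=False)
        np.testing.assert_allclose(out, np.maximum(x, 0), atol=1e-5)

    def test_zero_input_zero_output(self):
        block = ResBlock3d(3, 3, rng=np.random.default_rng(1))
        x = np.zeros((1, 3, 2, 4, 4), dtype=np.float32)
        out = block.forward(x, training=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_gradient_flows_through_shortcut(self, rng):
        block = ResBlock3d(2, 2, rng=np.random.default_rng(2))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
        x = np.abs(rng.standard_normal((1, 2, 2, 4, 4))).astype(np.float32)
        out = block.forward(x, training=True)
        gx = block.backward(np.ones_like(out))
        assert np.abs(gx).sum() > 0  # residual path keeps gradients alive

    def test_projection_when_channels_change(self, rng):
        block = ResBlock3d(2, 6, rng=np.random.default_rng(3))
        x = rng.standard_normal((1, 2, 3, 4, 4)).astype(np.float32)
        assert block.forward(x, training=False).shape == (1, 6, 3, 4, 4)


class TestSimAM:
    def test_zero_input_zero_output(self):
        layer = SimAM3d()
        x = np.zeros((1, 2, 2, 3, 3), dtype=np.float32)
        np.testing.assert_array_equal(layer.forward(x), 0)

    @pytest.mark.parametrize("variant", ["direct", "canonical"])
    def test_constant_channel_uniform_weights(self, variant):
        layer = SimAM3d(variant=variant)
        x = np.full((1, 1, 2, 3, 3), 1.7, dtype=np.float32)
        w = layer.attention_weights(x)
        assert np.allclose(w, w.flat[0])

    @pytest.mark.parametrize("variant", ["direct", "canonical"])
    def test_outlier_voxel_gets_strictly_largest_weight(self, variant):
        x = np.full((1, 1, 2, 3, 3), 0.5, dtype=np.float32)
        x[0, 0, 1, 2, 1] = 5.0
        # brute-force: evaluate the energy voxel by voxel
        e = simam_energy(x, variant=variant)[0, 0]
        flat = e.ravel()
        outlier_flat_index = np.ravel_multi_index((1, 2, 1), (2, 3, 3))
        assert np.argmax(flat) == outlier_flat_index
        w = SimAM3d(variant=variant).attention_weights(x)[0, 0].ravel()
        assert np.all(w[outlier_flat_index] > np.delete(w, outlier_flat_index))

    def test_parameter_free(self):
        assert count_trainable_parameters(SimAM3d()) == 0
        assert SimAM3d().parameters() == []

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ParameterError):
            SimAM3d(lam=0.0)

    def test_multiplicative_identity_when_weights_forced_to_one(self, rng):
        cfg = SMALL_CFG
        with_attn = UNet3D(cfg, seed=4, residual=True, use_simam=True)
        without = UNet3D(cfg, seed=4, residual=True, use_simam=False)
        for p, q in zip(with_attn.parameters(), without.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        for layer in with_attn.layers():
            if isinstance(layer, SimAM3d):
                layer.attention_weights = lambda x: np.ones_like(x)
        x = with_attn.prepare_input(
            rng.random((1, 8, 8, cfg.in_bands)).astype(np.float32))
        np.testing.assert_allclose(with_attn.forward(x), without.forward(x),
                                   atol=1e-6)


class TestParameterCounts:
    def test_single_conv_count_arithmetic(self):
        conv = Conv3d(1, 8, (3, 3, 3))
        assert count_trainable_parameters(conv) == 8 * 1 * 27 + 8

    def test_cracknet_minus_baseline_is_projection_only(self):
        cfg = NetworkConfig(in_bands=6, encoder_units=2, base_channels=4)
        crack = build_model("cracknet3d", cfg, seed=0)
        base = build_model("cnn3d", cfg, seed=0)
        diff = (count_trainable_parameters(crack)
                - count_trainable_parameters(base))
        expected = 0
        for block in (crack.enc_blocks + [crack.bottleneck]
                      + crack.dec_blocks):
            if block.proj is not None:
                expected += count_trainable_parameters(block.proj)
                expected += count_trainable_parameters(block.proj_bn)
        assert diff == expected


class TestBuildModel:
    def test_output_shape_and_range(self, rng):
        cfg = NetworkConfig(in_bands=15, encoder_units=3, base_channels=4)
        model = build_model("cracknet3d", cfg, seed=0)
        x = model.prepare_input(rng.random((1, 64, 64, 15)).astype(np.float32))
        prob = model.forward(x)
        assert prob.shape == (1, 64, 64)
        assert prob.min() >= 0 and prob.max() <= 1

    @pytest.mark.parametrize("kind", ["cracknet3d", "cnn3d", "cnn2d", "cnn1d"])
    def test_same_seed_same_weights(self, kind):
        a = build_model(kind, SMALL_CFG, seed=3)
        b = build_model(kind, SMALL_CFG, seed=3)
        for p, q in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            build_model("transformer", SMALL_CFG, seed=0)

    def test_cnn1d_spatially_permutation_invariant(self, rng):
        model = build_model("cnn1d", SMALL_CFG, seed=0)
        x = rng.random((1, 6, 6, SMALL_CFG.in_bands)).astype(np.float32)
        base = model.forward(model.prepare_input(x))
        perm = rng.permutation(36)
        flat = x.reshape(36, -1)[perm].reshape(1, 6, 6, -1)
        out = model.forward(model.prepare_input(flat))
        np.testing.assert_allclose(out.reshape(36)[np.argsort(perm)],
                                   base.reshape(36), atol=2e-5)

    def test_symmetric_output_dims_when_divisible(self, rng):
        cfg = NetworkConfig(in_bands=4, encoder_units=2, base_channels=3)
        model = build_model("cnn3d", cfg, seed=0)
        for size in (8, 12, 16):
            x = model.prepare_input(
                rng.random((1, size, size, 4)).astype(np.float32))
            assert model.forward(x).shape == (1, size, size)


class TestGradients:
    @pytest.mark.parametrize("kind", ["cnn3d", "cnn2d", "cnn1d"])
    def test_backward_matches_finite_differences(self, kind, rng):
        model = build_model(kind, SMALL_CFG, seed=1)
        x = model.prepare_input(rng.random((2, 8, 8, 5)).astype(np.float32))
        target = (rng.random((2, 8, 8)) > 0.8).astype(np.float32)

        def loss_of():
            prob = model.forward(x, training=True)
            return focal_dice_loss(prob, target, return_grad=True)

        _, grad = loss_of()
        model.zero_grad()
        model.backward(grad)
        params = model.parameters()
        for _ in range(6):
            p = params[rng.integers(len(params))]
            flat = p.data.ravel()
            i = rng.integers(flat.size)
            old, eps = flat[i], 1e-2
            flat[i] = old + eps
            lp, _ = loss_of()
            flat[i] = old - eps
            lm, _ = loss_of()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            # loose: ReLU/max-pool kinks make central differences noisy
            assert abs(num - ana) <= 0.2 * max(abs(num), abs(ana)) + 2e-3


class TestPredictMask:
    def _scene(self, rng, bands=5):
        grid = WavelengthGrid(np.linspace(1000, 2500, bands))
        data = rng.random((20, 24, bands), dtype=np.float32)
        return SpectralCube(data, grid)

    def test_threshold_extremes(self, rng):
        model = build_model("cracknet3d", SMALL_CFG, seed=0)
        cube = self._scene(rng)
        prob, ones = predict_mask(model, cube, threshold=0.0)
        assert np.array_equal(ones.labels, (prob > 0).astype(np.uint8))
        _, empty = predict_mask(model, cube, threshold=1.0)
        assert empty.crack_pixel_count == 0

    def test_tiled_equals_manual_stitching(self, rng):
        model = build_model("cracknet3d", SMALL_CFG, seed=0)
        grid = WavelengthGrid(np.linspace(1000, 2500, 5))
        cube = SpectralCube(rng.random((64, 64, 5), dtype=np.float32), grid)
        tiled_prob, _ = predict_mask(model, cube, tile=32)
        manual = np.zeros((64, 64), dtype=np.float32)
        for r in range(0, 64, 32):
            for c in range(0, 64, 32):
                part = SpectralCube(cube.data[r:r + 32, c:c + 32], grid)
                manual[r:r + 32, c:c + 32], _ = predict_mask(model, part)
        np.testing.assert_allclose(tiled_prob, manual, atol=1e-6)

    def test_band_mismatch_rejected(self, rng):
        model = build_model("cracknet3d", SMALL_CFG, seed=0)
        with pytest.raises(ParameterError, match="bands"):
            predict_mask(model, self._scene(rng, bands=7))

    def test_band_subset_applied_before_inference(self, rng):
        model = build_model("cracknet3d", SMALL_CFG, seed=0)
        cube = self._scene(rng, bands=9)
        subset = BandSubset(indices=np.arange(5))
        prob, mask = predict_mask(model, cube, subset=subset)
        assert prob.shape == mask.shape == (20, 24)


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_model("cracknet3d", SMALL_CFG, seed=2)
    model.input_mean, model.input_std = 0.4, 0.2
    subset = BandSubset(indices=[0, 2, 3, 4, 6], method="CARS")
    x = model.prepare_input(rng.random((1, 8, 8, 5)).astype(np.float32))
    before = model.forward(x)
    path = save_checkpoint(model, tmp_path / "model.ckpt", band_subset=subset)
    restored, sub, _ = load_checkpoint(path)
    np.testing.assert_allclose(restored.forward(x), before, atol=1e-7)
    np.testing.assert_array_equal(sub.indices, subset.indices)
    assert restored.input_std == pytest.approx(0.2)
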