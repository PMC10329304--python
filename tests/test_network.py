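"""Network assembly: embedding, stages, sampling layers, end-to-end forward."""

import numpy as np
import pytest

from vesselseg.network import (Downsample, IBSwinUNet3D, PatchEmbed, StageSpec,
                               TransformerBlock, TransformerStage, Upsample,
                               complexity_estimate, load_checkpoint,
                               save_checkpoint)
from vesselseg.nn import Tensor
from vesselseg.windowing import TokenGrid


def tiny_net(**kw):
    kw.setdefault("base_channels", 16)
    kw.setdefault("depths", (2,))
    kw.setdefault("window_size", (4, 4, 4))
    kw.setdefault("seed", 0)
    return IBSwinUNet3D(**kw)


class TestPatchEmbed:
    def test_paper_scale_shape(self):
        """128x128x96 volume embeds to a 32x32x24 grid of 128-channel tokens."""
        embed = PatchEmbed(128, np.random.default_rng(0))
        out = embed(Tensor(np.zeros((128, 128, 96, 1), dtype=np.float32)))
        assert out.tokens.shape == (32, 32, 24, 128)

    def test_tiny_shape(self):
        embed = PatchEmbed(16, np.random.default_rng(0))
        out = embed(Tensor(np.zeros((8, 8, 8, 1), dtype=np.float32)))
        assert out.tokens.shape == (2, 2, 2, 16)

    def test_deterministic(self, rng):
        embed = PatchEmbed(8, np.random.default_rng(1))
        x = Tensor(rng.normal(size=(8, 8, 8, 1)).astype(np.float32))
        assert np.array_equal(embed(x).tokens.data, embed(x).tokens.data)

    def test_indivisible_shape_rejected(self):
        embed = PatchEmbed(8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible"):
            embed(Tensor(np.zeros((9, 8, 8, 1), dtype=np.float32)))


class TestTransformerStage:
    def test_zeroed_projections_make_identity(self, rng):
        """With the attention output projection and second MLP layer zeroed,
        both residual branches vanish and the stage is the identity."""
        stage = TransformerStage(StageSpec(2, 16, 2, (2, 2, 2)),
                                 np.random.default_rng(0), dtype=np.float64)
        for blk in stage.blocks:
            blk.attn.proj.weight.data[:] = 0
            blk.attn.proj.bias.data[:] = 0
            blk.mlp.fc2.weight.data[:] = 0
            blk.mlp.fc2.bias.data[:] = 0
        g = TokenGrid(rng.normal(size=(4, 4, 4, 16)))
        out = stage(g)
        assert np.allclose(out.tokens.data, g.tokens.data)

    @pytest.mark.parametrize("shape", [(4, 4, 4), (8, 8, 6), (6, 6, 6)])
    def test_output_shape_equals_input(self, shape, rng):
        stage = TransformerStage(StageSpec(2, 16, 2, (4, 4, 4)),
                                 np.random.default_rng(0))
        g = TokenGrid(rng.normal(size=shape + (16,)).astype(np.float32))
        assert stage(g).spatial_shape == shape

    def test_stage_matches_stepwise_block_composition(self, rng):
        """Running the blocks by hand — LN, windowed attention, residual, LN,
        MLP, residual, twice — reproduces the stage output."""
        from vesselseg.windowing import (cyclic_shift, pad_to_multiple,
                                         partition_windows, reverse_windows)
        stage = TransformerStage(StageSpec(2, 16, 2, (2, 2, 2)),
                                 np.random.default_rng(3), dtype=np.float64)
        g = TokenGrid(rng.normal(size=(4, 4, 4, 16)))
        out = stage(g)

        x = g.tokens
        for blk in stage.blocks:
            h = pad_to_multiple(TokenGrid(blk.norm1(x)), blk.window_size)
            sh = cyclic_shift(h, blk.shift)
            ws = partition_windows(sh, blk.window_size, blk.shift)
            ws.windows = blk.attn(ws.windows, blk._mask((4, 4, 4)))
            h = cyclic_shift(reverse_windows(ws), blk.shift, inverse=True).tokens
            x = x + h
            x = x + blk.mlp(blk.norm2(x))
        assert np.allclose(out.tokens.data, x.data, atol=1e-12)

    def test_odd_depth_rejected(self):
        with pytest.raises(ValueError, match="even"):
            StageSpec(3, 16, 2, (2, 2, 2))


class TestSamplingLayers:
    def test_downsample_shape_contract(self, rng):
        g = TokenGrid(rng.normal(size=(8, 8, 6, 32)).astype(np.float32))
        out = Downsample(32, np.random.default_rng(0))(g)
        assert out.tokens.shape == (4, 4, 3, 64)

    def test_patch_merging_same_shapes(self, rng):
        g = TokenGrid(rng.normal(size=(8, 8, 6, 32)).astype(np.float32))
        out = Downsample(32, np.random.default_rng(0), mode="patch_merging")(g)
        assert out.tokens.shape == (4, 4, 3, 64)

    @pytest.mark.parametrize("mode", ["transposed_conv", "trilinear",
                                      "patch_expanding"])
    def test_upsample_shape_contract(self, mode, rng):
        g = TokenGrid(rng.normal(size=(4, 4, 3, 64)).astype(np.float32))
        out = Upsample(64, np.random.default_rng(0), mode=mode)(g)
        assert out.tokens.shape == (8, 8, 6, 32)

    def test_up_down_round_trip_shape(self, rng):
        g = TokenGrid(rng.normal(size=(8, 8, 8, 32)).astype(np.float32))
        down = Downsample(32, np.random.default_rng(0))(g)
        up = Upsample(64, np.random.default_rng(0))(down)
        assert up.tokens.shape == g.tokens.shape

    def test_trilinear_preserves_constant(self):
        g = TokenGrid(np.full((4, 4, 4, 8), 1.0, dtype=np.float64))
        up = Upsample(8, np.random.default_rng(0), mode="trilinear", dtype=np.float64)
        pre_norm = up.proj(g.tokens).data
        out = up(g)
        # before the layer norm, interpolation of a constant field is constant
        assert np.allclose(out.tokens.data.std(axis=(0, 1, 2)), 0, atol=1e-10)
        assert np.allclose(pre_norm.std(axis=(0, 1, 2)), 0, atol=1e-10)


class TestComplexity:
    def test_worked_example(self):
        assert complexity_estimate(4, 4, 4, 8, (4, 4, 4)) == 81920

    def test_single_token_window_specialization(self):
        h, w, d, c = 5, 6, 7, 12
        assert complexity_estimate(h, w, d, c, (1, 1, 1)) == \
            4 * h * w * d * c ** 2 + 2 * h * w * d * c

    def test_linear_in_grid_volume(self):
        a = complexity_estimate(4, 4, 4, 16, (4, 4, 4))
        b = complexity_estimate(8, 4, 4, 16, (4, 4, 4))
        assert b == 2 * a

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            complexity_estimate(0, 4, 4, 8, (4, 4, 4))


class TestForward:
    def test_probabilities_normalized_and_shaped(self, rng):
        net = tiny_net()
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        out = net.forward(x)
        assert out.probabilities.shape == (32, 32, 32, 2)
        assert np.abs(out.probabilities.data.sum(-1) - 1).max() < 1e-6

    def test_deterministic_given_weights(self, rng):
        net = tiny_net()
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        assert np.array_equal(net.forward(x).probabilities.data,
                              net.forward(x).probabilities.data)

    def test_multi_stage_skip_symmetry(self, rng):
        """Three-stage U: decoder output lands back on the input grid."""
        net = IBSwinUNet3D(base_channels=16, depths=(2, 2, 2), seed=0)
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        assert net.forward(x).probabilities.shape == (32, 32, 32, 2)

    def test_local_path_fusion_is_live(self, rng):
        """Perturbing the local-feature convolution changes the output."""
        net = tiny_net()
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        base = net.forward(x).probabilities.data.copy()
        # a single-element bump: uniform perturbations cancel against the
        # zero-mean layer-norm input feeding this convolution
        net.local.conv2.weight.data[0, 0, 0, 0, 0] += 2.0
        assert not np.allclose(net.forward(x).probabilities.data, base)

    def test_local_path_disabled(self, rng):
        net = tiny_net(local_path=False)
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        assert not hasattr(net, "local")
        assert net.forward(x).probabilities.shape == (16, 16, 16, 2)

    def test_gradients_reach_every_parameter(self, rng):
        """No dead branches: one backward pass touches all parameter groups."""
        net = tiny_net()
        x = rng.normal(size=(8, 8, 8)).astype(np.float32)
        out = net.forward(x)
        (out.probabilities[..., 0].sum()).backward()
        missing = [n for n, p in net.named_parameters() if p.grad is None]
        assert missing == []

    def test_ablation_variants_run(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        for kw in [dict(downsample_mode="patch_merging", depths=(2, 2)),
                   dict(upsample_mode="trilinear", depths=(2, 2)),
                   dict(upsample_mode="patch_expanding", depths=(2, 2)),
                   dict(position_mode="relative_only")]:
            net = tiny_net(**kw)
            out = net.forward(x)
            assert np.abs(out.probabilities.data.sum(-1) - 1).max() < 1e-6


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, tmp_path, rng):
        net = tiny_net()
        x = rng.normal(size=(8, 8, 8)).astype(np.float32)
        ref = net.forward(x).probabilities.data.copy()
        save_checkpoint(net, tmp_path / "ck.npz", config_hash="abc123")
        other = tiny_net(seed=99)
        assert not np.allclose(other.forward(x).probabilities.data, ref)
        assert load_checkpoint(other, tmp_path / "ck.npz") == "abc123"
        assert np.array_equal(other.forward(x).probabilities.data, ref)

    def test_mismatched_state_rejected(self, tmp_path):
        net = tiny_net()
        save_checkpoint(net, tmp_path / "ck.npz")
        bigger = IBSwinUNet3D(base_channels=32, depths=(2,), seed=0)
        with pytest.raises((KeyError, ValueError)):
            load_checkpoint(bigger, tmp_path / "ck.npz")
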