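"""Architecture: shapes, fusion widths, skip pathways, parameter counts."""

from dataclasses import replace

import numpy as np
import pytest

from rirsr.model import ModelConfig, ResidualBlock, ResidualGroup, RIRNetwork, count_parameters
from rirsr.nn import ChannelAttention, Conv2d, pixel_shuffle, pixel_unshuffle


def _zero_weights(module_params):
    for p in module_params:
        p.value[...] = 0.0


class TestShapeContracts:
    @pytest.mark.parametrize("scale,h_in,h_out", [(2, 32, 64), (4, 16, 64), (8, 16, 128)])
    def test_forward_scales_spatial_size(self, scale, h_in, h_out):
        cfg = ModelConfig(n_groups=1, n_blocks_per_group=1, n_filters=8,
                          scale=scale, seed=0)
        net = RIRNetwork(cfg)
        x = np.random.default_rng(0).random((1, h_in, h_in, 1), dtype=np.float32)
        assert net.forward(x).shape == (1, h_out, h_out, 1)

    def test_fully_convolutional_arbitrary_size(self, tiny_cfg):
        net = RIRNetwork(tiny_cfg)
        for h, w in [(8, 12), (16, 16), (20, 8)]:
            x = np.zeros((1, h, w, 1), dtype=np.float32)
            assert net.forward(x).shape == (1, 4 * h, 4 * w, 1)

    @pytest.mark.parametrize("flags", [(False, True, True), (True, True, True),
                                       (False, False, True), (True, False, False)])
    def test_residual_block_preserves_shape(self, flags):
        ca, concat, skip = flags
        cfg = ModelConfig(n_filters=16, use_channel_attention=ca,
                          use_concat_fusion=concat, use_skip=skip,
                          ca_reduction=4, seed=1)
        rb = ResidualBlock(cfg, np.random.default_rng(1))
        x = np.random.default_rng(2).random((2, 16, 16, 16), dtype=np.float32)
        assert rb.forward(x).shape == x.shape

    def test_channel_mismatch_rejected(self, tiny_cfg):
        rb = ResidualBlock(tiny_cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            rb.forward(np.zeros((1, 8, 8, 7), dtype=np.float32))

    def test_multichannel_input_rejected(self, tiny_cfg):
        net = RIRNetwork(tiny_cfg)
        with pytest.raises(ValueError, match="single-channel"):
            net.forward(np.zeros((1, 8, 8, 3), dtype=np.float32))

    def test_forward_deterministic(self, tiny_cfg):
        net = RIRNetwork(tiny_cfg)
        x = np.random.default_rng(5).random((1, 16, 16, 1), dtype=np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))


class TestFusionWidths:
    def test_group_fusion_input_width_reference_config(self):
        """Dense feature fusion inside a group concatenates the four
        block outputs plus the group input: (4+1)*64 = 320 channels."""
        cfg = ModelConfig()  # reference: 4 groups, 4 blocks, 64 filters
        grp = ResidualGroup(cfg, np.random.default_rng(0))
        assert grp.fuse.c_in == 320
        assert grp.fuse.c_out == 64
        assert grp.fuse.k == 1

    def test_trunk_fusion_input_width_reference_config(self):
        """The trunk concatenates the four group outputs: 4*64 = 256."""
        net = RIRNetwork(ModelConfig())
        assert net.trunk_fuse.c_in == 256
        assert net.trunk_fuse.c_out == 64

    def test_single_block_group_is_block_plus_fusion(self):
        """A 1-block group equals that block followed by a 1x1 fusion of
        the (block output, input) pair — manual composition oracle."""
        cfg = ModelConfig(n_groups=1, n_blocks_per_group=1, n_filters=8, seed=2)
        grp = ResidualGroup(cfg, np.random.default_rng(7))
        assert grp.fuse.c_in == 16  # 2f
        x = np.random.default_rng(3).random((1, 8, 8, 8), dtype=np.float32)
        manual = grp.fuse.forward(
            np.concatenate([grp.blocks[0].forward(x), x], axis=-1)
        )
        np.testing.assert_allclose(grp.forward(x), manual, rtol=1e-6)


class TestSkipPathways:
    def test_zero_trunk_reduces_to_shallow_features(self, tiny_cfg):
        """With all trunk weights zero the long skip makes the deep path
        an identity on the shallow features."""
        net = RIRNetwork(tiny_cfg)
        for grp in net.groups:
            _zero_weights(grp.params())
        _zero_weights(net.trunk_fuse.params())
        x = np.random.default_rng(1).random((1, 12, 12, 1), dtype=np.float32)
        sf = net.shallow_features(x)
        np.testing.assert_allclose(net.trunk(sf), sf, atol=1e-7)

    def test_zero_block_with_skip_is_leaky_identity(self):
        cfg = ModelConfig(n_filters=8, use_skip=True, seed=0)
        rb = ResidualBlock(cfg, np.random.default_rng(0))
        _zero_weights(rb.params())
        x = np.random.default_rng(2).standard_normal((1, 8, 8, 8)).astype(np.float32)
        out = rb.forward(x)
        expected = np.where(x > 0, x, cfg.leaky_slope * x)
        np.testing.assert_allclose(out, expected, atol=1e-7)

    def test_zero_block_without_skip_is_zero(self):
        cfg = ModelConfig(n_filters=8, use_skip=False, seed=0)
        rb = ResidualBlock(cfg, np.random.default_rng(0))
        _zero_weights(rb.params())
        x = np.random.default_rng(2).random((1, 8, 8, 8), dtype=np.float32)
        np.testing.assert_allclose(rb.forward(x), 0.0, atol=1e-9)


class TestChannelAttention:
    def test_gate_rescales_constant_channels(self):
        ca = ChannelAttention(8, 4, np.random.default_rng(0))
        x = np.ones((1, 6, 6, 8), dtype=np.float32) * np.arange(1, 9, dtype=np.float32)
        out = ca.forward(x)
        ratio = out / x
        # each channel scaled by one constant in (0, 1)
        assert np.allclose(ratio, ratio[:, :1, :1, :], atol=1e-6)
        assert (ratio > 0).all() and (ratio < 1).all()

    def test_zero_weight_gate_is_half(self):
        ca = ChannelAttention(8, 4, np.random.default_rng(0))
        for p in ca.params():
            p.value[...] = 0.0
        gate = ca.gate(np.zeros((2, 4, 4, 8), dtype=np.float32))
        np.testing.assert_allclose(gate, 0.5, atol=1e-9)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(10, 4, np.random.default_rng(0))


class TestPixelShuffle:
    def test_shuffle_arithmetic(self):
        x = np.random.default_rng(0).random((2, 16, 16, 16 * 3), dtype=np.float32)
        assert pixel_shuffle(x, 4).shape == (2, 64, 64, 3)

    def test_shuffle_unshuffle_bijection(self):
        x = np.random.default_rng(1).random((2, 8, 8, 4 * 5), dtype=np.float32)
        np.testing.assert_array_equal(pixel_unshuffle(pixel_shuffle(x, 2), 2), x)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            pixel_shuffle(np.zeros((1, 4, 4, 7)), 2)


class TestParameterCounts:
    def test_shallow_layer_count(self):
        cfg = ModelConfig(n_filters=64)
        net = RIRNetwork(cfg)
        w, b = net.shallow.params()
        assert w.value.size + b.value.size == (3 * 3 * 1 + 1) * 64

    def test_hand_enumerated_tiny_config(self):
        """Every tensor shape of (RG=1, RB=1, f=8, x2, no CA, concat on)
        enumerated by hand."""
        f = 8
        cfg = ModelConfig(n_groups=1, n_blocks_per_group=1, n_filters=f,
                          scale=2, use_channel_attention=False,
                          use_concat_fusion=True, use_skip=True, seed=0)
        shallow = (9 * 1 + 1) * f
        block = (1 * f + 1) * f + (9 * f + 1) * f + (25 * f + 1) * f \
            + (3 * f + 1) * f
        group_fuse = (2 * f + 1) * f
        trunk_fuse = (1 * f + 1) * f
        up = (9 * f + 1) * (4 * f)
        final = (9 * f + 1) * 1
        expected = shallow + block + group_fuse + trunk_fuse + up + final
        assert count_parameters(cfg) == expected
        assert RIRNetwork(cfg).n_parameters == expected

    @pytest.mark.parametrize("ca", [False, True])
    @pytest.mark.parametrize("concat", [False, True])
    @pytest.mark.parametrize("scale", [2, 4, 8])
    def test_closed_form_matches_instantiated(self, ca, concat, scale):
        cfg = ModelConfig(n_groups=2, n_blocks_per_group=3, n_filters=8,
                          scale=scale, use_channel_attention=ca,
                          use_concat_fusion=concat, ca_reduction=4, seed=0)
        assert count_parameters(cfg) == RIRNetwork(cfg).n_parameters

    def test_cascade_upsampler_counts(self):
        cfg = ModelConfig(n_groups=1, n_blocks_per_group=1, n_filters=8,
                          scale=8, upsampler="cascade", seed=0)
        assert count_parameters(cfg) == RIRNetwork(cfg).n_parameters

    def test_channel_attention_adds_expected_parameters(self):
        """CA adds 2 f^2/r + f + f/r parameters per block."""
        f, r = 16, 4
        base = ModelConfig(n_groups=2, n_blocks_per_group=2, n_filters=f,
                           ca_reduction=r)
        with_ca = replace(base, use_channel_attention=True)
        per_block = 2 * f * f // r + f + f // r
        n_blocks = base.n_groups * base.n_blocks_per_group
        assert count_parameters(with_ca) - count_parameters(base) \
            == n_blocks * per_block
        assert count_parameters(with_ca) > count_parameters(base)

    def test_concat_fusion_adds_exactly_the_fusion_conv(self):
        f = 16
        base = ModelConfig(n_filters=f, use_concat_fusion=False)
        with_cat = replace(base, use_concat_fusion=True)
        n_blocks = base.n_groups * base.n_blocks_per_group
        assert count_parameters(with_cat) - count_parameters(base) \
            == n_blocks * (3 * f + 1) * f

    def test_count_independent_of_input_size(self, tiny_cfg):
        net = RIRNetwork(tiny_cfg)
        n0 = net.n_parameters
        net.forward(np.zeros((1, 8, 8, 1), dtype=np.float32))
        net.forward(np.zeros((1, 24, 24, 1), dtype=np.float32))
        assert net.n_parameters == n0


class TestConfigValidation:
    def test_bad_scale(self):
        with pytest.raises(ValueError):
            ModelConfig(scale=3)

    def test_ca_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_filters=10, use_channel_attention=True, ca_reduction=4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            Conv2d(1, 1, 2, np.random.default_rng(0))


def test_seeded_init_reproducible(tiny_cfg):
    a = RIRNetwork(tiny_cfg)
    b = RIRNetwork(tiny_cfg)
    for pa, pb in zip(a.params(), b.params()):
        np.testing.assert_array_equal(pa.value, pb.value)
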