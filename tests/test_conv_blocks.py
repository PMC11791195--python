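"""Unit and oracle tests for the CNN-track convolutional blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfunet import autodiff as ad
from dfunet import nn
from dfunet.autodiff import Tensor
from dfunet.conv_blocks import (ConfigurationError, DDSC, DeformableConv2d,
                                GhostModule, LMDSBlock, LMDSConfig, MixConv,
                                channel_shuffle)


def make_cfg(**kw):
    base = dict(in_channels=16, out_channels=32)
    base.update(kw)
    return LMDSConfig(**base)


# ---------------------------------------------------------------------------
# ghost module
# ---------------------------------------------------------------------------

class TestGhost:
    def test_output_shape(self, rng):
        g = GhostModule(make_cfg(), rng)
        out = g(Tensor(rng.uniform(-1, 1, (1, 16, 8, 8))))
        assert out.shape == (1, 32, 8, 8)

    def test_fewer_parameters_than_dense_conv(self, rng):
        """ghost(16->32, k=3, ratio=2) vs dense conv(16->32, k=3):
        analytically (16*16*9 + 16) + (16*9 + 16) + 64 (BN) = 2,544
        < dense 16*32*9 + 32 = 4,640."""
        g = GhostModule(make_cfg(), rng)
        dense = nn.Conv2d(16, 32, 3, rng=rng)
        assert nn.count_parameters(g) == 2544
        assert nn.count_parameters(dense) == 4640
        assert nn.count_parameters(g) < nn.count_parameters(dense)

    def test_ratio_one_degenerates_to_intrinsic_conv(self, rng):
        g = GhostModule(make_cfg(ghost_ratio=1), rng)
        dense = nn.Conv2d(16, 32, 3, padding=(1, 1, 1, 1), rng=rng)
        out = g(Tensor(rng.uniform(-1, 1, (1, 16, 8, 8))))
        assert out.shape == (1, 32, 8, 8)
        # same conv parameter count (plus only the BN pair)
        assert (nn.count_parameters(g)
                == nn.count_parameters(dense) + 2 * 32)

    def test_channel_mismatch_raises(self, rng):
        from dfunet.conv_blocks import ghost_forward
        with pytest.raises(ConfigurationError, match="ghost"):
            ghost_forward(Tensor(np.zeros((1, 8, 4, 4))), make_cfg(), rng)


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

class TestChannelShuffle:
    def test_known_permutation(self):
        x = Tensor(np.arange(6, dtype=float).reshape(1, 6, 1, 1))
        assert channel_shuffle(x, 2).data.ravel().tolist() == [0, 3, 1, 4, 2, 5]

    def test_matches_closed_form_index_map(self, rng):
        C, g = 12, 3
        x = Tensor(np.arange(C, dtype=float).reshape(1, C, 1, 1))
        out = channel_shuffle(x, g).data.ravel()
        expect = [(i % g) * (C // g) + i // g for i in range(C)]
        assert out.tolist() == expect

    def test_groups_one_is_identity(self, rng):
        x = Tensor(rng.uniform(-1, 1, (2, 8, 3, 3)))
        assert np.array_equal(channel_shuffle(x, 1).data, x.data)

    def test_shuffle_then_complement_is_identity(self):
        for C, g in [(6, 2), (12, 3), (12, 4), (8, 2)]:
            x = Tensor(np.arange(C, dtype=float).reshape(1, C, 1, 1))
            roundtrip = channel_shuffle(channel_shuffle(x, g), C // g)
            assert np.array_equal(roundtrip.data, x.data), (C, g)

    @given(st.sampled_from([(2, 1), (6, 2), (6, 3), (12, 4), (24, 6), (9, 3)]))
    @settings(deadline=None, max_examples=20)
    def test_is_bijection_on_channels(self, cg):
        C, g = cg
        x = Tensor(np.arange(C, dtype=float).reshape(1, C, 1, 1))
        out = channel_shuffle(x, g).data.ravel()
        assert sorted(out.tolist()) == list(range(C))

    def test_non_divisible_raises(self):
        with pytest.raises(ConfigurationError):
            channel_shuffle(Tensor(np.zeros((1, 7, 2, 2))), 2)


# ---------------------------------------------------------------------------
# mixconv
# ---------------------------------------------------------------------------

class TestMixConv:
    def test_single_kernel_equals_plain_depthwise(self, rng):
        mc = MixConv(12, (3,), bias=False, rng=np.random.default_rng(5))
        x = Tensor(rng.uniform(-1, 1, (1, 12, 8, 8)))
        ref = ad.conv2d(x, mc.convs[0].weight, None, 1, (1, 1, 1, 1),
                        groups=12)
        assert np.allclose(mc(x).data, ref.data, atol=1e-12)

    def test_three_kernel_groups_preserve_shape(self, rng):
        mc = MixConv(12, (3, 5, 7), bias=False, rng=rng)
        assert mc.group_channels == 4
        out = mc(Tensor(rng.uniform(-1, 1, (1, 12, 8, 8))))
        assert out.shape == (1, 12, 8, 8)

    def test_averaging_kernels_keep_constant_input(self, rng):
        """All-ones input under averaging kernels stays all ones away from
        the borders (hand-evaluated interior contract)."""
        mc = MixConv(6, (3, 5), bias=False, rng=rng)
        for conv, k in zip(mc.convs, (3, 5)):
            conv.weight.data[:] = 1.0 / (k * k)
        out = mc(Tensor(np.ones((1, 6, 9, 9)))).data
        interior = out[:, :, 2:-2, 2:-2]
        assert np.allclose(interior, 1.0, atol=1e-12)

    @pytest.mark.parametrize("kernels", [(), (4,), (2, 3)])
    def test_invalid_kernel_lists_rejected(self, kernels, rng):
        with pytest.raises(ConfigurationError):
            MixConv(12, kernels, bias=False, rng=rng)


# ---------------------------------------------------------------------------
# dilated depth-wise separable conv
# ---------------------------------------------------------------------------

class TestDDSC:
    @pytest.mark.parametrize("k,d,rf", [(2, 1, 2), (2, 2, 3), (3, 2, 5)])
    def test_receptive_field_arithmetic(self, k, d, rf):
        assert (k - 1) * d + 1 == rf

    def test_parameter_count_below_dense(self, rng):
        C = 8
        cfg = make_cfg(in_channels=C, out_channels=C)
        d = DDSC(C, cfg, rng)
        # depth-wise C*k^2 + point-wise C*C + C bias
        assert nn.count_parameters(d) == C * 4 + C * C + C
        dense = C * C * 4 + C
        assert nn.count_parameters(d) < dense

    def test_delta_input_reproduces_dilated_footprint(self, rng):
        """A centred delta passes the depth-wise stage as the dilated kernel
        footprint; verified against a brute-force direct convolution."""
        C, k, d = 4, 2, 2
        cfg = make_cfg(in_channels=C, out_channels=C, ddsc_kernel_size=k,
                       ddsc_dilation=d)
        layer = DDSC(C, cfg, rng)
        x = np.zeros((1, C, 7, 7))
        x[0, :, 3, 3] = 1.0
        out = layer.depthwise(Tensor(x)).data
        # brute force: same-padded (bottom/right) dilated depth-wise conv
        ref = np.zeros_like(out)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 2), (0, 2)))
        w = layer.depthwise.weight.data
        for c in range(C):
            for i in range(7):
                for j in range(7):
                    acc = 0.0
                    for a in range(k):
                        for b in range(k):
                            acc += w[c, 0, a, b] * xp[0, c, i + a * d, j + b * d]
                    ref[0, c, i, j] = acc
        assert np.allclose(out, ref, atol=1e-12)

    def test_spatial_size_preserved(self, rng):
        layer = DDSC(6, make_cfg(in_channels=6, out_channels=6), rng)
        out = layer(Tensor(rng.uniform(-1, 1, (2, 6, 11, 13))))
        assert out.shape == (2, 6, 11, 13)


# ---------------------------------------------------------------------------
# deformable convolution
# ---------------------------------------------------------------------------

class TestDeformable:
    def test_zero_offsets_match_dense_conv_oracle(self, rng):
        dc = DeformableConv2d(4, 5, 3, rng=np.random.default_rng(2))
        x = Tensor(rng.uniform(-1, 1, (1, 4, 6, 6)))
        dense = ad.conv2d(x, dc.weight, dc.bias, 1, (1, 1, 1, 1))
        assert np.allclose(dc(x).data, dense.data, atol=1e-5)

    def test_integer_shift_on_constant_input(self, rng):
        """Shifting every tap by (+1, 0) leaves a constant input's response
        unchanged away from the borders (one extra border row at the bottom,
        where the shifted taps reach the zero padding)."""
        dc = DeformableConv2d(2, 3, 3, rng=np.random.default_rng(3))
        x = Tensor(np.full((1, 2, 8, 8), 0.7))
        base = dc(x).data
        offs = np.zeros((1, 18, 8, 8))
        offs[0, 0::2] = 1.0   # +1 row for every tap
        shifted = dc(x, Tensor(offs)).data
        assert np.allclose(shifted[:, :, 1:-2, 1:-1], base[:, :, 1:-2, 1:-1],
                           atol=1e-10)

    def test_stride_two_halves_grid(self, rng):
        dc = DeformableConv2d(8, 8, 1, stride=2, rng=rng)
        out = dc(Tensor(rng.uniform(-1, 1, (1, 8, 14, 14))))
        assert out.shape == (1, 8, 7, 7)

    def test_wrong_offset_channels_rejected(self, rng):
        dc = DeformableConv2d(2, 2, 3, rng=rng)
        with pytest.raises(ConfigurationError):
            dc(Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 4, 4, 4))))

    def test_offset_gradient_flows(self, rng):
        dc = DeformableConv2d(2, 2, 3, rng=np.random.default_rng(4))
        x = Tensor(rng.uniform(-1, 1, (1, 2, 5, 5)))
        offs = Tensor(rng.uniform(-0.3, 0.3, (1, 18, 5, 5)), requires_grad=True)
        dc(x, offs).sum().backward()
        assert offs.grad is not None and np.abs(offs.grad).max() > 0


# ---------------------------------------------------------------------------
# the assembled LMDS block
# ---------------------------------------------------------------------------

class TestLMDSBlock:
    def test_spatial_halving_and_width(self, rng):
        blk = LMDSBlock(LMDSConfig(3, 8), rng=rng)
        out = blk(Tensor(rng.uniform(-1, 1, (1, 3, 32, 32))))
        assert out.shape == (1, 8, 16, 16)

    def test_zero_ddsc_branch_zeroes_merge(self, rng):
        blk = LMDSBlock(LMDSConfig(3, 8), rng=np.random.default_rng(6))
        blk.ddsc.pointwise.weight.data[:] = 0.0
        blk.ddsc.pointwise.bias.data[:] = 0.0
        x = Tensor(rng.uniform(-1, 1, (1, 3, 16, 16)))
        merged = ad.mul(blk.mixconv(channel_shuffle(blk.ghost(x),
                                                    blk.cfg.shuffle_groups)),
                        blk.ddsc(blk.ghost(x)))
        assert np.allclose(merged.data, 0.0)

    def test_gradients_reach_every_parameter(self, rng):
        blk = LMDSBlock(LMDSConfig(3, 6), rng=np.random.default_rng(7))
        out = blk(Tensor(rng.uniform(-1, 1, (1, 3, 32, 32))))
        out.sum().backward()
        missing = [n for n, p in blk.named_parameters() if p.grad is None]
        assert missing == []

    def test_no_nan_inf_on_uniform_inputs(self, rng):
        blk = LMDSBlock(LMDSConfig(4, 8), rng=rng)
        out = blk(Tensor(rng.uniform(-1, 1, (2, 4, 16, 16))))
        assert np.isfinite(out.data).all()
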