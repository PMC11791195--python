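"""Oracle tests for the attention operators.

Each operator is checked against an independent loop-based evaluation of
its defining equations on small random inputs.
"""

import numpy as np
import pytest

from dfunet import autodiff as ad
from dfunet import nn
from dfunet.autodiff import Tensor
from dfunet.attention_blocks import (CoordinateAttention, DCLSConv, GDABlock,
                                     GlobalContextBlock, ShuffleAttention)
from dfunet.conv_blocks import ConfigurationError


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


# ---------------------------------------------------------------------------
# global context block
# ---------------------------------------------------------------------------

def gcb_loop_oracle(x, gcb):
    """Literal per-position evaluation of the attention-pooling equations."""
    N, C, H, W = x.shape
    wk = gcb.key.weight.data.reshape(C)
    bk = gcb.key.bias.data[0]
    out = np.empty_like(x)
    for n in range(N):
        logits = np.array([wk @ x[n, :, i, j] + bk
                           for i in range(H) for j in range(W)])
        e = np.exp(logits - logits.max())
        alpha = e / e.sum()
        z = sum(alpha[k] * x[n, :, k // W, k % W] for k in range(H * W))
        h = z @ gcb.v1.weight.data
        hn = ((h - h.mean()) / np.sqrt(h.var() + gcb.ln.eps)
              * gcb.ln.weight.data + gcb.ln.bias.data)
        delta = np.maximum(hn, 0) @ gcb.v2.weight.data
        out[n] = x[n] + delta[:, None, None]
    return out


class TestGlobalContext:
    def test_uniform_logits_give_uniform_weights(self, rng):
        gcb = GlobalContextBlock(3, rng=rng)
        gcb.key.weight.data[:] = 0.0
        gcb.key.bias.data[:] = 0.0
        a = gcb.attention_weights(Tensor(rng.uniform(-1, 1, (1, 3, 1, 2))))
        assert np.allclose(a.data, [[0.5, 0.5]])

    def test_log2_logit_gives_two_thirds(self, rng):
        """Logits [ln 2, 0] -> weights [2/3, 1/3]."""
        gcb = GlobalContextBlock(1, rng=rng)
        gcb.key.weight.data[:] = 1.0
        gcb.key.bias.data[:] = 0.0
        x = np.zeros((1, 1, 1, 2))
        x[0, 0, 0, 0] = np.log(2.0)
        a = gcb.attention_weights(Tensor(x))
        assert np.allclose(a.data, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_weights_sum_to_one(self, rng):
        gcb = GlobalContextBlock(4, rng=rng)
        a = gcb.attention_weights(Tensor(rng.uniform(-1, 1, (3, 4, 3, 3))))
        assert np.allclose(a.data.sum(axis=1), 1.0, atol=1e-6)
        assert (a.data >= 0).all()

    def test_matches_positionwise_softmax_oracle(self, rng):
        gcb = GlobalContextBlock(4, rng=np.random.default_rng(11))
        x = rng.uniform(-1, 1, (1, 4, 3, 3))
        a = gcb.attention_weights(Tensor(x)).data
        wk = gcb.key.weight.data.reshape(4)
        logits = np.array([wk @ x[0, :, i, j] + gcb.key.bias.data[0]
                           for i in range(3) for j in range(3)])
        ref = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(a[0], ref, atol=1e-12)

    def test_zero_v2_is_identity(self, rng):
        gcb = GlobalContextBlock(5, rng=np.random.default_rng(12))
        gcb.v2.weight.data[:] = 0.0
        x = Tensor(rng.uniform(-1, 1, (2, 5, 4, 4)))
        assert np.array_equal(gcb(x).data, x.data)

    def test_constant_input_context_is_the_constant(self, rng):
        gcb = GlobalContextBlock(3, rng=np.random.default_rng(13))
        c = np.array([0.3, -1.2, 0.8])
        x = np.broadcast_to(c[None, :, None, None], (1, 3, 4, 5)).copy()
        alpha = gcb.attention_weights(Tensor(x)).data[0]
        z = (x[0].reshape(3, -1) * alpha).sum(axis=1)
        assert np.allclose(z, c, atol=1e-12)

    def test_forward_matches_loop_oracle(self, rng):
        gcb = GlobalContextBlock(4, reduction=2, rng=np.random.default_rng(14))
        x = rng.uniform(-1, 1, (2, 4, 3, 3))
        assert np.allclose(gcb(Tensor(x)).data, gcb_loop_oracle(x, gcb),
                           atol=1e-5)


# ---------------------------------------------------------------------------
# learnable-spacing convolution
# ---------------------------------------------------------------------------

class TestDCLS:
    def test_frozen_grid_equals_standard_conv(self, rng):
        d = DCLSConv(3, n_elements=9, extent=3, rng=np.random.default_rng(5))
        d.freeze_grid(3)
        x = Tensor(rng.uniform(-1, 1, (2, 3, 6, 6)))
        w = Tensor(d.weight.data.reshape(3, 1, 3, 3))
        ref = ad.conv2d(x, w, None, 1, (1, 1, 1, 1), groups=3)
        assert np.allclose(d(x).data, ref.data, atol=1e-5)

    def test_frozen_dilated_grid_equals_dilated_conv(self, rng):
        """Positions on a regular dilation-2 grid reproduce a standard
        dilated depth-wise convolution."""
        d = DCLSConv(2, n_elements=9, extent=5, rng=np.random.default_rng(6))
        gy, gx = np.meshgrid(np.arange(3) * 2, np.arange(3) * 2, indexing="ij")
        d.positions.data = np.tile(
            np.stack([gy.ravel(), gx.ravel()], -1)[None], (2, 1, 1)).astype(float)
        x = Tensor(rng.uniform(-1, 1, (1, 2, 7, 7)))
        w = Tensor(d.weight.data.reshape(2, 1, 3, 3))
        ref = ad.conv2d(x, w, None, 1, (2, 2, 2, 2), dilation=2, groups=2)
        assert np.allclose(d(x).data, ref.data, atol=1e-5)

    def test_center_element_identity(self, rng):
        d = DCLSConv(2, n_elements=1, extent=5, rng=rng)
        d.weight.data[:] = 1.0
        d.positions.data[:] = 2.0   # extent // 2 == patch centre
        x = Tensor(rng.uniform(-1, 1, (1, 2, 6, 6)))
        assert np.allclose(d(x).data, x.data, atol=1e-12)

    def test_position_gradient_matches_finite_difference(self, rng):
        d = DCLSConv(2, n_elements=3, extent=5, rng=np.random.default_rng(7))
        x = Tensor(rng.uniform(-1, 1, (1, 2, 5, 5)))
        wref = rng.uniform(-1, 1, (1, 2, 5, 5))
        (d(x) * Tensor(wref)).sum().backward()
        idx = (0, 1, 0)
        eps = 1e-6
        orig = d.positions.data[idx]
        d.positions.data[idx] = orig + eps
        fp = float((d(x).data * wref).sum())
        d.positions.data[idx] = orig - eps
        fm = float((d(x).data * wref).sum())
        d.positions.data[idx] = orig
        num = (fp - fm) / (2 * eps)
        assert d.positions.grad[idx] == pytest.approx(num, abs=1e-5)
        assert abs(num) > 0  # positions are genuinely trainable


# ---------------------------------------------------------------------------
# coordinate attention
# ---------------------------------------------------------------------------

def ca_loop_oracle(x, ca):
    C, H, W = x.shape[1:]
    zh = x.mean(axis=3)[0]
    zw = x.mean(axis=2)[0]
    cat = np.concatenate([zh, zw], axis=1)
    f = ca.f1.weight.data[:, :, 0, 0] @ cat + ca.f1.bias.data[:, None]
    f = f * np.clip(f + 3, 0, 6) / 6          # hard-swish
    fh, fw = f[:, :H], f[:, H:]
    gh = sigmoid(ca.f_h.weight.data[:, :, 0, 0] @ fh + ca.f_h.bias.data[:, None])
    gw = sigmoid(ca.f_w.weight.data[:, :, 0, 0] @ fw + ca.f_w.bias.data[:, None])
    return x[0] * gh[:, :, None] * gw[:, None, :]


class TestCoordinateAttention:
    def test_constant_input_pools_to_constant(self, rng):
        ca = CoordinateAttention(4, reduction=2, rng=rng)
        c = 0.37
        x = Tensor(np.full((1, 4, 5, 6), c))
        zh = ad.tmean(x, axis=3).data
        zw = ad.tmean(x, axis=2).data
        assert np.allclose(zh, c) and np.allclose(zw, c)

    def test_output_bounded_by_input(self, rng):
        ca = CoordinateAttention(8, reduction=2, rng=np.random.default_rng(8))
        x = rng.uniform(-1, 1, (2, 8, 5, 5))
        out = ca(Tensor(x)).data
        assert (np.abs(out) <= np.abs(x) + 1e-12).all()

    def test_matches_loop_oracle(self, rng):
        ca = CoordinateAttention(8, reduction=2, rng=np.random.default_rng(9))
        x = rng.uniform(-1, 1, (1, 8, 4, 5))
        assert np.allclose(ca(Tensor(x)).data[0], ca_loop_oracle(x, ca),
                           atol=1e-5)


# ---------------------------------------------------------------------------
# GDA composition
# ---------------------------------------------------------------------------

class TestGDA:
    @pytest.mark.parametrize("C,H,W", [(4, 5, 5), (6, 7, 4)])
    def test_shape_preserved(self, C, H, W, rng):
        gda = GDABlock(C, dcls_elements=4, rng=rng)
        out = gda(Tensor(rng.uniform(-1, 1, (1, C, H, W))))
        assert out.shape == (1, C, H, W)

    def test_gradients_reach_all_sublayers(self, rng):
        gda = GDABlock(4, dcls_elements=4, rng=np.random.default_rng(10))
        gda(Tensor(rng.uniform(-1, 1, (1, 4, 6, 6)))).sum().backward()
        assert [n for n, p in gda.named_parameters() if p.grad is None] == []

    def test_identity_configuration(self, rng):
        """GCB with zero residual branch, a single centre DCLS element of
        weight one, and saturated CA gates compose to the identity."""
        gda = GDABlock(3, dcls_elements=1, dcls_extent=5,
                       rng=np.random.default_rng(15))
        gda.gcb.v2.weight.data[:] = 0.0
        gda.dcls.weight.data[:] = 1.0
        gda.dcls.positions.data[:] = 2.0
        gda.ca.f1.weight.data[:] = 0.0
        gda.ca.f1.bias.data[:] = 3.0      # hard-swish(3) = 3
        gda.ca.f_h.weight.data[:] = 0.0
        gda.ca.f_w.weight.data[:] = 0.0
        gda.ca.f_h.bias.data[:] = 40.0    # sigmoid saturates at 1
        gda.ca.f_w.bias.data[:] = 40.0
        x = Tensor(rng.uniform(-1, 1, (1, 3, 6, 6)))
        assert np.allclose(gda(x).data, x.data, atol=1e-12)


# ---------------------------------------------------------------------------
# shuffle attention
# ---------------------------------------------------------------------------

def sa_loop_oracle(x, sa):
    N, C, H, W = x.shape
    G = sa.groups
    half = C // (2 * G)
    w1, b1 = sa.w1.data.ravel(), sa.b1.data.ravel()
    w2, b2 = sa.w2.data.ravel(), sa.b2.data.ravel()
    gnw, gnb = sa.gn.weight.data, sa.gn.bias.data
    xg = x.reshape(N * G, C // G, H, W)
    og = np.empty_like(xg)
    for b in range(N * G):
        x1, x2 = xg[b, :half], xg[b, half:]
        s = x1.mean(axis=(1, 2))
        og[b, :half] = x1 * sigmoid(w1 * s + b1)[:, None, None]
        for c in range(half):
            gn = ((x2[c] - x2[c].mean()) / np.sqrt(x2[c].var() + sa.gn.eps)
                  * gnw[c] + gnb[c])
            og[b, half + c] = x2[c] * sigmoid(w2[c] * gn + b2[c])
    out = og.reshape(N, C, H, W)
    idx = np.arange(C).reshape(2, C // 2).T.ravel()  # final 2-group shuffle
    return out[:, idx]


class TestShuffleAttention:
    def test_saturated_gates_give_pure_permutation(self, rng):
        sa = ShuffleAttention(12, 2)
        sa.w1.data[:] = 0.0
        sa.w2.data[:] = 0.0
        sa.b1.data[:] = 50.0
        sa.b2.data[:] = 50.0
        x = rng.uniform(-1, 1, (2, 12, 4, 4))
        out = sa(Tensor(x)).data
        idx = np.arange(12).reshape(2, 6).T.ravel()
        assert np.allclose(out, x[:, idx], atol=1e-12)

    def test_parameter_count_closed_form(self):
        """3C/G parameters; at the fused width (C=918, G=3) this equals the
        published 918-parameter delta between the with-SA and without-SA
        networks."""
        for C, G in [(12, 2), (24, 3), (918, 3)]:
            assert nn.count_parameters(ShuffleAttention(C, G)) == 3 * C // G
        assert nn.count_parameters(ShuffleAttention(918, 3)) == 918

    def test_matches_loop_oracle(self, rng):
        sa = ShuffleAttention(12, 2)
        sa.w1.data[:] = rng.uniform(0.5, 1.5, sa.w1.shape)
        sa.b1.data[:] = rng.uniform(-0.5, 0.5, sa.b1.shape)
        sa.w2.data[:] = rng.uniform(0.5, 1.5, sa.w2.shape)
        sa.b2.data[:] = rng.uniform(-0.5, 0.5, sa.b2.shape)
        x = rng.uniform(-1, 1, (2, 12, 5, 5))
        assert np.allclose(sa(Tensor(x)).data, sa_loop_oracle(x, sa),
                           atol=1e-5)

    def test_invalid_group_count_lists_valid_ones(self):
        with pytest.raises(ConfigurationError, match="G in"):
            ShuffleAttention(10, 4)

    def test_batch_independence(self, rng):
        sa = ShuffleAttention(12, 3)
        x = rng.uniform(-1, 1, (3, 12, 4, 4))
        full = sa(Tensor(x)).data
        flipped = sa(Tensor(x[::-1].copy())).data
        assert np.allclose(flipped, full[::-1], atol=1e-12)
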