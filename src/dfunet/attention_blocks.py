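"""Attention operators of the CNN track and the fusion stage.

The GDA block composes three mechanisms in sequence: a global context block
(softmax attention pooling over all spatial positions plus a bottleneck
residual), a dilated convolution with learnable spacings (kernel elements at
continuous, trainable 2-D positions), and coordinate attention (row/column
pooled profiles turned into directional sigmoid gates).  Shuffle attention
refines the fused two-track representation with grouped channel and spatial
gates followed by a channel shuffle.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import Conv2d, Module, Parameter
from .conv_blocks import ConfigurationError, channel_shuffle


class GlobalContextBlock(Module):
    """Global context modeling: attention-pooled context vector passed
    through a layer-normalized bottleneck and added back to every position.

    alpha_j = exp(w_k . x_j) / sum_m exp(w_k . x_m) over spatial positions;
    out = x + W_v2 ReLU(LN(W_v1 z)) with z = sum_j alpha_j x_j.
    """

    def __init__(self, channels: int, reduction: int = 2, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(1, -(-channels // reduction))
        self.channels, self.hidden = channels, hidden
        self.key = Conv2d(channels, 1, 1, bias=True, rng=rng)  # W_k
        self.v1 = nn.Linear(channels, hidden, bias=bias, rng=rng)
        self.ln = nn.LayerNorm(hidden)
        self.v2 = nn.Linear(hidden, channels, bias=bias, rng=rng)

    def attention_weights(self, x: Tensor) -> Tensor:
        """Per-position softmax weights, shape (N, H*W); rows sum to 1."""
        N, C, H, W = x.shape
        logits = ad.reshape(self.key(x), (N, H * W))
        return ad.softmax(logits, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        alpha = self.attention_weights(x)                      # (N, P)
        xf = ad.reshape(x, (N, C, H * W))
        z = ad.tsum(ad.mul(xf, ad.reshape(alpha, (N, 1, H * W))), axis=2)
        delta = self.v2(ad.relu(self.ln(self.v1(z))))          # (N, C)
        return ad.add(x, ad.reshape(delta, (N, C, 1, 1)))


class DCLSConv(Module):
    """Depth-wise convolution with learnable element spacings.

    Each channel owns ``n_elements`` kernel elements with real-valued 2-D
    positions inside an ``extent`` x ``extent`` neighbourhood; elements
    sample the input bilinearly, so positions as well as weights receive
    gradients.  Same-padded (extent // 2 on every side).
    """

    def __init__(self, channels: int, n_elements: int = 4, extent: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n_elements < 1:
            raise ConfigurationError("DCLS needs at least one kernel element")
        rng = rng or np.random.default_rng()
        self.channels, self.n_elements, self.extent = channels, n_elements, extent
        self.weight = Parameter(
            rng.uniform(-1, 1, (channels, n_elements)) / np.sqrt(n_elements))
        self.positions = Parameter(
            rng.uniform(0, extent - 1, (channels, n_elements, 2)))

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.channels:
            raise ConfigurationError(
                f"DCLS built for {self.channels} channels, got {C}")
        pad = self.extent // 2
        if self.extent > H + 2 * pad or self.extent > W + 2 * pad:
            raise ConfigurationError("DCLS extent exceeds the padded input")
        pos = ad.clamp(self.positions, 0.0, self.extent - 1)
        return dcls_apply(x, self.weight, pos, self.extent)

    def freeze_grid(self, kernel_size: int) -> None:
        """Pin positions to the integer points of a centred k x k grid
        (row-major); turns the layer into a standard convolution."""
        k = kernel_size
        if k * k != self.n_elements:
            raise ConfigurationError("freeze_grid needs n_elements == k*k")
        off = self.extent // 2 - (k - 1) // 2
        gy, gx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        grid = np.stack([gy.ravel() + off, gx.ravel() + off], axis=-1)
        self.positions.data = np.tile(grid[None], (self.channels, 1, 1)).astype(float)


def dcls_apply(x: Tensor, weight: Tensor, positions: Tensor,
               extent: int) -> Tensor:
    """Fused learnable-spacing depth-wise convolution.

    Because element positions are shared over the spatial grid, each element
    contributes a weighted integer-shifted copy of the input through its four
    bilinear corners; the whole layer collapses to at most ``extent**2``
    shift-and-scale terms, which keeps memory flat.  Gradients with respect
    to the input, the element weights and the element positions are analytic.
    ``positions`` must already lie inside [0, extent - 1].
    """
    N, C, H, W = x.shape
    E = weight.shape[1]
    L = extent
    pad = L // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    p = positions.data
    y0 = np.minimum(np.floor(p[:, :, 0]), L - 2).astype(np.int64)   # (C, E)
    x0 = np.minimum(np.floor(p[:, :, 1]), L - 2).astype(np.int64)
    ty = p[:, :, 0] - y0
    tx = p[:, :, 1] - x0
    w = weight.data                                                  # (C, E)
    # accumulate per-channel coefficients on the integer (a, b) shift grid
    corners = (
        (y0, x0, (1 - ty) * (1 - tx), -(1 - tx), -(1 - ty)),
        (y0, x0 + 1, (1 - ty) * tx, -tx, (1 - ty)),
        (y0 + 1, x0, ty * (1 - tx), (1 - tx), -ty),
        (y0 + 1, x0 + 1, ty * tx, tx, ty),
    )
    cidx = np.arange(C)[:, None]
    K = np.zeros((L, L, C))
    for a, b, fw, _, _ in corners:
        np.add.at(K, (a, b, cidx), w * fw)
    out = np.zeros((N, C, H, W))
    nonzero = np.argwhere(np.abs(K).sum(axis=2) > 0)
    for a, b in nonzero:
        out += xp[:, :, a:a + H, b:b + W] * K[a, b][None, :, None, None]

    def backward(g):
        # D[a, b, c] = <g_c, shift_ab(x)_c> for every used shift
        D = np.zeros((L, L, C))
        used_mask = np.zeros((L, L), dtype=bool)
        for a, b, _, _, _ in corners:
            used_mask[a.ravel(), b.ravel()] = True
        for a, b in np.argwhere(used_mask):
            D[a, b] = np.einsum("nchw,nchw->c", g,
                                xp[:, :, a:a + H, b:b + W], optimize=True)
        gw = np.zeros_like(w)
        gp = np.zeros_like(p)
        for a, b, fw, dty, dtx in corners:
            Dc = D[a, b, cidx]                      # (C, E)
            gw += fw * Dc
            gp[:, :, 0] += w * dty * Dc
            gp[:, :, 1] += w * dtx * Dc
        gxp = np.zeros_like(xp)
        for a, b in nonzero:
            gxp[:, :, a:a + H, b:b + W] += g * K[a, b][None, :, None, None]
        gx = gxp[:, :, pad:pad + H, pad:pad + W]
        return [(x, gx), (weight, gw), (positions, gp)]

    return ad._make(out, (x, weight, positions), backward)


def hard_swish(x: Tensor) -> Tensor:
    """x * clamp(x + 3, 0, 6) / 6 — the smooth gating nonlinearity used
    inside coordinate attention."""
    return ad.mul(x, ad.mul(ad.clamp(ad.add(x, 3.0), 0.0, 6.0), 1.0 / 6.0))


class CoordinateAttention(Module):
    """Direction-aware channel attention.

    Row means z^h and column means z^w are concatenated, reduced by a shared
    1x1 transform F1 (nonlinearity: hard-swish), split back, and mapped by
    per-direction transforms F_h, F_w into sigmoid gates applied as
    y_c(i,j) = x_c(i,j) * g^h_c(i) * g^w_c(j).
    """

    def __init__(self, channels: int, reduction: int = 32, min_hidden: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        hidden = max(min_hidden, -(-channels // reduction))
        self.channels, self.hidden = channels, hidden
        self.f1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.f_h = Conv2d(hidden, channels, 1, bias=True, rng=rng)
        self.f_w = Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        zh = ad.tmean(x, axis=3, keepdims=True)                  # (N,C,H,1)
        zw = ad.tmean(x, axis=2, keepdims=True)                  # (N,C,1,W)
        zw_t = ad.transpose(zw, (0, 1, 3, 2))                    # (N,C,W,1)
        f = hard_swish(self.f1(ad.concat([zh, zw_t], axis=2)))   # (N,h,H+W,1)
        fh, fw = f[:, :, :H], f[:, :, H:]
        gh = ad.sigmoid(self.f_h(fh))                            # (N,C,H,1)
        gw = ad.sigmoid(self.f_w(ad.transpose(fw, (0, 1, 3, 2))))  # (N,C,1,W)
        return ad.mul(ad.mul(x, gh), gw)


class GDABlock(Module):
    """Global context -> learnable-spacing convolution -> coordinate
    attention, all shape-preserving at the stage width."""

    def __init__(self, channels: int, gcb_reduction: int = 2,
                 ca_reduction: int = 1, dcls_elements: int = 62,
                 dcls_extent: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.gcb = GlobalContextBlock(channels, gcb_reduction, rng=rng)
        self.dcls = DCLSConv(channels, dcls_elements, dcls_extent, rng=rng)
        self.ca = CoordinateAttention(channels, ca_reduction, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.ca(self.dcls(self.gcb(x)))


class ShuffleAttention(Module):
    """Grouped channel/spatial gating with parameter sharing across groups.

    The C-channel map splits into G groups; each group splits into a channel
    half (gated by sigmoid(W1 * mean + b1)) and a spatial half (gated by
    sigmoid(W2 * GN(x) + b2), GN per-channel with affine).  Halves and groups
    are re-joined and a 2-group channel shuffle mixes the sub-features.
    All five parameter vectors have length C / (2G), shared across groups:
    3C/G trainable parameters in total.
    """

    def __init__(self, channels: int, groups: int = 3):
        super().__init__()
        if channels % (2 * groups):
            valid = [g for g in range(1, channels // 2 + 1)
                     if channels % (2 * g) == 0]
            raise ConfigurationError(
                f"shuffle attention needs channels divisible by 2*groups; "
                f"C={channels} allows G in {valid[:12]}...")
        self.channels, self.groups = channels, groups
        half = channels // (2 * groups)
        self.w1 = Parameter(np.ones((1, half, 1, 1)))
        self.b1 = Parameter(np.zeros((1, half, 1, 1)))
        self.w2 = Parameter(np.ones((1, half, 1, 1)))
        self.b2 = Parameter(np.zeros((1, half, 1, 1)))
        self.gn = nn.GroupNorm(half, half)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        G = self.groups
        half = C // (2 * G)
        xg = ad.reshape(x, (N * G, C // G, H, W))
        xk1, xk2 = xg[:, :half], xg[:, half:]
        s = ad.tmean(xk1, axis=(2, 3), keepdims=True)            # (NG,half,1,1)
        gate_c = ad.sigmoid(ad.add(ad.mul(self.w1, s), self.b1))
        out1 = ad.mul(xk1, gate_c)
        gate_s = ad.sigmoid(ad.add(ad.mul(self.w2, self.gn(xk2)), self.b2))
        out2 = ad.mul(xk2, gate_s)
        out = ad.reshape(ad.concat([out1, out2], axis=1), (N, C, H, W))
        return channel_shuffle(out, 2)
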