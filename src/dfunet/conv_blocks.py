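"""Convolutional building blocks of the lightweight CNN track.

The track's stage block (LMDS: lightweight multi-scale deformable shuffle)
chains a ghost module, two parallel branches (channel-shuffle + mixed
depth-wise kernels, and a dilated depth-wise separable convolution), a
Hadamard merge of the branches, and a stride-2 deformable convolution that
replaces pooling as the down-sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import Conv2d, Module, Parameter, same_padding


class ConfigurationError(ValueError):
    """Raised when a block is built or fed inconsistently with its config."""


@dataclass
class LMDSConfig:
    """Configuration of one LMDS stage.

    ``ghost_ratio`` is the intrinsic-to-total split of the ghost module
    (ratio 2 means half the output channels are cheap ghost maps); the even
    ``ddsc_kernel_size`` pads bottom/right only so the spatial size is kept.
    """
    in_channels: int
    out_channels: int
    ghost_ratio: int = 2
    ghost_primary_kernel: int = 3
    shuffle_groups: int = 2
    mixconv_kernel_sizes: tuple[int, ...] = (3, 5)
    ddsc_kernel_size: int = 2
    ddsc_dilation: int = 2
    deform_kernel_size: int = 1
    deform_stride: int = 2
    conv_bias: bool = True
    depthwise_bias: bool = False

    def __post_init__(self):
        if self.out_channels % self.shuffle_groups:
            raise ConfigurationError(
                f"LMDS: out_channels={self.out_channels} not divisible by "
                f"shuffle_groups={self.shuffle_groups}")
        if not self.mixconv_kernel_sizes:
            raise ConfigurationError("LMDS: mixconv kernel list is empty")
        if any(k % 2 == 0 for k in self.mixconv_kernel_sizes):
            raise ConfigurationError("LMDS: mixconv kernels must be odd")
        if self.out_channels % len(self.mixconv_kernel_sizes):
            raise ConfigurationError(
                "LMDS: out_channels must divide into mixconv kernel groups")
        if self.out_channels % self.ghost_ratio:
            raise ConfigurationError(
                "LMDS: out_channels must be divisible by ghost_ratio")
        if self.deform_stride < 1:
            raise ConfigurationError("LMDS: deform_stride must be >= 1")


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Permute channels: index i -> (i mod g) * (C/g) + i // g."""
    N, C, H, W = x.shape
    if C % groups:
        raise ConfigurationError(
            f"channel_shuffle: {C} channels not divisible by groups={groups}")
    xg = ad.reshape(x, (N, groups, C // groups, H, W))
    xt = ad.transpose(xg, (0, 2, 1, 3, 4))
    return ad.reshape(xt, (N, C, H, W))


class GhostModule(Module):
    """Intrinsic convolution plus cheap depth-wise maps derived from it.

    Of ``out_channels`` maps, ``out_channels / ratio`` come from a dense
    primary convolution and the rest from 3x3 depth-wise transforms of those
    intrinsic maps, cutting parameters relative to a dense convolution.
    """

    def __init__(self, cfg: LMDSConfig, rng: np.random.Generator):
        super().__init__()
        cin, cout, s = cfg.in_channels, cfg.out_channels, cfg.ghost_ratio
        self.intrinsic_channels = cout // s
        self.ratio = s
        kp = cfg.ghost_primary_kernel
        self.primary = Conv2d(cin, self.intrinsic_channels, kp,
                              padding=same_padding(kp), bias=cfg.conv_bias, rng=rng)
        if s > 1:
            self.cheap = Conv2d(self.intrinsic_channels,
                                self.intrinsic_channels * (s - 1), 3,
                                padding=same_padding(3),
                                groups=self.intrinsic_channels,
                                bias=cfg.conv_bias, rng=rng)
        else:
            self.cheap = None
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        intrinsic = self.primary(x)
        if self.cheap is None:
            y = intrinsic
        else:
            y = ad.concat([intrinsic, self.cheap(intrinsic)], axis=1)
        return ad.relu(self.bn(y))


def ghost_forward(x: Tensor, cfg: LMDSConfig,
                  rng: np.random.Generator | None = None) -> Tensor:
    if x.shape[1] != cfg.in_channels:
        raise ConfigurationError(
            f"ghost module expected {cfg.in_channels} channels, got {x.shape[1]}")
    return GhostModule(cfg, rng or np.random.default_rng())(x)


class MixConv(Module):
    """Depth-wise convolution whose channel groups use different kernels."""

    def __init__(self, channels: int, kernel_sizes: tuple[int, ...],
                 bias: bool, rng: np.random.Generator):
        super().__init__()
        if not kernel_sizes:
            raise ConfigurationError("MixConv: empty kernel list")
        if any(k % 2 == 0 for k in kernel_sizes):
            raise ConfigurationError("MixConv: even kernel size has no "
                                     "symmetric same-padding")
        if channels % len(kernel_sizes):
            raise ConfigurationError(
                f"MixConv: {channels} channels not divisible into "
                f"{len(kernel_sizes)} kernel groups")
        self.group_channels = channels // len(kernel_sizes)
        self.convs = nn.ModuleList([
            Conv2d(self.group_channels, self.group_channels, k,
                   padding=same_padding(k), groups=self.group_channels,
                   bias=bias, rng=rng)
            for k in kernel_sizes])

    def forward(self, x: Tensor) -> Tensor:
        g = self.group_channels
        outs = [conv(x[:, i * g:(i + 1) * g])
                for i, conv in enumerate(self.convs)]
        return ad.concat(outs, axis=1) if len(outs) > 1 else outs[0]


class DDSC(Module):
    """Dilated depth-wise separable convolution.

    Depth-wise filter of (even) kernel size ``k`` and dilation ``d`` —
    padded bottom/right to keep the spatial size — followed by a 1x1
    point-wise mix.  Effective receptive field is (k-1)*d + 1.
    """

    def __init__(self, channels: int, cfg: LMDSConfig, rng: np.random.Generator):
        super().__init__()
        k, d = cfg.ddsc_kernel_size, cfg.ddsc_dilation
        self.depthwise = Conv2d(channels, channels, k,
                                padding=same_padding(k, d), dilation=d,
                                groups=channels, bias=cfg.depthwise_bias, rng=rng)
        self.pointwise = Conv2d(channels, channels, 1, bias=cfg.conv_bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class DeformableConv2d(Module):
    """Convolution that samples its taps at learned 2-D offsets.

    Offsets (2 per tap, per output position) are predicted by a dedicated
    zero-initialized 3x3 convolution over the block's input, so the layer
    starts out exactly equal to a regular convolution.  Sampling is bilinear
    and differentiable in both the feature values and the offsets; with
    ``stride`` > 1 the layer is the block's down-sampler.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2
        fan_in = in_channels * k * k
        self.weight = Parameter(
            rng.uniform(-1, 1, (out_channels, in_channels, k, k)) / np.sqrt(fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.offset_conv = Conv2d(in_channels, 2 * k * k, 3, stride=stride,
                                  padding=same_padding(3), bias=True, rng=rng)
        self.offset_conv.weight.data[:] = 0.0
        self.offset_conv.bias.data[:] = 0.0

    def forward(self, x: Tensor, offsets: Tensor | None = None) -> Tensor:
        if offsets is None:
            offsets = self.offset_conv(x)
        if offsets.shape[1] != 2 * self.k * self.k:
            raise ConfigurationError(
                f"deformable conv expects {2 * self.k * self.k} offset "
                f"channels, got {offsets.shape[1]}")
        return deform_sample_conv(x, offsets, self.weight, self.bias,
                                  self.k, self.stride, self.pad)


def deform_sample_conv(x: Tensor, offsets: Tensor, weight: Tensor,
                       bias: Tensor | None, k: int, stride: int,
                       pad: int) -> Tensor:
    """Bilinear-sampled convolution shared by the deformable layer."""
    N, C, H, W = x.shape
    xp = ad.pad2d(x, (pad, pad, pad, pad)) if pad else x
    Hp, Wp = H + 2 * pad, W + 2 * pad
    _, _, Ho, Wo = offsets.shape
    K = k * k
    # base tap positions in padded coordinates, shape (K, Ho, Wo)
    oy, ox = np.meshgrid(np.arange(Ho) * stride, np.arange(Wo) * stride,
                         indexing="ij")
    ky, kx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    base_y = (ky.ravel()[:, None, None] + oy[None]).astype(float)
    base_x = (kx.ravel()[:, None, None] + ox[None]).astype(float)
    off = ad.reshape(offsets, (N, K, 2, Ho, Wo))
    py = ad.clamp(ad.add(off[:, :, 0], base_y[None]), 0.0, Hp - 1)
    px = ad.clamp(ad.add(off[:, :, 1], base_x[None]), 0.0, Wp - 1)
    y0 = np.minimum(np.floor(py.data), Hp - 2).astype(np.int64)
    x0 = np.minimum(np.floor(px.data), Wp - 2).astype(np.int64)
    ty = ad.add(py, -y0)  # in [0, 1]; fractional part carries offset grads
    tx = ad.add(px, -x0)
    xf = ad.reshape(xp, (N, C, Hp * Wp))

    def corner(yi, xi):
        idx = (yi * Wp + xi).reshape(N, 1, K * Ho * Wo)
        g = ad.gather_spatial(xf, idx)
        return ad.reshape(g, (N, C, K, Ho, Wo))

    v00 = corner(y0, x0)
    v01 = corner(y0, x0 + 1)
    v10 = corner(y0 + 1, x0)
    v11 = corner(y0 + 1, x0 + 1)
    ty1 = ad.reshape(ty, (N, 1, K, Ho, Wo))
    tx1 = ad.reshape(tx, (N, 1, K, Ho, Wo))
    one = 1.0
    sampled = (v00 * ((one - ty1) * (one - tx1)) + v01 * ((one - ty1) * tx1)
               + v10 * (ty1 * (one - tx1)) + v11 * (ty1 * tx1))
    Cout = weight.shape[0]
    w2 = ad.reshape(weight, (Cout, C * K))
    s2 = ad.reshape(ad.transpose(sampled, (0, 1, 2, 3, 4)), (N, C * K, Ho * Wo))
    out = ad.matmul(w2, s2)  # (N, Cout, Ho*Wo) via broadcasting
    out = ad.reshape(out, (N, Cout, Ho, Wo))
    if bias is not None:
        out = ad.add(out, ad.reshape(bias, (1, Cout, 1, 1)))
    return out


class LMDSBlock(Module):
    """One stage of the CNN track; halves the spatial size via the
    stride-2 deformable convolution (in place of pooling)."""

    def __init__(self, cfg: LMDSConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        c = cfg.out_channels
        self.ghost = GhostModule(cfg, rng)
        self.mixconv = MixConv(c, tuple(cfg.mixconv_kernel_sizes),
                               cfg.depthwise_bias, rng)
        self.ddsc = DDSC(c, cfg, rng)
        self.deform = DeformableConv2d(c, c, cfg.deform_kernel_size,
                                       stride=cfg.deform_stride,
                                       bias=cfg.conv_bias, rng=rng)
        self.bn_out = nn.BatchNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"LMDS block expected {self.cfg.in_channels} input channels, "
                f"got {x.shape[1]}")
        g = self.ghost(x)
        branch_a = self.mixconv(channel_shuffle(g, self.cfg.shuffle_groups))
        branch_b = self.ddsc(g)
        if branch_a.shape != branch_b.shape:
            raise RuntimeError("LMDS branches disagree in shape at the merge; "
                               "branch widths are mis-configured")
        merged = ad.mul(branch_a, branch_b)  # Hadamard merge of the branches
        out = self.deform(merged)
        return ad.relu(self.bn_out(out))
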