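"""Hierarchical shifted-window transformer track.

Four stages of window-attention block pairs over a token grid that starts at
1/4 input resolution and is quartered (tokens) / doubled (width) by patch
merging between stages, ending at a 7x7 x 768 feature map for 224x224 input.

Block structure (l and l+1 form a pair):
    z_hat^l   = W-MSA(LN(z^{l-1})) + z^{l-1}
    z^l       = MLP(LN(z_hat^l))   + z_hat^l
    z_hat^l+1 = SW-MSA(LN(z^l))    + z^l
    z^l+1     = MLP(LN(z_hat^l+1)) + z_hat^l+1
with GELU in the two-layer MLP and a cyclic half-window shift plus boundary
masking in the SW-MSA step.

The reference configuration is calibrated so the track's trainable-parameter
count (with its standalone classification head) is exactly 27,512,560: all
attention and MLP linear layers are bias-free, there is no relative position
bias, patch merging carries no norm, and the patch-embedding convolution
keeps its bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .nn import Conv2d, Linear, LayerNorm, Module


@dataclass
class SwinConfig:
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: int = 4
    attn_bias: bool = False
    mlp_bias: bool = False
    patch_embed_bias: bool = True
    final_norm: bool = True
    pad_mode: bool = False  # pad-and-crop for non-divisible inputs

    @property
    def out_features(self) -> int:
        return self.embed_dim * 2 ** (len(self.depths) - 1)

    def __post_init__(self):
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must align per stage")
        if any(d % 2 for d in self.depths):
            raise ValueError("stage depths must be even (W-MSA/SW-MSA pairs)")


def wmsa_complexity(h: int, w: int, C: int, M: int) -> int:
    """Operation count of windowed attention: 4 h w C^2 + 2 M^2 h w C."""
    for v in (h, w, C, M):
        if v < 1 or int(v) != v:
            raise ValueError("complexity arguments must be positive integers")
    return 4 * h * w * C ** 2 + 2 * M ** 2 * h * w * C


class PatchEmbed(Module):
    """Non-overlapping patch partition + linear embedding (as a strided
    convolution over raw RGB values)."""

    def __init__(self, cfg: SwinConfig, in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        p = cfg.patch_size
        self.patch_size = p
        self.proj = Conv2d(in_channels, cfg.embed_dim, p, stride=p,
                           bias=cfg.patch_embed_bias, rng=rng)

    def forward(self, img: Tensor) -> Tensor:
        N, C, H, W = img.shape
        p = self.patch_size
        if H % p or W % p:
            raise ValueError(f"image size {H}x{W} not divisible by patch size {p}")
        x = self.proj(img)                       # (N, D, H/p, W/p)
        return ad.transpose(x, (0, 2, 3, 1))     # token grid (N, h, w, D)


def _window_partition(x: Tensor, M: int) -> Tensor:
    """(N, H, W, D) -> (N * nWin, M*M, D)."""
    N, H, W, D = x.shape
    x = ad.reshape(x, (N, H // M, M, W // M, M, D))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (N * (H // M) * (W // M), M * M, D))


def _window_reverse(win: Tensor, M: int, N: int, H: int, W: int) -> Tensor:
    D = win.shape[-1]
    x = ad.reshape(win, (N, H // M, W // M, M, M, D))
    x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
    return ad.reshape(x, (N, H, W, D))


def shift_attention_mask(H: int, W: int, M: int, shift: int) -> np.ndarray:
    """Additive mask (nWin, M^2, M^2): 0 where tokens share an original
    window region, -1e9 across boundaries of the cyclic shift."""
    ids = np.zeros((H, W), dtype=np.int64)
    cnt = 0
    slices = (slice(0, -M), slice(-M, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            ids[hs, ws] = cnt
            cnt += 1
    ids = np.roll(ids, (-shift, -shift), axis=(0, 1))
    ids = ids.reshape(H // M, M, W // M, M).transpose(0, 2, 1, 3)
    ids = ids.reshape(-1, M * M)
    diff = ids[:, :, None] != ids[:, None, :]
    return np.where(diff, -1e9, 0.0)


class WindowAttention(Module):
    """Multi-head self-attention restricted to M x M windows."""

    def __init__(self, dim: int, num_heads: int, bias: bool,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if dim % num_heads:
            raise ValueError("embed dim must divide the head count")
        self.dim, self.num_heads = dim, num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, bias=bias, rng=rng)
        self.proj = Linear(dim, dim, bias=bias, rng=rng)

    def forward(self, win: Tensor, mask: np.ndarray | None = None,
                return_weights: bool = False):
        B, T, D = win.shape
        h, hd = self.num_heads, self.head_dim
        qkv = ad.reshape(self.qkv(win), (B, T, 3, h, hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))        # (3, B, h, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), self.scale)
        if mask is not None:
            nw = mask.shape[0]
            m = np.tile(mask, (B // nw, 1, 1))[:, None]   # (B, 1, T, T)
            logits = ad.add(logits, m)
        attn = ad.softmax(logits, axis=-1)              # (B, h, T, T)
        out = ad.matmul(attn, v)                        # (B, h, T, hd)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, T, D))
        out = self.proj(out)
        if return_weights:
            return out, attn
        return out


class SwinBlock(Module):
    """One W-MSA or SW-MSA block with its LN/MLP residual structure."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 shifted: bool, mlp_ratio: int, attn_bias: bool,
                 mlp_bias: bool, rng: np.random.Generator | None = None):
        super().__init__()
        self.dim, self.M, self.shifted = dim, window_size, shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, attn_bias, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, bias=mlp_bias, rng=rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, bias=mlp_bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, D = x.shape
        M = min(self.M, H, W)  # a window larger than the grid degenerates
        if H % M or W % M:
            raise ValueError(f"token grid {H}x{W} not divisible by window {M}")
        shift = M // 2 if (self.shifted and (H > M or W > M)) else 0
        y = self.norm1(x)
        if shift:
            y = ad.roll2d(y, (-shift, -shift))
            mask = shift_attention_mask(H, W, M, shift)
        else:
            mask = None
        win = _window_partition(y, M)
        win = self.attn(win, mask)
        y = _window_reverse(win, M, N, H, W)
        if shift:
            y = ad.roll2d(y, (shift, shift))
        x = ad.add(x, y)
        z = self.fc2(ad.gelu(self.fc1(self.norm2(x))))
        return ad.add(x, z)


class PatchMerging(Module):
    """Concatenate 2x2 neighbouring tokens (4C) and reduce linearly to 2C;
    quarters the token count."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.dim = dim
        self.reduction = Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, D = x.shape
        if H % 2 or W % 2:
            raise ValueError("patch merging needs an even token grid")
        x = ad.reshape(x, (N, H // 2, 2, W // 2, 2, D))
        x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
        x = ad.reshape(x, (N, H // 2, W // 2, 4 * D))
        return self.reduction(x)


class SwinTrack(Module):
    """The full transformer track: patch embed, four stages of block pairs
    with merging between stages, final LN; outputs an NCHW feature map of
    width ``cfg.out_features`` at 1/32 input resolution."""

    def __init__(self, cfg: SwinConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg or SwinConfig()
        rng = rng or np.random.default_rng()
        self.patch_embed = PatchEmbed(cfg, rng=rng)
        self.stages = nn.ModuleList()
        self.merges = nn.ModuleList()
        dim = cfg.embed_dim
        for si, (depth, heads) in enumerate(zip(cfg.depths, cfg.num_heads)):
            blocks = nn.ModuleList([
                SwinBlock(dim, heads, cfg.window_size, shifted=bool(b % 2),
                          mlp_ratio=cfg.mlp_ratio, attn_bias=cfg.attn_bias,
                          mlp_bias=cfg.mlp_bias, rng=rng)
                for b in range(depth)])
            self.stages.append(blocks)
            if si < len(cfg.depths) - 1:
                self.merges.append(PatchMerging(dim, rng=rng))
                dim *= 2
        self.norm = LayerNorm(dim) if cfg.final_norm else None

    def forward(self, img: Tensor) -> Tensor:
        cfg = self.cfg
        N, C, H, W = img.shape
        divisor = cfg.patch_size * 2 ** (len(cfg.depths) - 1)
        if (H % divisor or W % divisor) and not cfg.pad_mode:
            raise ValueError(
                f"input {H}x{W} must be divisible by {divisor} "
                f"(patch size x 2^stages); enable pad_mode to pad-and-crop")
        if cfg.pad_mode:
            ph = (-H) % divisor
            pw = (-W) % divisor
            if ph or pw:
                img = ad.pad2d(img, (0, ph, 0, pw))
        x = self.patch_embed(img)
        for si, blocks in enumerate(self.stages):
            for block in blocks:
                x = block(x)
            if si < len(self.stages) - 1:
                x = self.merges[si](x)
        if self.norm is not None:
            x = self.norm(x)
        return ad.transpose(x, (0, 3, 1, 2))   # (N, 768, H/32, W/32)
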