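"""Neural-network layers over the autodiff engine.

Covers what the dual-track classifier needs: linear and grouped-conv layers,
batch/layer/group normalization, dropout, pooling.  Initialization follows
the usual fan-in scaling and every module draws from an explicit
``numpy.random.Generator`` so whole networks are seed-reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Composable container with named parameters and train/eval modes."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for n, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                pass  # running stats handled below via buffers
        # buffers (running stats) are exported with a reserved suffix
        for name, m in self._walk(""):
            if isinstance(m, BatchNorm2d):
                out[f"{name}running_mean!"] = m.running_mean.copy()
                out[f"{name}running_var!"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.endswith("!"):
                continue
            if params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data = np.asarray(v, dtype=ad.DTYPE)
        for name, m in self._walk(""):
            if isinstance(m, BatchNorm2d):
                if f"{name}running_mean!" in state:
                    m.running_mean = np.asarray(state[f"{name}running_mean!"],
                                                dtype=ad.DTYPE)
                    m.running_var = np.asarray(state[f"{name}running_var!"],
                                               dtype=ad.DTYPE)

    def _walk(self, prefix: str):
        yield prefix, self
        for n, m in self._modules.items():
            yield from m._walk(f"{prefix}{n}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module, trainable_only: bool = True) -> int:
    """Total number of parameter elements in ``module``."""
    return sum(p.size for p in module.parameters()
               if (p.requires_grad or not trainable_only))


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = []
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
            self._list.append(m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(_kaiming(rng, (out_features,), in_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = ad.add(y, self.bias)
        return y


class Conv2d(Module):
    """Grouped conv with explicit 4-way padding (top, bottom, left, right)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride: int = 1, padding=(0, 0, 0, 0), dilation: int = 1,
                 groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if isinstance(padding, int):
            padding = (padding,) * 4
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(_kaiming(rng, (out_channels,), fan_in)) if bias else None
        self.stride, self.padding, self.dilation, self.groups = \
            stride, tuple(padding), dilation, groups
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                         self.dilation, self.groups)


def same_padding(k: int, dilation: int = 1) -> tuple[int, int, int, int]:
    """Symmetric same-padding for odd kernels; even kernels pad only
    bottom/right (output size equals input size at stride 1)."""
    eff = (k - 1) * dilation
    if k % 2:
        p = eff // 2
        return (p, p, p, p)
    return (0, eff, 0, eff)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = ad.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ad.tmean(ad.power(ad.add(x, ad.mul(mean, -1.0)), 2.0),
                           axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = ad.mul(ad.add(x, ad.mul(mean, -1.0)),
                      ad.power(ad.add(var, self.eps), -0.5))
        w = ad.reshape(self.weight, (1, -1, 1, 1))
        b = ad.reshape(self.bias, (1, -1, 1, 1))
        return ad.add(ad.mul(xhat, w), b)


class LayerNorm(Module):
    """Normalizes over the last dimension (token embeddings)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = ad.tmean(x, axis=-1, keepdims=True)
        centered = ad.add(x, ad.mul(mean, -1.0))
        var = ad.tmean(ad.power(centered, 2.0), axis=-1, keepdims=True)
        xhat = ad.mul(centered, ad.power(ad.add(var, self.eps), -0.5))
        return ad.add(ad.mul(xhat, self.weight), self.bias)


class GroupNorm(Module):
    """Group normalization over NCHW maps."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5,
                 affine: bool = True):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide groups")
        self.num_groups, self.eps = num_groups, eps
        if affine:
            self.weight = Parameter(np.ones(num_channels))
            self.bias = Parameter(np.zeros(num_channels))
        else:
            self.weight = self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.num_groups
        xg = ad.reshape(x, (N, g, C // g, H, W))
        mean = ad.tmean(xg, axis=(2, 3, 4), keepdims=True)
        centered = ad.add(xg, ad.mul(mean, -1.0))
        var = ad.tmean(ad.power(centered, 2.0), axis=(2, 3, 4), keepdims=True)
        xhat = ad.mul(centered, ad.power(ad.add(var, self.eps), -0.5))
        xhat = ad.reshape(xhat, (N, C, H, W))
        if self.weight is not None:
            w = ad.reshape(self.weight, (1, C, 1, 1))
            b = ad.reshape(self.bias, (1, C, 1, 1))
            xhat = ad.add(ad.mul(xhat, w), b)
        return xhat


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return ad.mul(x, Tensor(mask))


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial grid."""
    return ad.tmean(x, axis=(2, 3))
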