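"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the wound-classification network
needs: broadcast-aware arithmetic, batched matmul, reductions, shape ops,
grouped/strided/dilated 2-D convolution, and a differentiable ``take`` used
by the bilinear-sampling operators (deformable convolution, learnable-spacing
kernels).  Gradients are accumulated by topological traversal of the recorded
tape; float64 is used throughout so oracle comparisons are tight.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "retains_grad")
    __array_priority__ = 100  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self.retains_grad = False
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def retain_grad(self) -> "Tensor":
        self.retains_grad = True
        return self

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without argument needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep networks overflow recursion
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=DTYPE)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and (node._backward is None or node.retains_grad):
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    # convenience reductions / shapes
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list[tuple[Tensor, np.ndarray]]]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))]

    return _make(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return [(a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape))]

    return _make(out, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p

    def backward(g):
        return [(a, g * p * a.data ** (p - 1))]

    return _make(out, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return [(a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape))]

    return _make(out, (a, b), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return [(a, g * out)]

    return _make(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        return [(a, g / a.data)]

    return _make(out, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def erf(a) -> Tensor:
    from scipy.special import erf as _erf
    a = as_tensor(a)
    out = _erf(a.data)

    def backward(g):
        return [(a, g * (2.0 / math.sqrt(math.pi)) * np.exp(-a.data ** 2))]

    return _make(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out = a.data * mask

    def backward(g):
        return [(a, g * mask)]

    return _make(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return [(a, g * out * (1.0 - out))]

    return _make(out, (a,), backward)


def gelu(a) -> Tensor:
    """Exact (erf-based) GELU."""
    a = as_tensor(a)
    return mul(mul(a, 0.5), add(erf(mul(a, 1.0 / math.sqrt(2.0))), 1.0))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return [(a, np.broadcast_to(g, a.shape).copy())]
        g2 = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            for ax in sorted(axes):
                g2 = np.expand_dims(g2, ax)
        return [(a, np.broadcast_to(g2, a.shape).copy())]

    return _make(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax]
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def backward(g):
        return [(a, g.reshape(a.shape))]

    return _make(out, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return [(a, g.transpose(inv))]

    return _make(out, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        return list(zip(ts, pieces))

    return _make(out, tuple(ts), backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)
    out = a.data[key]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, key, g)
        return [(a, full)]

    return _make(out, (a,), backward)


def pad2d(a, pads: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad an NCHW tensor: pads = (top, bottom, left, right)."""
    a = as_tensor(a)
    pt, pb, pl, pr = pads
    out = np.pad(a.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))

    def backward(g):
        H, W = a.shape[2], a.shape[3]
        return [(a, g[:, :, pt:pt + H, pl:pl + W])]

    return _make(out, (a,), backward)


def take(a, indices: np.ndarray, axis: int) -> Tensor:
    """Differentiable ``np.take`` with a constant integer index array."""
    a = as_tensor(a)
    out = np.take(a.data, indices, axis=axis)

    def backward(g):
        full = np.zeros_like(a.data)
        sl = [slice(None)] * a.ndim
        np.add.at(full, tuple(sl[:axis]) + (indices,), g)
        return [(a, full)]

    return _make(out, (a,), backward)


def gather_spatial(a, indices: np.ndarray) -> Tensor:
    """Gather along the flattened-position axis of an (N, C, P) tensor.

    ``indices`` is an integer array broadcastable to (N, C, K); gradients
    scatter-add back to the gathered positions.  This is the backbone of the
    bilinear-sampling operators.
    """
    a = as_tensor(a)
    N, C, P = a.shape
    idx = np.broadcast_to(indices, (N, C) + indices.shape[2:]).astype(np.int64)
    out = np.take_along_axis(a.data, idx, axis=2)

    def backward(g):
        full = np.zeros_like(a.data)
        ni = np.arange(N)[:, None, None]
        ci = np.arange(C)[None, :, None]
        np.add.at(full, (ni, ci, idx), g)
        return [(a, full)]

    return _make(out, (a,), backward)


def roll2d(a, shift: tuple[int, int]) -> Tensor:
    """Cyclic shift of axes (1, 2) of an (N, H, W, D) tensor."""
    a = as_tensor(a)
    out = np.roll(a.data, shift, axis=(1, 2))

    def backward(g):
        return [(a, np.roll(g, (-shift[0], -shift[1]), axis=(1, 2)))]

    return _make(out, (a,), backward)


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient strictly inside the interval."""
    return add(relu(add(a, -lo)), lo) - relu(add(a, -hi))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = add(a, -a.data.max(axis=axis, keepdims=True))  # max is constant
    e = exp(shifted)
    return mul(e, power(tsum(e, axis, keepdims=True), -1.0))


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = add(a, -a.data.max(axis=axis, keepdims=True))
    return add(shifted, mul(log(tsum(exp(shifted), axis, keepdims=True)), -1.0))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _window_view(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
                 dh: int, dw: int) -> np.ndarray:
    """Strided sliding windows of an NCHW array -> (N,C,Ho,Wo,kh,kw)."""
    eh, ew = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    v = np.lib.stride_tricks.sliding_window_view(x, (eh, ew), axis=(2, 3))
    v = v[:, :, ::sh, ::sw, ::dh, ::dw]
    return v


def conv2d(x, weight, bias=None, stride: int | tuple = 1,
           padding: tuple[int, int, int, int] = (0, 0, 0, 0),
           dilation: int | tuple = 1, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution.

    ``x``: (N, Cin, H, W); ``weight``: (Cout, Cin/groups, kh, kw);
    ``padding`` is explicit (top, bottom, left, right) so even kernels can
    pad asymmetrically.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
    Cout, Cin_g, kh, kw = weight.shape
    N, Cin, H, W = x.shape
    if Cin != Cin_g * groups:
        raise ValueError(f"conv2d: input has {Cin} channels, weight expects "
                         f"{Cin_g * groups} (groups={groups})")
    if Cout % groups:
        raise ValueError("conv2d: out channels not divisible by groups")

    xp = pad2d(x, padding) if any(padding) else x
    v = _window_view(xp.data, kh, kw, sh, sw, dh, dw)  # N,Cin,Ho,Wo,kh,kw
    Ho, Wo = v.shape[2], v.shape[3]
    G, Cog = groups, Cout // groups
    vg = v.reshape(N, G, Cin_g, Ho, Wo, kh, kw)
    wg = weight.data.reshape(G, Cog, Cin_g, kh, kw)
    out = np.einsum("ngchwkl,gockl->ngohw", vg, wg, optimize=True)
    out = out.reshape(N, Cout, Ho, Wo)

    def backward(g):
        gg = g.reshape(N, G, Cog, Ho, Wo)
        gw = np.einsum("ngohw,ngchwkl->gockl", gg, vg, optimize=True)
        gw = gw.reshape(weight.shape)
        # grad wrt (padded) input: scatter each tap's contribution
        gx = np.zeros_like(xp.data)
        gxg = gx.reshape(N, G, Cin_g, *gx.shape[2:])
        for ki in range(kh):
            for kj in range(kw):
                # contribution of tap (ki,kj) lands at rows ki*dh + sh*i
                contrib = np.einsum("ngohw,goc->ngchw", gg, wg[:, :, :, ki, kj],
                                    optimize=True)
                gxg[:, :, :,
                    ki * dh: ki * dh + sh * Ho: sh,
                    kj * dw: kj * dw + sw * Wo: sw] += contrib
        pt, pb, pl, pr = padding
        gx_in = gx[:, :, pt:pt + H, pl:pl + W]
        return [(x, gx_in), (weight, gw)]

    out_t = _make(out, (x, weight), backward)
    if bias is not None:
        out_t = add(out_t, reshape(as_tensor(bias), (1, Cout, 1, 1)))
    return out_t


def nll_loss(log_probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; ``targets`` are integer class ids."""
    n = log_probs.shape[0]
    picked = getitem(log_probs, (np.arange(n), np.asarray(targets)))
    return mul(tsum(picked), -1.0 / n)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    return nll_loss(log_softmax(logits, axis=-1), targets)
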