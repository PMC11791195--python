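"""Grad-CAM saliency maps.

Channel weights are the spatial means of the target-class score's gradient
at the chosen activation layer (default: the shuffle-attention output, the
network's last convolutional representation); the map is the ReLU of the
weighted channel sum, bilinearly upsampled to the input resolution and
min-max normalized to [0, 1].  If every pre-ReLU value is non-positive the
heat map is defined as all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Module


@dataclass
class HeatMap:
    values: np.ndarray          # (H, W) in [0, 1] at input resolution
    target_class: int
    raw: np.ndarray             # pre-normalization ReLU'd map at layer size


def bilinear_resize(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Align-corners bilinear upsampling of a 2-D array."""
    h, w = arr.shape
    if (h, w) == (out_h, out_w):
        return arr.copy()
    ys = np.linspace(0, h - 1, out_h)
    xs = np.linspace(0, w - 1, out_w)
    y0 = np.minimum(np.floor(ys).astype(int), h - 2) if h > 1 else np.zeros(out_h, int)
    x0 = np.minimum(np.floor(xs).astype(int), w - 2) if w > 1 else np.zeros(out_w, int)
    ty = (ys - y0) if h > 1 else np.zeros(out_h)
    tx = (xs - x0) if w > 1 else np.zeros(out_w)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    a = arr[np.ix_(y0, x0)] * np.outer(1 - ty, 1 - tx)
    b = arr[np.ix_(y0, x1)] * np.outer(1 - ty, tx)
    c = arr[np.ix_(y1, x0)] * np.outer(ty, 1 - tx)
    d = arr[np.ix_(y1, x1)] * np.outer(ty, tx)
    return a + b + c + d


def grad_cam(model: Module, img: np.ndarray | Tensor, target_class: int,
             features_attr: str = "_sa_features") -> HeatMap:
    """Saliency for ``target_class`` on a single image (1, C, H, W).

    ``model`` must retain its target-layer activations (with gradient) in
    the attribute named by ``features_attr`` during forward — the fused
    classifier exposes its shuffle-attention output that way.  Model weights
    are left untouched.
    """
    x = img if isinstance(img, Tensor) else Tensor(np.asarray(img))
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("grad_cam expects a single image batch (1, C, H, W)")
    model.eval()
    logits = model(x)
    n_classes = logits.shape[-1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target class {target_class} outside 0..{n_classes - 1}")
    feats = getattr(model, features_attr, None)
    if feats is None or not isinstance(feats, Tensor):
        raise AttributeError(
            f"model does not expose activations via {features_attr!r}")
    model.zero_grad()
    feats.grad = None
    onehot = np.zeros(logits.shape)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    grads = feats.grad[0]                       # (C, h, w)
    acts = feats.data[0]
    weights = grads.mean(axis=(1, 2))           # w_k = GAP of d score / d A_k
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    full = bilinear_resize(cam, x.shape[2], x.shape[3])
    lo, hi = full.min(), full.max()
    norm = (full - lo) / (hi - lo) if hi > lo else np.zeros_like(full)
    return HeatMap(values=norm, target_class=target_class, raw=cam)


def save_heatmap_overlay(heatmap: HeatMap, image_rgb: np.ndarray,
                         path: str, alpha: float = 0.45) -> None:
    """PNG overlay using a blue-to-red colormap with a color bar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(4.2, 4))
    axis.imshow(image_rgb)
    im = axis.imshow(heatmap.values, cmap="jet", vmin=0, vmax=1, alpha=alpha)
    axis.set_axis_off()
    fig.colorbar(im, ax=axis, fraction=0.046)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
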