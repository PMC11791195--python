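"""Synthetic four-class wound-image generator and split/augmentation logic.

The generator emulates the data regime of the study dataset — close-up
224x224 RGB photographs labelled {none, infection, ischemia, both} — with
classes made separable by construction: each class has its own hue range,
lesion blob statistics, texture frequency and rim colour (an
erythema-like red rim for infection, a pallor rim for ischemia, both for
the combined class).  It is plumbing for desk-scale experiments, not a
photorealistic wound model.

The split/augmentation bookkeeping mirrors the published protocol: a
stratified 60/20/20 split, then four augmented copies (random vertical and
horizontal flips and a rotation drawn from {0, 90, 270} degrees — all
lossless right-angle ops) added for every train and validation original of
the two minority classes (ischemia, both), with the test set untouched.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("none", "infection", "ischemia", "both")
MINORITY_CLASSES = ("ischemia", "both")
AUG_COPIES = 4
ROTATIONS = (0, 90, 270)

#: per-class before-augmentation counts (train, val, test) of the study's
#: class-wise table; used as the bookkeeping ground truth.
STUDY_SPLIT_COUNTS = {
    "none": (1631, 510, 511),
    "infection": (1533, 511, 511),
    "ischemia": (136, 45, 46),
    "both": (372, 124, 125),
}


@dataclass
class SyntheticClassSpec:
    name: str
    hue: tuple[float, float]            # base hue range (HSV, 0..1)
    blob_count: tuple[int, int]         # min/max lesion blobs
    blob_sigma: tuple[float, float]     # blob size range (pixels)
    texture_freq: float                 # cycles across the image
    red_rim: bool = False               # erythema-like rim
    pale_rim: bool = False              # ischemic pallor rim


DEFAULT_CLASS_SPECS = {
    "none": SyntheticClassSpec("none", hue=(0.05, 0.09), blob_count=(0, 1),
                               blob_sigma=(6, 10), texture_freq=3.0),
    "infection": SyntheticClassSpec("infection", hue=(0.98, 1.02),
                                    blob_count=(2, 4), blob_sigma=(12, 22),
                                    texture_freq=8.0, red_rim=True),
    "ischemia": SyntheticClassSpec("ischemia", hue=(0.55, 0.62),
                                   blob_count=(2, 4), blob_sigma=(10, 18),
                                   texture_freq=14.0, pale_rim=True),
    "both": SyntheticClassSpec("both", hue=(0.78, 0.84), blob_count=(3, 6),
                               blob_sigma=(8, 16), texture_freq=20.0,
                               red_rim=True, pale_rim=True),
}


def _hsv_to_rgb(h, s, v):
    h = np.mod(h, 1.0) * 6.0
    i = np.floor(h)
    f = h - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    i = (i.astype(int) % 6)[..., None]
    out = np.select(
        [i == 0, i == 1, i == 2, i == 3, i == 4, i == 5],
        [np.stack([v, t, p], -1), np.stack([q, v, p], -1),
         np.stack([p, v, t], -1), np.stack([p, q, v], -1),
         np.stack([t, p, v], -1), np.stack([v, p, q], -1)])
    return out


def render_class_image(spec: SyntheticClassSpec, rng: np.random.Generator,
                       size: int = 224) -> np.ndarray:
    """One uint8 HxWx3 image drawn from a class specification."""
    yy, xx = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size),
                         indexing="ij")
    # skin-tone base with class-specific oriented texture
    base_h = 0.07 + rng.uniform(-0.01, 0.01)
    theta = rng.uniform(0, np.pi)
    carrier = np.sin(2 * np.pi * spec.texture_freq
                     * (np.cos(theta) * xx + np.sin(theta) * yy)
                     + rng.uniform(0, 2 * np.pi))
    v = 0.75 + 0.08 * carrier + 0.05 * rng.standard_normal((size, size))
    h = np.full((size, size), base_h)
    s = np.full((size, size), 0.35)
    # lesion blobs in the class hue, with optional rims
    nblob = rng.integers(spec.blob_count[0], spec.blob_count[1] + 1)
    for _ in range(int(nblob)):
        cy, cx = rng.uniform(0.2, 0.8, 2)
        sig = rng.uniform(*spec.blob_sigma) / size
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        core = np.exp(-r2 / (2 * sig ** 2))
        hue = rng.uniform(*spec.hue)
        h = np.where(core > 0.4, hue, h)
        s = np.where(core > 0.4, 0.75, s)
        v = np.where(core > 0.4, v * 0.85, v)
        rim = (core > 0.12) & (core <= 0.4)
        if spec.red_rim:
            h, s = np.where(rim, 0.0, h), np.where(rim, 0.85, s)
        if spec.pale_rim:
            s, v = np.where(rim, 0.08, s), np.where(rim, 0.95, v)
    rgb = _hsv_to_rgb(h, np.clip(s, 0, 1), np.clip(v, 0, 1))
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def generate_synthetic_dataset(class_counts: dict[str, int], seed: int,
                               size: int = 224,
                               specs: dict[str, SyntheticClassSpec] | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Images (N, size, size, 3) uint8 and integer labels in class order
    {none, infection, ischemia, both}.  Identical seeds give identical bytes.
    """
    specs = specs or DEFAULT_CLASS_SPECS
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for ci, name in enumerate(CLASS_NAMES):
        n = int(class_counts.get(name, 0))
        if n < 1:
            raise ValueError(f"class {name!r} needs at least one image")
        for _ in range(n):
            images.append(render_class_image(specs[name], rng, size))
            labels.append(ci)
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def dataset_checksum(images: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(images).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def apply_aug_op(img: np.ndarray, vflip: bool, hflip: bool,
                 rotation: int) -> np.ndarray:
    """Apply a specific (vflip, hflip, rotation) op; lossless right angles."""
    if rotation not in ROTATIONS:
        raise ValueError(f"rotation must be one of {ROTATIONS}")
    if rotation and img.shape[0] != img.shape[1]:
        raise ValueError("right-angle rotation of a non-square image would "
                         "change its shape")
    out = img
    if vflip:
        out = out[::-1]
    if hflip:
        out = out[:, ::-1]
    if rotation:
        out = np.rot90(out, k=rotation // 90)
    return np.ascontiguousarray(out)


def augment_image(img: np.ndarray, rng: np.random.Generator
                  ) -> tuple[np.ndarray, str]:
    """Independently sampled vertical flip, horizontal flip and rotation
    from {0, 90, 270} degrees; returns the image and an op descriptor."""
    vflip = bool(rng.integers(2))
    hflip = bool(rng.integers(2))
    rotation = int(ROTATIONS[rng.integers(len(ROTATIONS))])
    out = apply_aug_op(img, vflip, hflip, rotation)
    return out, f"v{int(vflip)}h{int(hflip)}r{rotation}"


# ---------------------------------------------------------------------------
# splits and balancing
# ---------------------------------------------------------------------------

@dataclass
class SplitRecord:
    index: int            # row in the images array of the split
    origin: int           # index of the origin image in the source dataset
    label: int
    split: str            # train | val | test
    provenance: str       # "original" or "augmented-from:<origin>:<op>"


@dataclass
class DatasetSplit:
    images: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    records: list[SplitRecord] = field(default_factory=list)
    seed: int | None = None

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for name in ("train", "val", "test"):
            y = self.labels.get(name)
            out[name] = {c: int((y == i).sum())
                         for i, c in enumerate(CLASS_NAMES)} if y is not None else {}
        return out


def balance_counts(before: dict[str, tuple[int, int, int]],
                   copies: int = AUG_COPIES,
                   minority: tuple[str, ...] = MINORITY_CLASSES
                   ) -> dict[str, tuple[int, int, int]]:
    """After-augmentation (train, val, test) cells from before-augmentation
    cells: minority train/val multiply by (copies + 1), everything else is
    unchanged and test never grows."""
    after = {}
    for name, (tr, va, te) in before.items():
        if name in minority:
            after[name] = (tr * (copies + 1), va * (copies + 1), te)
        else:
            after[name] = (tr, va, te)
    return after


def stratified_split(labels: np.ndarray, seed: int,
                     fractions: tuple[float, float] = (0.6, 0.2)
                     ) -> dict[str, np.ndarray]:
    """Seeded per-class shuffle into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for ci in range(len(CLASS_NAMES)):
        idx = np.flatnonzero(labels == ci)
        if len(idx) < 5:
            warnings.warn(f"class {CLASS_NAMES[ci]!r} has only {len(idx)} "
                          f"images; the split will be degenerate")
        rng.shuffle(idx)
        n_tr = int(round(fractions[0] * len(idx)))
        n_va = int(round(fractions[1] * len(idx)))
        parts["train"] += list(idx[:n_tr])
        parts["val"] += list(idx[n_tr:n_tr + n_va])
        parts["test"] += list(idx[n_tr + n_va:])
    return {k: np.asarray(sorted(v), dtype=np.int64) for k, v in parts.items()}


def make_splits_and_balance(images: np.ndarray, labels: np.ndarray, seed: int,
                            copies: int = AUG_COPIES,
                            minority: tuple[str, ...] = MINORITY_CLASSES
                            ) -> DatasetSplit:
    """Stratified 60/20/20 split, then ``copies`` augmented images for every
    train and validation original of the minority classes.  Test images are
    never augmented and no origin image appears in two splits."""
    part = stratified_split(labels, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    minority_ids = {CLASS_NAMES.index(m) for m in minority}
    split = DatasetSplit(seed=seed)
    for name in ("train", "val", "test"):
        imgs, labs = [], []
        for origin in part[name]:
            rec = SplitRecord(len(imgs), int(origin), int(labels[origin]),
                              name, "original")
            imgs.append(images[origin])
            labs.append(labels[origin])
            split.records.append(rec)
            if name != "test" and copies and labels[origin] in minority_ids:
                for _ in range(copies):
                    aug, op = augment_image(images[origin], rng)
                    split.records.append(SplitRecord(
                        len(imgs), int(origin), int(labels[origin]), name,
                        f"augmented-from:{int(origin)}:{op}"))
                    imgs.append(aug)
                    labs.append(labels[origin])
        split.images[name] = np.stack(imgs)
        split.labels[name] = np.asarray(labs, dtype=np.int64)
    return split


def normalization_stats(train_images: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of the training split (images in [0, 255])."""
    x = train_images.astype(np.float64) / 255.0
    return x.mean(axis=(0, 1, 2)), x.std(axis=(0, 1, 2))


def to_model_input(images: np.ndarray, mean: np.ndarray,
                   std: np.ndarray) -> np.ndarray:
    """HWC uint8 batch -> normalized NCHW float batch."""
    x = images.astype(np.float64) / 255.0
    x = (x - mean) / np.maximum(std, 1e-8)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
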