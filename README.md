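# dfunet

A dual-track deep network for classifying diabetic foot ulcer (DFU)
photographs into four complication classes — **none**, **infection**,
**ischemia**, **both** — together with the tooling needed to study the
architecture at desk scale: a synthetic wound-image generator, the
split/augmentation bookkeeping of the study protocol, a training and
evaluation harness, and Grad-CAM explainability.

The package is self-contained scientific Python: the network, including
every exotic operator, runs on a small reverse-mode autodiff engine built
on numpy (float64), so forward passes, gradients, training and attribution
need no deep-learning framework.

## The model

Two feature extractors run in parallel on a 224×224 RGB image:

* **Transformer track** — a hierarchical shifted-window transformer.
  4×4 patches are linearly embedded (dim 96) and processed by four stages
  of window-attention block pairs (depths 2/2/6/2, heads 3/6/12/24,
  window M = 7), with patch merging between stages quartering tokens and
  doubling width. Each pair follows the residual scheme
  ẑˡ = W-MSA(LN(zˡ⁻¹)) + zˡ⁻¹, zˡ = MLP(LN(ẑˡ)) + ẑˡ, then the same with
  the shifted-window attention SW-MSA (cyclic ⌊M/2⌋ shift plus boundary
  masking). Per-window attention cost is Ω(W-MSA) = 4hwC² + 2M²hwC.
  Output: a 7×7×768 feature map.

* **CNN track (EMADN)** — five cascaded (LMDS → GDA) stages.
  The LMDS block chains a ghost module (dense + cheap depth-wise maps),
  a channel-shuffle + mixed-kernel depth-wise branch and a dilated
  depth-wise-separable branch merged by Hadamard product, and a stride-2
  deformable convolution as the down-sampler. The GDA block composes a
  global context block (softmax attention pooling αⱼ = exp(Wₖxⱼ)/Σexp(Wₖxₘ)
  with a layer-normalized bottleneck residual), a dilated convolution with
  learnable element spacings, and coordinate attention
  (y_c(i,j) = x_c(i,j)·g^h_c(i)·g^w_c(j) from row/column pooled profiles).
  Output: a 7×7×150 feature map.

The maps are concatenated (918 channels, transformer channels first),
refined by **shuffle attention** — grouped channel gates σ(W₁s + b₁) and
spatial gates σ(W₂·GN(x) + b₂) with parameters shared across groups
(3C/G = 918 parameters at G = 3) — then global-average-pooled and
classified by a ReLU hidden layer with dropout 0.6 and cross-entropy loss.

Every width the architecture description leaves open is pinned by the five
published model sizes; the frozen configuration reproduces all of them
exactly (see `scripts/calibrate_counts.py` and `docs/methods.md`).

## Worked example

```python
import numpy as np
from dfunet import (build_variant, count_parameters, wmsa_complexity,
                    generate_synthetic_dataset, make_splits_and_balance)

for v in ("full", "no-sa", "swin", "emadn", "emadn-no-gda"):
    print(f"{v:14s}{count_parameters(build_variant(v, seed=0)):>12,}")
print(wmsa_complexity(56, 56, 96, 7))

imgs, labels = generate_synthetic_dataset(
    {"none": 40, "infection": 40, "ischemia": 12, "both": 12}, seed=7)
split = make_splits_and_balance(imgs, labels, seed=7)
print(split.counts()["train"])
```

prints

```
full            29,161,395
no-sa           29,160,477
swin            27,512,560
emadn              707,373
emadn-no-gda       411,990
145108992
{'none': 24, 'infection': 24, 'ischemia': 35, 'both': 35}
```

The five counts are the trainable-parameter sizes of the published model
variants, reproduced exactly by construction; their differences isolate
the shuffle-attention block (918 parameters) and the GDA blocks (295,383).
`145108992` is the stage-one windowed-attention operation count
(h = w = 56, C = 96, M = 7). The split counts show the ×5 minority
expansion: 7 ischemia training originals become 35 (each spawns four
flip/rotation copies), while majority classes keep their 60% share and the
test set is untouched.

A command-line interface mirrors the library
(`dfunet gen-data | train | evaluate | gridsearch | count-params |
complexity | explain`); run `dfunet --help` for details.

## Layout

| module | contents |
| --- | --- |
| `dfunet.autodiff` | numpy reverse-mode autodiff (conv2d, gather, roll, …) |
| `dfunet.nn` | layers: Linear, Conv2d, BatchNorm/LayerNorm/GroupNorm, Dropout |
| `dfunet.conv_blocks` | ghost module, channel shuffle, MixConv, DDSC, deformable conv, LMDS |
| `dfunet.attention_blocks` | global context block, DCLS, coordinate attention, GDA, shuffle attention |
| `dfunet.swin` | patch embed, W-MSA/SW-MSA block pairs, patch merging, complexity |
| `dfunet.assembly` | track assembly, fusion, classifier, parameter counting |
| `dfunet.synthetic` | 4-class image generator, augmentation, split bookkeeping |
| `dfunet.training` | SGD/Adam + step scheduler, grid search, metrics/ROC/PR |
| `dfunet.explain` | Grad-CAM heat maps |
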