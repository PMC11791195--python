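# Methods

## Problem and model

The package implements a dual-track classifier for diabetic foot ulcer
(DFU) photographs labelled {none, infection, ischemia, both}. The design
premise is complementarity: a hierarchical shifted-window transformer
captures long-range context while a lightweight multi-scale CNN (EMADN)
captures fine local texture; their 7×7 feature maps (768 and 150 channels
for 224×224 input) are concatenated, refined by shuffle attention, pooled
and classified.

### Transformer track

Standard shifted-window design: 4×4 patch embedding to width 96; four
stages of attention block pairs (depths 2/2/6/2, heads 3/6/12/24, window
M = 7, MLP ratio 4); patch merging (2×2 concatenation, linear 4C→2C)
between stages; a final LayerNorm. The W-MSA/SW-MSA pair follows the
residual structure

    ẑ  = W-MSA(LN(z)) + z        z' = MLP(LN(ẑ)) + ẑ

and the same with the ⌊M/2⌋-shifted, boundary-masked attention. The
shifted variant cyclically rolls the token grid, partitions into windows,
and adds −10⁹ to logits between tokens whose pre-shift window regions
differ, so no attention mass leaks across boundaries (verified < 1e-8).
A window larger than the grid degrades gracefully to full-grid attention;
input sizes not divisible by 32 are rejected unless `pad_mode` is set
(zero pad to the next multiple).

### CNN track (EMADN)

Five stages of (LMDS → GDA), each LMDS halving the spatial size so the
track meets the transformer at 7×7. Within an LMDS block:

* ghost module — a dense primary 3×3 convolution produces half the output
  channels, cheap depth-wise 3×3 transforms of those maps produce the
  rest (ratio 2); batch norm + ReLU follow the concatenation;
* branch A — channel shuffle (2 groups) then mixed depth-wise kernels
  (sizes 3 and 5, one per half of the channels, symmetric same-padding);
* branch B — dilated depth-wise separable convolution: depth-wise k = 2,
  dilation 2 (receptive field 3), then a 1×1 point-wise mix. The even
  kernel pads bottom/right only, keeping the spatial size;
* merge — Hadamard product of the branches (both are built at the same
  width precisely so the element-wise product is defined);
* down-sampling — a stride-2 deformable convolution instead of pooling.
  Offsets (2 per tap and output position) come from a dedicated 3×3
  convolution over the merged features, zero-initialized so training
  starts as a regular convolution; sampling is bilinear and
  differentiable in both features and offsets. The reference
  configuration uses a 1×1 deformable kernel — a learned content-
  dependent warp — which is what the published track size admits.

The GDA block composes, at constant width:

* global context block — spatial softmax attention pooling
  αⱼ = softmax(Wₖxⱼ) giving a per-channel context vector z = Σαⱼxⱼ,
  transformed by a bottleneck W_v2 ReLU(LN(W_v1 z)) (reduction 2, no
  biases) and added back to every position;
* DCLS — a depth-wise convolution whose kernel elements live at
  continuous per-channel 2-D positions inside a 7×7 extent, sampled
  bilinearly; positions are trainable parameters, clamped to the extent.
  Because positions are shared over the spatial grid, the layer is
  evaluated as at most extent² integer-shifted scaled copies of the
  input with analytic gradients — memory stays flat regardless of the
  element count;
* coordinate attention — row and column mean profiles, concatenated and
  reduced by a shared 1×1 transform (hard-swish nonlinearity), split and
  mapped to per-direction sigmoid gates; output x·g^h(i)·g^w(j). The
  reference reduction ratio is 1 (no bottleneck).

### Fusion, shuffle attention, head

Fusion is channel concatenation (768 + 150 = 918, transformer first):
the two widths cannot be multiplied element-wise, and the published
918-parameter attention delta is consistent only with a 918-channel fused
map. Shuffle attention splits the map into G = 3 groups, each group into
a channel-gated half (sigmoid of an affine in the spatial mean) and a
spatial-gated half (sigmoid of an affine in per-channel group-normalized
values); the five parameter vectors (four affines + GN pair, each of
length C/2G = 153) are shared across groups — 3C/G = 918 parameters,
exactly the published delta. A final 2-group channel shuffle mixes the
halves. The classifier is GAP → Linear(918→1218, bias) → ReLU →
Dropout(0.6) → Linear(1218→4, no bias).

## Calibration against the published sizes

The published description fixes the structure but not the CNN widths,
reduction ratios, DCLS element count, transformer bias/norm details, or
head hidden widths. The five published trainable-parameter counts are
treated as binding constraints:

| variant | parameters |
| --- | ---: |
| fused network with SA | 29,161,395 |
| fused network without SA | 29,160,477 |
| transformer track + head | 27,512,560 |
| EMADN track + head | 707,373 |
| EMADN track without GDA + head | 411,990 |

Their differences isolate the SA block (918) and the GDA blocks
(295,383). A discrete search over the open design space
(`scripts/calibrate_counts.py --search`) has exactly one solution meeting
all five counts simultaneously:

* transformer: bias-free attention and MLP linears, no relative position
  bias, patch-embed bias kept, merging without norm or bias, final
  LayerNorm (backbone 27,450,720);
* EMADN widths 3 → 66 → 68 → 78 → 116 → 150, GCB reduction 2, CA
  reduction 1, 62 DCLS elements per channel, 1×1 deformable kernels;
* head hidden widths 80 (transformer-only), 786 (CNN-only), 1218 (fused),
  with a biased hidden layer and a bias-free output layer.

Standalone-track models carry their own GAP + head, mirroring the
ablation protocol, so track counts are not additive to the fused count.
Some calibrated values are unusual as design choices (no relative
position bias; CA without a bottleneck; 62 kernel elements); they are
what the printed sizes admit, and the classes keep conventional defaults
(`DCLSConv` n = 4, `CoordinateAttention` r = 32, `GlobalContextBlock`
r = 2 configurable) for standalone use.

## Training and evaluation

Cross-entropy loss; SGD with momentum 0.9 (Adam available); defaults
lr = 1e-4, weight decay = 1e-3, StepLR with step 1 and gamma 0.99;
batch size 32 (unstated in the protocol; configurable); no early
stopping — a fixed epoch budget with best-validation checkpointing
alongside the final model. Grid search is exhaustive over a discrete
space in lexicographic order, selecting by validation macro F1 with a
first-in-order tie break.

Metrics are confusion-matrix-derived per-class precision/recall/F1
(scikit-learn), unweighted macro averages, one-vs-rest ROC and PR curves,
and macro AUC as the unweighted mean of per-class one-vs-rest AUCs. A
class absent from the ground truth has recall reported as 0 (with a
warning) and is excluded from macro AUC.

## Synthetic data

The generator emulates the data regime, not the imagery: 224×224 RGB
images in four classes made separable by construction — class-specific
lesion hue ranges, blob counts/sizes, texture frequencies, and rim colour
(erythema-like red rim for infection, pallor rim for ischemia, both for
the combined class) on a skin-tone textured base. Identical seeds give
identical bytes. The split logic is a seeded stratified 60/20/20, after
which every train and validation original of the two minority classes
spawns exactly four augmented copies (independent vertical flip,
horizontal flip, rotation from {0°, 90°, 270°} — all lossless); the test
set is never augmented and no origin image appears in two splits. The
bookkeeping, applied to the study's before-augmentation counts
(136/45/46 ischemia, 372/124/125 both, 1631/510/511 none,
1533/511/511 infection), reproduces every after-augmentation cell
(680, 225, 1860, 620; totals 5704/1866/1193). Those before-augmentation
counts sum to 6055, not the 5,955 the study text states for the dataset;
the per-class table column is taken as ground truth for the arithmetic.
Per-channel normalization statistics are computed from the training
split.

What passing tests show: the architecture can fit and explain visually
separable 4-class images, every operator matches its defining equations,
and the bookkeeping is exact. They say nothing about clinical wound
imagery — real DFU photographs share neither the generator's color
statistics nor its separability.

## Numerical choices

* float64 throughout; oracle comparisons at 1e-5 are then conservative.
* Softmax and log-softmax subtract the (constant) row max.
* Even-kernel same-padding pads bottom/right only; odd kernels pad
  symmetrically.
* Deformable sampling clamps coordinates to the padded input; at integer
  coordinates bilinear interpolation is exact, so zero offsets reproduce
  a standard convolution to machine precision.
* DCLS positions are clamped to [0, extent − 1] with pass-through
  gradients strictly inside the interval.
* Grad-CAM targets the shuffle-attention output (the last convolutional
  representation); channel weights are spatial gradient means, the map
  is ReLU'd, bilinearly upsampled (align-corners) and min-max
  normalized; an all-nonpositive map is defined as all zeros.
* Batch norm keeps running statistics (momentum 0.1) for eval-mode
  determinism; eval-mode forwards are bit-reproducible.
* All initialization draws from explicit `numpy.random.Generator`
  instances, so whole models are seed-reproducible.

## Desk-scale problem sizes

The CPU test and acceptance runs exercise the full architecture at
reduced scale: 32- or 64-pixel inputs, a two-stage transformer
(width 8, window 4) and a three-stage CNN track (widths 8/12/20) joined
at 1/8 resolution — every operator class present, every contract
identical. The end-to-end sanity check trains this configuration on 32
synthetic images (8 per class, 32×32) to 100% training accuracy, typically
within 20–60 epochs. The frozen 224×224 reference configuration is built
in full for parameter accounting (construction is cheap; a full-scale
forward pass is ~15 s per image on one CPU core and is not part of the
routine suite).

## Limitations

* No GPU path and no float32 mode; throughput is desk-scale by design.
* The published accuracy/F1/AUC on the study dataset are not
  reproducible here: the dataset is license-gated and training is
  GPU-scale. Nothing in this package claims those numbers.
* The calibrated configuration is the unique solution within the
  searched design space, not a disclosed ground truth; other spaces
  (e.g., per-stage bias toggles) could admit alternatives.
* The deformable 1×1 reference kernel warps rather than aggregates;
  larger kernels are supported and tested but not used by the frozen
  configuration.
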