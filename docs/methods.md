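# Methods

## Model

`pointattn` implements an attention-based edge-convolution network for
unordered 3-D point sets, for whole-cloud classification and per-point part
segmentation.

**CW-EdgeConv.** Each layer builds a kNN graph over the points, lifts every
directed edge to the feature pair (x_j − x_i, x_i), applies a shared MLP
h_Θ (a 1×1 convolution equivalent: one dense map per point pair, weights
shared across all groups) followed by batch normalization and an
activation, rescales the channels with a squeeze-and-excitation (SE) gate,
and max-aggregates over each group. A group is the center point plus its
k−1 nearest neighbours under exact Euclidean distance; the center is stored
first and distance ties resolve to the smaller point index, which makes
grouping deterministic and permutation tests well posed. Dropping the SE
gate recovers plain EdgeConv, which the test suite uses as an independent
oracle.

The shared MLP on edge pairs is evaluated in factored form,
h = (x_j − x_i)·W_diff + x_i·W_center + b. Because gathering neighbours
commutes with a per-point linear map, both products run at O(N) instead of
O(N·k); the fused `edge_combine` primitive then assembles the N×k×C_out
grouped tensor. This is an implementation identity, not an approximation.

**SE gates.** The squeeze averages each channel over all spatial positions
(points and group members) per sample; the excitation is two full-width
dense stages — no bottleneck reduction — with the configured activation
between and a sigmoid after, so each channel is scaled by a factor strictly
inside (0,1). A per-point (1-d) variant gates the global feature.

**Global attention.** The first layer ("CW-EdgeConv++") additionally emits
a fixed 10-channel geometric descriptor per group entry:
[x_i, x_j, x_j − x_i, ‖x_j − x_i‖]. A two-stage shared MLP (10 → 64 → 1,
batch norm after the first stage) followed by a sigmoid and a max over the
group produces one soft weight per point in (0,1). The global feature g is
multiplied by this mask and passed through ReLU. Two alternatives are
implemented: a hard mask that averages the sigmoid responses over the group
and thresholds at 0.5 (inclusive, so a mean response of exactly 0.5 keeps
the point), and a spatial-attention EdgeConv whose mask branch consumes the
9-channel descriptor without the distance channel — the distance gradient
is unstable near zero separation, and including it destabilizes training.

**Architecture.** Classification trunk: four edge-convolution layers
(default widths 64, 64, 128, 256), the first grouped on input coordinates
and later layers on the current feature space (dynamic graph; a `graph`
switch fixes all layers to coordinates instead). The global feature
concatenates all four layer outputs (512 channels), maps them to C_g =
1024 with a shared MLP and SE-1d gate, applies the attention mask, then
max- and average-pools over points into a 2048-d vector. The head is a
3-layer MLP 2048 → 512 → 256 → m with batch norm, activation and dropout
0.5 on the first two stages. An alternative `global_inputs="last"` mode
builds g from the fourth layer only. Segmentation shares the trunk; each
point's feature is the concatenation of the tiled category one-hot, the
masked global feature g_m and the tiled ReLU(max-pool(g_m)), followed by a
4-layer shared MLP (256, 256, 128, P).

Design points the source architecture leaves open, resolved here once:
the head widths are the DGCNN-style 512 → 256 → m with the reduction
factor R = 2 configurable; excitation stages keep full width; the
global-attention hidden width is 64; dropout is 0.5; momentum 0.9 and
weight decay 1e-4; batch norm sits after every shared MLP and before the
activation. The default activation is LeakyReLU (slope 0.2), the common
choice for edge-convolution trunks; plain ReLU is available via config.

## Training

SGD with momentum on a cosine-annealed learning rate,
lr(e) = 0.015·(1 + cos(πe/E)), i.e. 0.03 at epoch 0 decaying to 0 at the
final epoch. The loss is cross-entropy on raw logits (softmax lives inside
the loss only). Augmentation is per-cloud uniform translation in
[−0.2, 0.2] per axis, anisotropic uniform scaling in [2/3, 3/2] per axis,
and a point-order shuffle; there is **no rotation augmentation**, so the
rotation sweep below measures genuine sensitivity. When a validation set is
supplied the best-on-validation weights are restored.

Batch norm uses batch statistics in training and running statistics
(momentum 0.1, eps 1e-5) at inference; inference therefore never
backpropagates through the normalizer. The max-aggregation routes the
gradient to the first maximizer; ties have measure zero for continuous
inputs.

## Numerics

The layers run on a small in-package reverse-mode autodiff core over NumPy
arrays. Dtype follows the inputs: training uses float32, gradient checks
run the identical graph in float64. The gradient check compares analytic
gradients with central differences elementwise under
|a − n| ≤ 1e-7 + 1e-4·|n|; the absolute floor absorbs finite-difference
noise on structurally zero gradients (a bias feeding a batch norm cannot
affect the loss). The check perturbs parameters away from zero first,
because zero-initialized shifts would place activations exactly on the
LeakyReLU kink where central differences are invalid, and it uses a batch
of two clouds because a batch norm over a singleton pooled batch is
identically constant.

kNN uses exact pairwise distances with an argpartition top-k followed by an
exact sort of the k candidates; candidate indices are pre-sorted so equal
distances resolve to the smaller index. No approximate neighbour structures
are used.

## Synthetic data

Shape mode emulates CAD-derived single-object clouds: uniform surface
samples of five parametric families (sphere, cube, torus, cylinder, cone)
in a canonical orientation with the symmetry axis along z, scaled about the
origin so the farthest point lies on the unit sphere, then jittered with
Gaussian noise (σ = 0.01 in normalized units). Cylinder (side, two caps)
and cone (side, base) carry analytic part labels in a single global label
space, mirroring how part-segmentation benchmarks index parts across
categories. Volume mode emulates clouds sampled from 3-D density maps as
in cryo-electron tomography: a mixture-of-Gaussians voxel density, a
with-replacement categorical draw of a fixed number of voxels proportional
to density, intra-voxel uniform jitter, and optional unit-sphere
normalization. Classes are fixed random blob layouts; at the scale of
typical subtomogram studies this is seven classes of 400 clouds each.

What the generators do not model: measurement physics (contrast transfer,
missing wedge, noise spectra), intra-class shape variation beyond jitter
and augmentation, occlusion, or varying point counts within a dataset.
Passing the desk-scale checks therefore demonstrates that the architecture,
gradients, optimization and metrics are correct and that the model learns
genuinely separable geometry — not that benchmark-level accuracy on real
scan data is reproduced.

## Desk-scale study conditions

The toy classification task is the first four families, 400 training and
100 test clouds of N = 256 points, k = 20. The trunk is a width-reduced
variant of the default architecture — channels (16, 16, 32, 64), C_g = 128,
attention hidden width 32 — chosen for single-CPU NumPy throughput; every
structural element (channel gates, dynamic graph, soft attention,
max+avg pooling head) is retained. Training runs 8 epochs of SGD at batch
16. A nearest-centroid baseline on radial histograms certifies the task is
learnable before any network training.

The robustness protocol evaluates a trained model without retraining under
(a) rigid rotations of 10°, 20°, 30° and (b) random point dropout. The
default rotation axis is x (a tilt), not the vertical: the synthetic
families are mostly rotationally symmetric about z, so a vertical-axis
rotation would be a near no-op and could not exercise the protocol. The
axis is configurable.

## Known limitations

- Throughput is single-CPU NumPy; the full-width architecture trains at
  desk scale only on reduced problems.
- The hard-attention mask is non-differentiable and is used at inference
  (its training path treats the mask as a constant).
- Dynamic-graph grouping recomputes neighbourhoods per layer from
  features; with heavily duplicated points, tie-breaking inside a layer's
  feature space can differ from coordinate space.
- OFF parsing covers the line-oriented ASCII dialect (including the
  header-glued count quirk of common CAD releases); binary OFF is not
  supported.
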