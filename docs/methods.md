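# Methods

## Pipeline

Volumes are indexed `(x, y, z)`, 0-based; sizes quoted H×W×D map to
`(x, y, z) = (H, W, D)`. Preprocessing applies four steps in order:
(1) crop to the tight liver-mask bounding box and resize to 256×256×192
(trilinear for intensities, nearest for labels; one transform object is
reused so image and masks stay on a shared grid); (2) clip intensities to
[−50, 250] HU; (3) keep vessel-label voxels outside the liver mask as
supplementary supervision — vessel masks are never restricted to the liver
ROI; (4) normalize to zero mean, unit variance. No resampling to isotropic
spacing is performed: header spacing is carried through and used wherever
physical units matter (component volumes, centerline lengths, phantom
rasterization).

Augmentation yields exactly three copies per case: in-plane rotations of
60° and 270° about the axial axis plus an identity-rotation copy, each with
an independent uniform integer translation in [−25, +25] voxels per
in-plane axis. The 270° copy uses an exact quarter-turn (`rot90`); 60° uses
linear (image) / nearest (label) interpolation. Reading the "three times"
multiplier as including an identity-rotation copy is a declared choice; the
alternative (a third rotation angle) is not offered.

## Architecture

Encoder: voxel-wise embedding — conv k7 s2 then conv k3 s2, each followed
by GELU and LayerNorm — gives a 1/4-resolution token grid with C = 128
channels (kernels are config fields; the printed defaults are declared, not
canonical). Three transformer stages (2 blocks each, channels C, 2C, 4C)
are separated by stride-2 convolution + GELU + LayerNorm down-sampling
(3D patch merging available as an ablation switch). The decoder mirrors
with stride-2 transposed convolutions (trilinear interpolation and patch
expanding selectable), fusing skip connections at the two intermediate
resolutions and at the embedding output — three skips in total. Two further
transposed convolutions expand 1/4 → full resolution, where a full-resolution
convolutional local-feature path (k7/k3, stride 1) is concatenated before a
1×1×1 two-class softmax head. Channel 0 is vessel foreground. Heads per
stage default to `C_stage/32`, keeping the per-head dimension constant.

Window size is fixed at 4×4×4. Within each block pair the second block
shifts the window grid by the half-window (2,2,2); the shifted partition is
realised by rolling the grid by −shift and reusing the regular partition,
with an additive mask (sentinel −10⁹) blocking token pairs that were not
neighbours before the roll. Grid sides not divisible by the window are
zero-padded high-side *before* the roll, and padded tokens are masked into
their own attention region so they can neither influence nor receive real
tokens. Relative offsets per axis span [−(M−1), M−1], giving the (2M−1)³
bias table; the diagonal pair maps to the zero-offset entry.

The IB-MSA logit combines the query-dependent axial terms and the bias
table additively,
`l_ij = (q_i/√d)·(k_j + r^W + r^H + r^D) + B̂[rel(i,j)]`;
either term alone is the special case of the other being zero. Axial
embeddings are initialized as scaled differences of a fixed sinusoidal 1-D
position code (`r_a[o] = 0.02·(pe(o) − pe(0))`), so the zero offset is
exactly zero, positional logits vary smoothly with offset, and the init is
deterministic and parameter-free; B̂ starts at zero. Under the default
`inductive_bias` mode this initialization is applied in the first stage;
deeper stages start from zero positional terms and learn them. Modes
`relative_only` (zero-initialized learnable terms) and `none` (frozen
zeros) expose the position-embedding ablation axis.

## Numerics

The network runs on an in-package reverse-mode autodiff engine over numpy
(`vesselseg.nn`): a tape-based `Tensor` with the op set the model needs —
broadcast arithmetic, batched matmul, reshape/transpose/roll/pad/slice,
softmax, exact-erf GELU, chunked im2col 3D convolution (scratch buffer
capped near 200 MB regardless of volume size), transposed convolution, and
scatter-add gathers for the positional tables. Activations are float32 by
default; all ops preserve input dtype so unit-level checks run in float64.
Optimizers: SGD with classical momentum (default, matching the reference
protocol's momentum 0.9 / weight decay 2e-3 reading) and Adam.

The training loss is `1 − WD(β)` on soft foreground probabilities with a
1e−5 additive smoothing for the empty-foreground corner; reported metrics
always use the unsmoothed formula. Patch sampling alternates
foreground-centred and uniform draws, guaranteeing at least half of all
patches contain vessel voxels when the case has any (disable for strict
uniform sampling). Degenerate inputs fail loudly: constant volumes cannot
be normalized, empty liver masks cannot be cropped, β ≤ 0 and window sizes
that do not tile the token grid are rejected at config validation, a
non-finite loss aborts training, and a fully masked attention row raises
rather than renormalizing.

Inference tiles patches with per-axis step `patch − overlap` (default
overlap 24; `overlap_is_step` selects the other reading of that phrase),
clamps the last window to the volume edge so coverage is total, and
averages overlapping probabilities (Gaussian weighting optional).
Binarization uses `p ≥ 0.5` (ties to foreground). Post-processing removes
26-connected components with `voxel_count × voxel_volume < 180 mm³`; a 3D
morphological close is available but off by default. BD/TD conventions —
26-connectivity junctions (≥ 3 skeleton neighbours), branch = connected
piece of the skeleton minus junctions, branch length = spacing-weighted
minimum-spanning-tree length over the branch voxels, branch detected at
≥ 80% voxel coverage — are declared choices, configurable, and flagged in
the evaluation report; the underlying airway-metric literature leaves them
operationally open.

## Synthetic phantoms

The phantom generator emulates a contrast-enhanced liver CT patch: a
recursive branching tube tree (default depth 3, branching factor 2, root
radius 2.5 mm tapering ×0.75 per generation, segment length 24 mm tapering
×0.8, child directions uniform within a 60° cone) rasterized by radial
distance in physical mm — so anisotropic spacing is exercised — over a
90 HU background with +90 HU vessel contrast and σ = 15 HU Gaussian noise,
clipped to the preprocessing HU range. Those intensity choices sit in the
range of portal-phase liver parenchyma and enhanced vessels after clipping.
Branch counts and centerline lengths come from the generating tree, not
from the raster, so the tree metrics are validated against exact ground
truth (`BD/TD = 100/100` of a label against itself, analytic cylinder
volume for a straight tube).

What the phantoms do *not* model: partial-volume blur beyond rasterization,
beam hardening, tumors, missing or noisy annotations, and the anatomical
variability of real hepatic trees. Passing the phantom suite therefore
demonstrates the machinery (shapes, gradients, metrics, determinism,
trainability), not clinical segmentation accuracy; benchmark-scale training
on real annotated CT is out of scope here.

## Problem sizes and presets

The `tiny_config` preset (C = 16, one regular/shifted block pair, 32³
patches, SGD momentum at lr 0.05 without weight decay) is the package's
desk-scale configuration: every architectural component is exercised and a
single 32³ phantom is memorized to foreground Dice ≥ 0.8 within 300 steps
on one CPU core. The paper-scale defaults (C = 128, three stages,
128×128×96 patches, lr 3e-5, 750 epochs, batch 2) are fully supported by
the same code paths but are not exercised by the test suite; the tiny
preset's larger learning rate is its own declared setting, chosen for the
short-horizon overfit regime rather than the long full-scale schedule.
Checkpoints are single `.npz` files embedding the configuration hash.
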