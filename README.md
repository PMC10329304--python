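# vesselseg

A 3D shifted-window transformer toolkit for **hepatic vessel segmentation**
in contrast-enhanced CT, built for researchers who need the full pipeline —
preprocessing, a windowed-attention U-net, weighted-dice training,
sliding-window inference, component filtering, and centerline tree metrics —
testable end to end on synthetic vessel phantoms without any external data.

Liver vessels occupy a tiny fraction of the liver volume, run at low
contrast against parenchyma, and branch into thin, curvy trees. Plain
convolutional segmenters miss distal branches because their receptive field
is local; this toolkit pairs convolutional embedding/sampling layers (precise
spatial detail) with windowed self-attention (long-range context).

## The model

A voxel-wise convolutional embedding (total stride 4 per axis) turns an
H×W×D patch into a token grid `T ∈ R^{H/4 × W/4 × D/4 × C}` (C = 128 by
default). Token stages apply pairs of transformer blocks

```
T̂ˡ   = IB-MSA(LN(Tˡ⁻¹)) + Tˡ⁻¹
Tˡ   = MLP(LN(T̂ˡ)) + T̂ˡ
T̂ˡ⁺¹ = Shifted-IB-MSA(LN(Tˡ)) + Tˡ
Tˡ⁺¹ = MLP(LN(T̂ˡ⁺¹)) + T̂ˡ⁺¹
```

where attention is computed inside non-overlapping S_H×S_W×S_D = 4×4×4
windows; the shifted twin displaces the window grid by half a window and
reuses the regular partition via a cyclic roll plus an attention mask (an
8×8×8 token grid has 8 regular windows, 27 geometric windows after the
(2,2,2) shift, but still only 8 batched windows). Windowing makes the cost
linear in the grid: `4·hwd·C² + 2·S_H S_W S_D·hwd·C` multiplies.

**Inductive-biased attention (IB-MSA).** The pre-softmax logit carries two
relative-position terms —

```
l_ij = (q_i/√d)·(k_j + r^W_{jx−ix} + r^H_{jy−iy} + r^D_{jz−iz}) + B̂[rel(i,j)]
```

— a learned `(2M−1)³` bias table `B̂` and per-axis offset embeddings `r`,
initialized from differences of a sinusoidal absolute position code so the
attention starts out local and translation-equivariant.

Training minimizes `1 − WD(β)` with the weighted dice

```
WD(β) = Σ p₀g₀ / (Σ p₀g₀ + 0.5·β·(Σ p₀g₁ + Σ p₁g₀)),   β = 6
```

which scales the penalty on misclassified voxels to counter the extreme
foreground/background imbalance (β = 1 recovers plain Dice). Whole-volume
prediction tiles 128×128×96 patches with 24 voxels of overlap and averages
probabilities; 26-connected components under 180 mm³ are removed.

Quality is reported as Dice / precision / sensitivity plus two centerline
metrics: **BD** (% of ground-truth branches with ≥ 80% of their skeleton
voxels inside the prediction) and **TD** (% of ground-truth centerline
length covered).

## Worked example

Train the desk-scale configuration on one synthetic phantom and evaluate:

```python
import numpy as np
from vesselseg import PhantomSpec, generate, VesselSegmenter, bd_td, voxel_metrics
from vesselseg.preprocessing import normalize

ph = generate(PhantomSpec(shape=(32, 32, 32), depth=2, seed=11,
                          root_radius_mm=2.5, root_length_mm=12))
img = normalize(ph.image)

seg = VesselSegmenter(base_channels=16, depths=(2,), learning_rate=0.05,
                      steps=300, seed=0,
                      config_overrides={"training.patch_size": [32, 32, 32],
                                        "training.weight_decay": 0.0,
                                        "training.batch_size": 1,
                                        "inference.patch_size": [32, 32, 32],
                                        "inference.overlap": 8})
seg.fit([img], [ph.label])
pred = seg.predict(img)
dice, precision, sensitivity = voxel_metrics(pred.data, ph.label.data)
bd, td = bd_td(pred.data, ph.label.data, ph.label.spacing)
```

Output (about three CPU-minutes):

```
phantom branches: 3, centerline length: 31.2 mm
final training loss (1 - WD, beta=6): 0.0627
Dice: 0.989  precision: 0.991  sensitivity: 0.988
BD: 100.0%  TD: 100.0%
```

The phantom is a branching tube tree with analytically known topology, so
BD/TD = 100/100 confirms the prediction covers every branch and the full
centerline; the voxel scores say the tube boundaries are reproduced almost
exactly after 300 optimization steps.

A `vesselseg` CLI wraps the same library for file-based work:
`vesselseg phantom`, `preprocess`, `train`, `predict`, `evaluate`
(NIfTI in/out, DICOM series read-only).

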