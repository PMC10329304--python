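"""Whole-volume inference and post-processing.

Prediction on volumes larger than a network patch uses a sliding window:
patch origins step by ``patch_size - overlap`` per axis (default overlap 24
voxels, configurable to the alternative "step = 24" reading), the last
window is clamped so every voxel is covered, and overlapping probabilities
are averaged (optionally Gaussian-weighted).  Post-processing removes
26-connected components whose physical volume falls below 180 mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .io import CTVolume, LabelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SlidingPlan:
    """Patch origins covering a volume, sorted lexicographically."""

    patch_size: tuple[int, int, int]
    volume_shape: tuple[int, int, int]
    origins: list[tuple[int, int, int]] = field(repr=False)
    pad: tuple[int, int, int] = (0, 0, 0)      # high-side padding when volume < patch


def _axis_origins(size: int, patch: int, step: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)                 # clamp the last window to the edge
    return sorted(set(starts))


def build_sliding_plan(volume_shape, patch_size=(128, 128, 96), overlap: int = 24,
                       overlap_is_step: bool = False) -> SlidingPlan:
    """Sliding-window plan with per-axis step ``patch - overlap`` (default) or
    ``overlap`` itself when ``overlap_is_step`` (the other reading of
    "overlapping stride")."""
    shape = tuple(int(s) for s in volume_shape)
    patch = tuple(int(p) for p in patch_size)
    pad = tuple(max(p - s, 0) for p, s in zip(patch, shape))
    padded = tuple(max(p, s) for p, s in zip(patch, shape))
    axes = []
    for size, p in zip(padded, patch):
        if size <= p:
            axes.append([0])
            continue
        step = overlap if overlap_is_step else p - overlap
        if step <= 0:
            raise ValueError(f"non-positive step {step} (patch {p}, overlap {overlap})")
        axes.append(_axis_origins(size, p, step))
    origins = sorted(product(*axes))
    return SlidingPlan(patch, shape, [tuple(o) for o in origins], pad)


def _gaussian_weight(patch_size) -> np.ndarray:
    grids = [np.exp(-0.5 * ((np.arange(p) - (p - 1) / 2) / (0.125 * p)) ** 2)
             for p in patch_size]
    w = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return (w / w.max()).astype(np.float32)


def sliding_window_infer(vol: CTVolume, predict_patch, plan: SlidingPlan | None = None,
                         aggregation: str = "mean") -> np.ndarray:
    """Per-voxel foreground probability for an arbitrarily sized volume.

    ``predict_patch`` maps a patch array to a foreground-probability array of
    the same spatial shape (e.g. ``lambda p: model.forward(p).foreground``).
    Volumes smaller than the patch are zero-padded and cropped back.
    """
    if plan is None:
        plan = build_sliding_plan(vol.shape)
    data = vol.data
    if any(plan.pad):
        data = np.pad(data, [(0, p) for p in plan.pad])
    acc = np.zeros(data.shape, dtype=np.float64)
    norm = np.zeros(data.shape, dtype=np.float64)
    weight = _gaussian_weight(plan.patch_size) if aggregation == "gaussian" else \
        np.ones(plan.patch_size, dtype=np.float32)
    px, py, pz = plan.patch_size
    for ox, oy, oz in plan.origins:
        patch = data[ox:ox + px, oy:oy + py, oz:oz + pz]
        prob = np.asarray(predict_patch(patch), dtype=np.float64)
        if prob.shape != patch.shape:
            raise ValueError(f"predict_patch returned shape {prob.shape}, "
                             f"expected {patch.shape}")
        acc[ox:ox + px, oy:oy + py, oz:oz + pz] += prob * weight
        norm[ox:ox + px, oy:oy + py, oz:oz + pz] += weight
    out = acc / norm
    sx, sy, sz = vol.shape
    return out[:sx, :sy, :sz]


def binarize(prob: np.ndarray, threshold: float = 0.5,
             spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Voxel is foreground iff probability >= threshold (ties go foreground)."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return LabelVolume((prob >= threshold).astype(np.uint8), spacing)


def remove_small_components(mask: LabelVolume, min_volume_mm3: float = 180.0) -> LabelVolume:
    """Drop 26-connected components below the physical volume threshold.

    A component is removed when ``voxel_count * voxel_volume < min_volume_mm3``;
    surviving components are untouched, so the filter is idempotent and never
    adds voxels.
    """
    labels, n = ndimage.label(mask.data > 0, structure=_STRUCT26)
    if n == 0:
        return mask.with_data(np.zeros_like(mask.data))
    counts = np.bincount(labels.ravel())
    keep = counts * mask.voxel_volume_mm3 >= min_volume_mm3
    keep[0] = False
    return mask.with_data(keep[labels].astype(mask.data.dtype))


def morphological_close(mask: LabelVolume, iterations: int = 1) -> LabelVolume:
    """Optional 3D closing to smooth patch-edge artefacts (off by default)."""
    closed = ndimage.binary_closing(mask.data > 0, structure=_STRUCT26,
                                    iterations=iterations)
    return mask.with_data(closed.astype(mask.data.dtype))


def postprocess(prob: np.ndarray, spacing, threshold: float = 0.5,
                min_component_mm3: float = 180.0, close: bool = False) -> LabelVolume:
    """Binarize then filter small components (optionally close first)."""
    mask = binarize(prob, threshold, spacing)
    if close:
        mask = morphological_close(mask)
    return remove_small_components(mask, min_component_mm3)
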