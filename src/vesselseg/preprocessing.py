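"""CT preprocessing for liver-vessel segmentation.

The pipeline has four steps, applied in this order:

1. crop to the liver bounding box (ROI) and resize to a fixed grid
   (default 256x256x192) — trilinear for intensities, nearest for labels;
2. clip intensities to [-50, 250] HU to suppress irrelevant detail and
   stretch vessel/parenchyma contrast;
3. carry vessel labels outside the liver mask along as supplementary
   supervision (vessel masks are never clipped to the liver);
4. normalize to zero mean and unit variance.

Training-time augmentation produces three copies per case: in-plane
rotations of 60° and 270° plus an identity-rotation copy, each with an
independent random in-plane translation of up to ±25 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CTVolume, LabelVolume

DEFAULT_CLIP_HU = (-50.0, 250.0)
DEFAULT_OUT_SHAPE = (256, 256, 192)


@dataclass
class CropResizeTransform:
    """The ROI crop + resize of one case, reusable for its masks."""

    roi_box: tuple[int, int, int, int, int, int]   # (x0, x1, y0, y1, z0, z1), half-open
    in_shape: tuple[int, int, int]
    out_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]            # input spacing, mm

    @property
    def out_spacing(self) -> tuple[float, float, float]:
        x0, x1, y0, y1, z0, z1 = self.roi_box
        crop = (x1 - x0, y1 - y0, z1 - z0)
        return tuple(s * c / o for s, c, o in zip(self.spacing, crop, self.out_shape))

    def _apply(self, data: np.ndarray, order: int) -> np.ndarray:
        x0, x1, y0, y1, z0, z1 = self.roi_box
        cropped = data[x0:x1, y0:y1, z0:z1]
        zoom = [o / c for o, c in zip(self.out_shape, cropped.shape)]
        out = ndimage.zoom(cropped.astype(np.float32 if order else cropped.dtype),
                           zoom, order=order, grid_mode=True, mode="grid-constant")
        # zoom can be off by one voxel on some ratios; enforce the contract
        out = out[:self.out_shape[0], :self.out_shape[1], :self.out_shape[2]]
        pads = [(0, o - s) for o, s in zip(self.out_shape, out.shape)]
        if any(p[1] for p in pads):
            out = np.pad(out, pads)
        return out

    def apply_to_image(self, vol: CTVolume) -> CTVolume:
        return CTVolume(self._apply(vol.data, order=1), self.out_spacing, vol.origin)

    def apply_to_label(self, mask: LabelVolume) -> LabelVolume:
        return LabelVolume(self._apply(mask.data, order=0), self.out_spacing, mask.origin)


@dataclass
class PreprocessReport:
    clip_bounds: tuple[float, float]
    roi_box: tuple[int, int, int, int, int, int]
    output_shape: tuple[int, int, int]
    mean_before_norm: float
    std_before_norm: float


def clip_intensity(vol: CTVolume, lo: float = DEFAULT_CLIP_HU[0],
                   hi: float = DEFAULT_CLIP_HU[1]) -> CTVolume:
    """Truncate voxel intensities to [lo, hi] HU; interior voxels unchanged."""
    if lo >= hi:
        raise ValueError(f"clip bounds must satisfy lo < hi, got ({lo}, {hi})")
    return vol.with_data(np.clip(vol.data, lo, hi))


def liver_roi_transform(vol: CTVolume, liver_mask: LabelVolume,
                        out_shape=DEFAULT_OUT_SHAPE) -> CropResizeTransform:
    """Tight bounding box of the liver mask plus the resize to ``out_shape``."""
    if vol.shape != liver_mask.shape:
        raise ValueError(f"grid mismatch: {vol.shape} vs {liver_mask.shape}")
    m = liver_mask.data > 0
    if not m.any():
        raise ValueError("liver mask is empty; no ROI to crop")
    box = []
    for axis in range(3):
        proj = m.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        box += [int(idx[0]), int(idx[-1]) + 1]
    return CropResizeTransform(tuple(box), vol.shape, tuple(out_shape), vol.spacing)


def crop_to_liver_roi(vol: CTVolume, liver_mask: LabelVolume,
                      out_shape=DEFAULT_OUT_SHAPE):
    """Crop to the liver bounding box and resize; returns (volume, transform)."""
    t = liver_roi_transform(vol, liver_mask, out_shape)
    return t.apply_to_image(vol), t


def supplement_vessel_mask(vessel_mask: LabelVolume, liver_mask: LabelVolume) -> LabelVolume:
    """Retain vessel labels outside the liver as supplementary supervision.

    Vessel voxels are *not* clipped to the liver ROI: the output is the union
    of the vessel mask with its extra-hepatic voxels (monotone ⊇ input).
    """
    if vessel_mask.shape != liver_mask.shape:
        raise ValueError(f"grid mismatch: {vessel_mask.shape} vs {liver_mask.shape}")
    v = vessel_mask.data > 0
    outside = v & ~(liver_mask.data > 0)
    return vessel_mask.with_data((v | outside).astype(vessel_mask.data.dtype))


def normalize(vol: CTVolume) -> CTVolume:
    """Shift/scale to zero mean and unit variance; rejects constant volumes."""
    data = vol.data.astype(np.float64)
    std = data.std()
    if std == 0:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    return vol.with_data(((data - data.mean()) / std).astype(np.float32))


def _rotate_pair(img: np.ndarray, lab: np.ndarray, angle: float):
    """In-plane (x, y) rotation about the axial z-axis."""
    if angle % 360 == 0:
        return img, lab
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return np.rot90(img, k, axes=(0, 1)).copy(), np.rot90(lab, k, axes=(0, 1)).copy()
    ri = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
    rl = ndimage.rotate(lab, angle, axes=(0, 1), reshape=False, order=0, mode="constant")
    return ri, rl


def _translate(a: np.ndarray, tx: int, ty: int, order: int) -> np.ndarray:
    return ndimage.shift(a, (tx, ty, 0), order=order, mode="constant", cval=a.min()
                         if order else 0)


def augment(vol: CTVolume, label: LabelVolume, seed: int,
            max_translation: int = 25) -> list[tuple[CTVolume, LabelVolume]]:
    """Three augmented copies: rotations of 60°, 270° and identity, each with
    an independent random in-plane translation in [-max_translation, +max]."""
    rng = np.random.default_rng(seed)
    out = []
    for angle in (60.0, 270.0, 0.0):
        ri, rl = _rotate_pair(vol.data, label.data, angle)
        tx, ty = (int(rng.integers(-max_translation, max_translation + 1))
                  for _ in range(2)) if max_translation else (0, 0)
        if (tx, ty) != (0, 0):
            ri = _translate(ri, tx, ty, order=1)
            rl = _translate(rl, tx, ty, order=0)
        out.append((vol.with_data(ri),
                    LabelVolume((rl > 0.5).astype(np.uint8), label.spacing, label.origin)))
    return out


def preprocess_case(ct: CTVolume, liver_mask: LabelVolume, vessel_mask: LabelVolume,
                    out_shape=DEFAULT_OUT_SHAPE, clip=DEFAULT_CLIP_HU):
    """Run the four preprocessing steps; returns (image, label, report)."""
    transform = liver_roi_transform(ct, liver_mask, out_shape)
    img = transform.apply_to_image(ct)
    img = clip_intensity(img, *clip)
    supplemented = supplement_vessel_mask(vessel_mask, liver_mask)
    lab = transform.apply_to_label(supplemented)
    mean, std = float(img.data.mean()), float(img.data.std())
    img = normalize(img)
    report = PreprocessReport(tuple(clip), transform.roi_box, tuple(out_shape), mean, std)
    return img, lab, report
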