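"""Volume I/O with faithful voxel-spacing handling.

Volumes are indexed ``(x, y, z)``, 0-based; spatial sizes quoted H×W×D map to
``(x, y, z) = (H, W, D)``.  NIfTI is the native on-disk format; DICOM series
are read-only (slices ordered by physical slice position, never by
filename).  CT intensities are kept in Hounsfield units as stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("vesselseg")


@dataclass
class CTVolume:
    """3D scalar field in HU with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D "
                             f"(shape {self.data.shape})")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if self.data.dtype.kind == "f" and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "CTVolume":
        return CTVolume(data, self.spacing, self.origin)


@dataclass
class LabelVolume(CTVolume):
    """Binary mask on the same grid as its paired CT volume."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label values must be in {{0, 1}}, found {vals[:10]}")

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(data, self.spacing, self.origin)


def _affine(spacing, origin) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = np.diag(spacing)
    a[:3, 3] = origin
    return a


def read_volume(path, label: bool = False) -> CTVolume:
    """Read a NIfTI file or a DICOM series directory.

    Spacing and origin come from the header; intensities are returned as
    stored.  ``label=True`` returns a validated :class:`LabelVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        data, spacing, origin = _read_dicom_series(path)
    else:
        try:
            img = nib.load(str(path))
        except Exception as e:  # corrupt / unreadable header
            raise ValueError(f"cannot read {path} as NIfTI: {e}") from e
        if img.ndim != 3:
            raise ValueError(f"expected 3D data in {path}, got {img.ndim}D "
                             f"(shape {img.shape})")
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    cls = LabelVolume if label else CTVolume
    return cls(data, spacing, origin)


def _read_dicom_series(directory: Path):
    """Load a DICOM series sorted by slice position via SimpleITK."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # sitk arrays are (z, y, x); transpose to our (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI; integer data round-trips bit-identically."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data, _affine(vol.spacing, vol.origin))
    img.header.set_data_dtype(vol.data.dtype)
    nib.save(img, str(path))


def log_run(command: str, seed: int | None, config_hash: str) -> None:
    """One structured log line per CLI command invocation."""
    logger.info("command=%s seed=%s config_hash=%s", command, seed, config_hash)
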