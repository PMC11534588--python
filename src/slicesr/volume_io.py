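"""NIfTI volume/mask I/O and intensity normalization.

Volumes are held in a fixed canonical axis order (closest-to-RAS), so the
slice direction of a multi-slice acquisition is always one of the three
array axes and the acquisition operator's rotation reduces to an axis
permutation.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_intensity",
]

CANONICAL_AXES = "RAS"


@dataclass
class Volume:
    """A 3D intensity grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: str = CANONICAL_AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Mask:
    """Binary 3D grid aligned with a Volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: str = CANONICAL_AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Mask must be 3D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"Mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = self.data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


def _load_canonical(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(f"No such image file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for corrupt files
        raise IOError(f"Could not read NIfTI image {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(path: str) -> Volume:
    """Read a NIfTI volume, canonicalized to the fixed axis order."""
    data, spacing = _load_canonical(path)
    return Volume(np.asarray(data, dtype=np.float64), spacing)


def read_mask(path: str) -> Mask:
    data, spacing = _load_canonical(path)
    return Mask(np.rint(data).astype(np.uint8), spacing)


def _write_nifti(path: str, data: np.ndarray, spacing, dtype):
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(spacing)
    # atomic write: temp file in the target directory, then rename
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    suffix = ".nii.gz" if path.endswith(".gz") else ".nii"
    fd, tmp = tempfile.mkstemp(suffix=suffix, dir=d)
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_volume(path: str, v: Volume):
    _write_nifti(path, v.data, v.spacing, np.float32)


def write_mask(path: str, m: Mask):
    _write_nifti(path, m.data.astype(np.uint8), m.spacing, np.uint8)


def normalize_intensity(v: Volume, m: Mask, percentile: float = 99.5):
    """Scale a volume to [0,1] by a robust upper percentile inside the mask.

    Division by the 99.5th percentile of masked intensities keeps
    hyperintense lesion tails mostly below 1 while being robust to them;
    values above the percentile are clipped to 1.  Returns the normalized
    volume and the scale so SR outputs can be mapped back to the input
    intensity range.
    """
    if v.data.shape != m.data.shape:
        raise ValueError(f"volume/mask shape mismatch {v.shape} vs {m.shape}")
    inside = v.data[m.data]
    if inside.size == 0:
        raise ValueError("normalize_intensity: mask is empty")
    scale = float(np.percentile(inside, percentile))
    if scale <= 0:
        raise ValueError(f"non-positive normalization scale {scale}")
    data = np.clip(v.data / scale, 0.0, 1.0)
    return Volume(data, v.spacing, v.axes), scale
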