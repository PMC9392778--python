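"""Core grid containers: scalar volumes and integer label masks.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based;
* ``spacing`` is millimetres per voxel along ``(z, y, x)``;
* scalar volumes are floating point, label masks are small non-negative
  integers with 0 reserved for background.

NIfTI I/O goes through nibabel.  nibabel stores arrays in ``(x, y, z)``
(Fortran) order, so arrays are transposed on the way in and out; spacing is
carried in the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMask", "read_volume", "read_mask"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data:
        3D float array, ``(z, y, x)``.
    spacing:
        mm per voxel along ``(z, y, x)``.
    intensity_units:
        ``"normalized"`` if intensities live on [0, 1] (after windowing),
        ``"raw"`` otherwise.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_units: str = "normalized"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        if self.intensity_units not in ("normalized", "raw"):
            raise ValueError(f"unknown intensity_units {self.intensity_units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> None:
        _save_nifti(self.data, self.spacing, path)


@dataclass
class LabelMask:
    """Integer-labelled grid aligned to a :class:`Volume` (0 = background)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("mask values must be integers")
            self.data = self.data.astype(np.int16)
        if self.data.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def labels(self) -> list[int]:
        """Foreground labels present, ascending."""
        return [int(v) for v in np.unique(self.data) if v != 0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean array for one label (or any foreground if None)."""
        if label is None:
            return self.data > 0
        return self.data == label

    def save(self, path: str | Path) -> None:
        _save_nifti(self.data.astype(np.int16), self.spacing, path)


def _save_nifti(data: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    # nibabel expects (x, y, z); our arrays are (z, y, x)
    arr = np.transpose(data, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    return arr, (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def read_volume(path: str | Path, intensity_units: str = "normalized") -> Volume:
    arr, spacing = _load_nifti(path)
    return Volume(arr.astype(np.float64), spacing, intensity_units)


def read_mask(path: str | Path) -> LabelMask:
    arr, spacing = _load_nifti(path)
    return LabelMask(np.rint(arr).astype(np.int16), spacing)


def require_same_grid(a, b) -> None:
    """Raise if two grid objects disagree on shape or spacing."""
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
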