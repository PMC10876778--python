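"""Core voxel-grid containers shared across the pipeline.

All spatial data live on a common voxel grid described by a 4x4 affine
mapping voxel indices (i, j, k) to MNI millimetre coordinates.  Three light
containers wrap plain numpy arrays together with that geometry:

``TimeSeriesVolume``
    a 4D (x, y, z, t) BOLD-like signal with its repetition time,
``ActivityMap``
    a 3D voxel-wise metric map (ReHo, ALFF, fALFF or a standardized
    variant),
``StatMap``
    a 3D statistic map (t or p) carrying its degrees of freedom.

NIfTI round-tripping goes through :mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TimeSeriesVolume",
    "ActivityMap",
    "StatMap",
    "voxel_sizes",
    "voxel_centers_mm",
    "mm_to_voxel",
    "sphere_mask",
]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm, read off the affine."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """MNI mm coordinates of every voxel centre, shape ``(n_voxels, 3)``.

    Voxels are enumerated in C order over ``shape``.
    """
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    return nib.affines.apply_affine(np.asarray(affine), grid)


def mm_to_voxel(coords_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map mm coordinates to (fractional) voxel indices."""
    inv = np.linalg.inv(np.asarray(affine))
    return nib.affines.apply_affine(inv, np.atleast_2d(np.asarray(coords_mm, float)))


def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within ``radius_mm`` of a point.

    The voxel-in-sphere rule is centre-within-radius (Euclidean distance in
    mm); it is the same rule used for tissue-sample sphere extraction.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    centers = voxel_centers_mm(shape, affine)
    d2 = ((centers - np.asarray(center_mm, float)) ** 2).sum(axis=1)
    return (d2 <= radius_mm**2).reshape(shape)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class TimeSeriesVolume:
    """4D BOLD-like signal on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values; at least two time points.
    affine : ndarray, shape (4, 4)
        Voxel-to-MNI-mm transform.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4:
            raise ValueError("TimeSeriesVolume data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.affine = _check_affine(self.affine)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def with_data(self, data: np.ndarray) -> "TimeSeriesVolume":
        return replace(self, data=np.asarray(data, float))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.tr
        img.header.set_zooms(zooms)
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str | Path, tr: float | None = None) -> "TimeSeriesVolume":
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img))
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        return cls(np.asarray(img.dataobj, float), img.affine, tr)


@dataclass
class ActivityMap:
    """3D voxel-wise local-activity metric map.

    ``label`` names the metric (``"reho"``, ``"alff"``, ``"falff"``, or an
    ``"m"``-prefixed globally standardized variant); ``mask`` marks the
    voxels where the metric is defined.
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "map"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("ActivityMap data must be 3D")
        self.affine = _check_affine(self.affine)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    def with_data(self, data: np.ndarray, label: str | None = None) -> "ActivityMap":
        return replace(self, data=np.asarray(data, float), label=label or self.label)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str | Path, label: str = "map") -> "ActivityMap":
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img))
        return cls(np.asarray(img.dataobj, float), img.affine, label)


@dataclass
class StatMap:
    """3D statistic map (t-values or p-values) with degrees of freedom."""

    data: np.ndarray
    affine: np.ndarray
    df: int
    stat: str = "t"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        self.affine = _check_affine(self.affine)
        if self.df <= 0:
            raise ValueError(f"degrees of freedom must be positive, got {self.df}")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str | Path, df: int, stat: str = "t") -> "StatMap":
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img))
        return cls(np.asarray(img.dataobj, float), img.affine, df, stat)
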