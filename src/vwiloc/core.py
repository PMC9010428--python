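"""Core spatial containers: axis-aligned image grids, volumes and displacement fields.

All physical quantities are in millimetres.  Arrays are indexed ``[i, j, k]``
with world coordinate ``origin + index * spacing`` (axis-aligned grids, no
direction matrix).  Displacement fields follow the *pull-back* convention: to
resample a moving image onto the target grid, the moving image is read at
``p + d(p)`` for each target point ``p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy.ndimage import map_coordinates


class GeometryError(ValueError):
    """Raised when grids are incompatible or malformed."""


@dataclass(frozen=True)
class VolumeGeometry:
    """An axis-aligned 3-D sampling grid.

    Parameters
    ----------
    dims : tuple of int
        Grid size ``(n1, n2, n3)`` in voxels; every axis must have >= 8 samples.
    spacing : tuple of float
        Voxel size in mm per axis, strictly positive.
    origin : tuple of float
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.55, 0.55, 0.55)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 8 for d in self.dims):
            raise GeometryError(f"dims must be 3 axes of >= 8 voxels, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (mm) from first to last voxel centre."""
        return (np.asarray(self.dims) - 1) * np.asarray(self.spacing)

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, float) * np.asarray(self.spacing)

    def world_to_index(self, pt) -> np.ndarray:
        return (np.asarray(pt, float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_point(self, pt, margin_vox: float = 0.0) -> bool:
        idx = self.world_to_index(pt)
        return bool(np.all(idx >= margin_vox) and np.all(idx <= np.asarray(self.dims) - 1 - margin_vox))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``dims + (3,)``."""
        axes = [self.origin[a] + np.arange(self.dims[a]) * self.spacing[a] for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def physical_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        return lo, lo + self.extent


@dataclass
class ImageVolume:
    """A scalar volume on a :class:`VolumeGeometry` grid."""

    geometry: VolumeGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.dims:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("image contains non-finite values")

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate at world points (N, 3); zero outside the grid."""
        idx = self.geometry.world_to_index(np.atleast_2d(points))
        return map_coordinates(self.values, idx.T, order=order, mode="constant", cval=0.0)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.geometry, self.values.copy())


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (mm) on a target grid, pull-back convention.

    ``vectors`` has shape ``dims + (3,)``; component order matches axis order.
    """

    geometry: VolumeGeometry
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != self.geometry.dims + (3,):
            raise GeometryError(
                f"vectors shape {self.vectors.shape} != {self.geometry.dims + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise GeometryError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, geometry: VolumeGeometry) -> "DisplacementField":
        return cls(geometry, np.zeros(geometry.dims + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear displacement at world points (N, 3); edge-clamped outside
        (smooth fields extrapolate by their boundary value, which also keeps
        the fixed-point field inversion from oscillating at the rim)."""
        idx = self.geometry.world_to_index(np.atleast_2d(points))
        out = np.empty((idx.shape[0], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.vectors[..., c], idx.T, order=1, mode="nearest"
            )
        return out

    def jacobian_determinant(self) -> np.ndarray:
        """Finite-difference Jacobian determinant of ``p -> p + d(p)`` on the grid."""
        sp = self.geometry.spacing
        J = np.zeros(self.geometry.dims + (3, 3))
        for c in range(3):
            for a in range(3):
                J[..., c, a] = np.gradient(self.vectors[..., c], sp[a], axis=a)
        J += np.eye(3)
        return np.linalg.det(J)

    def negative_jacobian_count(self) -> int:
        return int(np.sum(self.jacobian_determinant() <= 0))


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine encodes spacing and origin; arrays are stored in
# (i, j, k) index order matching the in-memory layout.

def _affine(geom: VolumeGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(geom.spacing)
    aff[:3, 3] = geom.origin
    return aff


def save_image(img: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(img.values.astype(np.float32), _affine(img.geometry)), str(path))


def load_image(path: str | Path) -> ImageVolume:
    nii = nib.load(str(path))
    aff = nii.affine
    spacing = tuple(np.abs(np.diag(aff)[:3]))
    origin = tuple(aff[:3, 3])
    data = np.asarray(nii.dataobj, dtype=np.float64)
    return ImageVolume(VolumeGeometry(data.shape, spacing, origin), data)


def save_dvf(dvf: DisplacementField, path: str | Path, sidecar: bool = True) -> None:
    """Write a 3-component NIfTI plus a JSON sidecar recording conventions."""
    nib.save(
        nib.Nifti1Image(dvf.vectors.astype(np.float32), _affine(dvf.geometry)), str(path)
    )
    if sidecar:
        meta = {"convention": "pull-back", "units": "mm", "components": ["dx", "dy", "dz"]}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_dvf(path: str | Path) -> DisplacementField:
    nii = nib.load(str(path))
    aff = nii.affine
    data = np.asarray(nii.dataobj, dtype=np.float64)
    geom = VolumeGeometry(data.shape[:3], tuple(np.abs(np.diag(aff)[:3])), tuple(aff[:3, 3]))
    return DisplacementField(geom, data)
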