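"""Spatial data model: volumes on a voxel lattice with an affine into MNI mm.

Conventions: coordinates are RAS MNI millimeters throughout; voxel indices are
0-based ``(i, j, k)`` triples in array order. The affine maps homogeneous voxel
indices to mm, as in the NIfTI-1 standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "StatMap",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "voxel_to_mm",
    "mm_to_voxel",
]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with a voxel-index -> MNI-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.voxel_sizes <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 affine part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} grid mismatch: shape/affine differ")


@dataclass
class StatMap:
    """A t-statistic volume with its degrees of freedom."""

    grid: VolumeGrid
    df: int

    def __post_init__(self) -> None:
        self.df = int(self.df)
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not np.all(np.isfinite(self.grid.data)):
            raise ValueError("t-values must be finite")


@dataclass
class MaskVolume:
    """A binary {0,1} volume sharing a grid with the maps it is applied to."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask values must be binary {0,1}")

    @property
    def bool_array(self) -> np.ndarray:
        return self.grid.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.bool_array.sum())


def read_volume(path) -> VolumeGrid:
    """Load a 3D NIfTI-1 image as a :class:`VolumeGrid`.

    Raises ``ValueError`` for non-3D images ("expected 3D") and for images
    whose affine is singular.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D")
    return VolumeGrid(data=np.asarray(data, dtype=float), affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` to a NIfTI-1 file."""
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float64), grid.affine)
    nib.save(img, str(path))


def read_volume_4d(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D NIfTI-1 image; returns ``(data_4d, affine)``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D")
    return np.asarray(data, dtype=float), np.asarray(img.affine)


def write_volume_4d(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got {data.ndim}D")
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), str(path))


def voxel_to_mm(grid: VolumeGrid, index) -> np.ndarray:
    """Map 0-based voxel indices to MNI mm via the grid affine.

    ``index`` is a length-3 integer triple or an (n, 3) array of triples; all
    indices must lie inside the grid shape.
    """
    idx = np.atleast_2d(np.asarray(index))
    if idx.shape[-1] != 3:
        raise ValueError("index must have 3 components")
    shape = np.asarray(grid.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"voxel index out of bounds for shape {grid.shape}")
    mm = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return mm[0] if np.asarray(index).ndim == 1 else mm


def mm_to_voxel(grid: VolumeGrid, mm) -> np.ndarray:
    """Map MNI mm to the nearest 0-based voxel index (exact inverse on lattice
    points after rounding)."""
    pts = np.atleast_2d(np.asarray(mm, dtype=float))
    inv = np.linalg.inv(grid.affine)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = np.rint(idx).astype(int)
    return idx[0] if np.asarray(mm).ndim == 1 else idx
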