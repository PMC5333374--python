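"""Volume and mask I/O with voxel/world coordinate transforms.

All electrode coordinates in this package are world-space millimetres
(RAS+ is assumed for reporting); voxel indices are 0-based.  CT and MRI
volumes are expected to be pre-registered on a shared grid — no
resampling is performed on load, and operations that combine a volume
with a mask require matching shape and affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "BinaryMask", "load_volume", "load_mask", "save_volume",
           "voxel_to_world", "world_to_voxel"]


@dataclass
class Volume:
    """A 3D scalar image with a voxel-to-world affine.

    ``data`` holds intensities (Hounsfield units for CT); ``affine`` is a
    4x4 invertible matrix mapping 0-based voxel indices to world mm.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("singular affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A 3D boolean image sharing grid and affine with its Volume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return data, np.asarray(img.affine, dtype=float)


def load_volume(path: str | Path, units: str = "HU") -> Volume:
    """Read a NIfTI-1/2 volume; the affine is taken from the header verbatim."""
    data, affine = _load_nifti(path)
    return Volume(data=data, affine=affine, units=units)


def load_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI mask; nonzero voxels are True."""
    data, affine = _load_nifti(path)
    return BinaryMask(data=data != 0, affine=affine)


def save_volume(vol: Volume | BinaryMask, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)  # CT dynamic range fits comfortably
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def check_shared_grid(a: Volume | BinaryMask, b: Volume | BinaryMask) -> None:
    """Require two images to live on the same grid (shape and affine)."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("grid mismatch: affines differ; images must be pre-registered")


def voxel_to_world(vol: Volume | BinaryMask, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (..., 3) to world mm via the affine."""
    ijk = np.asarray(ijk, dtype=float)
    single = ijk.ndim == 1
    ijk = np.atleast_2d(ijk)
    if np.any(ijk < 0) or np.any(ijk >= np.array(vol.shape)):
        raise IndexError("voxel index out of bounds")
    xyz = ijk @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return xyz[0] if single else xyz


def world_to_voxel(vol: Volume | BinaryMask, xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns fractional voxel indices."""
    xyz = np.asarray(xyz, dtype=float)
    single = xyz.ndim == 1
    xyz = np.atleast_2d(xyz)
    inv = np.linalg.inv(vol.affine)
    ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
    return ijk[0] if single else ijk
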