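"""Brain-mask morphology and CT thresholding.

Metal electrode contacts produce bright, compact artifacts in post-
implantation CT.  The brain mask is dilated or eroded with a 3x3x3
cubical structuring element to exclude the high-intensity skull shell
while keeping the contacts, and the CT is then thresholded (default
1,800 HU) inside the adjusted mask to extract the artifact voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import BinaryMask, Volume, check_shared_grid, voxel_to_world

__all__ = ["VoxelCloud", "DEFAULT_THRESHOLD_HU", "morph_adjust", "threshold_ct",
           "connected_components", "remove_components", "select_near"]

#: Default CT intensity threshold separating electrode artifacts from tissue.
DEFAULT_THRESHOLD_HU = 1800.0

_CUBE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelCloud:
    """Above-threshold voxels: world coordinates, intensities, grid indices.

    ``coords`` is (N, 3) world mm, ``intensities`` (N,) HU, and ``ijk``
    the (N, 3) integer voxel indices on the source grid (kept so that
    connected components can be computed on the voxel lattice).
    """

    coords: np.ndarray
    intensities: np.ndarray
    ijk: np.ndarray
    warning: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        self.ijk = np.asarray(self.ijk, dtype=np.int64).reshape(-1, 3)
        if not (len(self.coords) == len(self.intensities) == len(self.ijk)):
            raise ValueError("coords, intensities and ijk must have equal length")

    @property
    def count(self) -> int:
        return len(self.coords)

    def subset(self, sel: np.ndarray) -> "VoxelCloud":
        return VoxelCloud(self.coords[sel], self.intensities[sel], self.ijk[sel])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_mm": self.coords[:, 0],
            "y_mm": self.coords[:, 1],
            "z_mm": self.coords[:, 2],
            "intensity": self.intensities,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def morph_adjust(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Dilate (positive iterations) or erode (negative) with a 3x3x3 cube.

    Zero iterations returns an identical mask.  Erosion that empties the
    mask raises, reporting the iteration at which it vanished.
    """
    if abs(iterations) > 20:
        raise ValueError("|iterations| must be <= 20")
    data = mask.data
    if iterations > 0:
        data = ndimage.binary_dilation(data, structure=_CUBE, iterations=iterations)
    elif iterations < 0:
        for it in range(1, -iterations + 1):
            data = ndimage.binary_erosion(data, structure=_CUBE)
            if not data.any():
                raise ValueError(f"mask emptied by erosion at iteration {it}")
    else:
        data = data.copy()
    return BinaryMask(data=data, affine=mask.affine)


def threshold_ct(ct: Volume, mask: BinaryMask,
                 threshold: float = DEFAULT_THRESHOLD_HU) -> VoxelCloud:
    """Select voxels with intensity >= threshold inside the mask.

    The comparison is inclusive, so voxels exactly at the threshold are
    kept.  An empty selection yields an empty cloud carrying a warning
    rather than raising.
    """
    check_shared_grid(ct, mask)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sel = (np.asarray(ct.data, dtype=float) >= threshold) & mask.data
    ijk = np.argwhere(sel)
    if len(ijk) == 0:
        warnings.warn("no voxels above threshold inside mask")
        empty = np.empty((0, 3))
        return VoxelCloud(empty, np.empty(0), np.empty((0, 3), dtype=np.int64),
                          warning="no voxels above threshold inside mask")
    coords = voxel_to_world(ct, ijk)
    intens = np.asarray(ct.data, dtype=float)[sel.nonzero()]
    return VoxelCloud(coords, intens, ijk)


def connected_components(cloud: VoxelCloud) -> np.ndarray:
    """Label the cloud's voxels by 26-connected component on the voxel grid.

    Returns an (N,) array of 1-based component ids.  Labeling is
    deterministic: components are numbered by ascending minimal voxel
    index (lexicographic i, j, k), independent of voxel storage order.
    """
    if cloud.count == 0:
        return np.empty(0, dtype=int)
    lo = cloud.ijk.min(axis=0)
    local = cloud.ijk - lo
    shape = tuple(local.max(axis=0) + 1)
    grid = np.zeros(shape, dtype=bool)
    grid[tuple(local.T)] = True
    labeled, n = ndimage.label(grid, structure=_CUBE)
    raw = labeled[tuple(local.T)]
    # relabel by minimal flat voxel index per component
    order = np.full(n + 1, -1, dtype=int)
    flat = np.ravel_multi_index(tuple(local.T), shape)
    first = {}
    for lab in range(1, n + 1):
        first[lab] = flat[raw == lab].min()
    for newid, lab in enumerate(sorted(first, key=first.get), start=1):
        order[lab] = newid
    return order[raw]


def remove_components(cloud: VoxelCloud, keep=None, drop=None) -> VoxelCloud:
    """Retain selected 26-connected components of the cloud.

    This is the programmatic replacement for interactive removal of
    spurious non-electrode voxels (cables, grid markers).  ``keep`` may be
    a list of 1-based component ids or a predicate taking the component's
    centroid (world mm) and returning True to keep; ``drop`` is the
    complementary id list.  Exactly one of keep/drop may be given; neither
    means keep everything.
    """
    if cloud.count == 0:
        raise ValueError("cloud is empty")
    labels = connected_components(cloud)
    ids = np.unique(labels)
    if keep is not None and drop is not None:
        raise ValueError("give either keep or drop, not both")
    if keep is None and drop is None:
        return cloud.subset(np.ones(cloud.count, dtype=bool))
    if callable(keep):
        chosen = [i for i in ids
                  if keep(cloud.coords[labels == i].mean(axis=0))]
    elif keep is not None:
        chosen = list(keep)
    else:
        chosen = [i for i in ids if i not in set(drop)]
    bad = set(chosen) - set(ids.tolist())
    if bad:
        raise ValueError(f"nonexistent component id(s): {sorted(bad)}")
    sel = np.isin(labels, list(chosen))
    return cloud.subset(sel)


def select_near(cloud: VoxelCloud, points: np.ndarray,
                radius: float) -> VoxelCloud:
    """Keep components whose centroid lies within ``radius`` mm of any
    guide point (e.g. samples along a planned electrode trajectory).

    This is the seed-point flavour of programmatic voxel selection: it
    assigns connected components to an array without touching individual
    voxels, replacing interactive 3D lassoing.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)

    def near(centroid: np.ndarray) -> bool:
        return bool(np.min(np.linalg.norm(points - centroid, axis=1)) <= radius)

    return remove_components(cloud, keep=near)
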