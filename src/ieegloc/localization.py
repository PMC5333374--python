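"""Contact localization: K-means voxel clustering and intensity-weighted centroids.

Each electrode array contributes N above-threshold voxels.  With K, the
number of contacts, known from the implantation notes, the voxels are
partitioned into K clusters by K-means on world-mm coordinates (minimising
the within-cluster sum of squares), and each contact coordinate L_k is the
centre of mass of its cluster using voxel intensities as weights.  The
result is a K x 3 coordinate matrix L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .masking import VoxelCloud

__all__ = ["ElectrodeArraySpec", "ElectrodeSet", "cluster_voxels",
           "center_of_mass", "localize_array"]


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """Geometry of one implanted array.

    kind is 'grid', 'strip' or 'depth'; strips and depth arrays use
    rows=1.  pitch is the inter-contact centre-to-centre spacing in mm
    (10 mm for standard grids; 5, 6 or 10 mm depth variants exist).
    """

    kind: str
    rows: int
    cols: int
    pitch: float = 10.0
    prefix: str = "E"

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "strip", "depth"):
            raise ValueError(f"unknown array kind {self.kind!r}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.kind == "grid" and (self.rows < 2 or self.cols < 2):
            raise ValueError("grids need rows >= 2 and cols >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def K(self) -> int:
        return self.rows * self.cols


@dataclass
class ElectrodeSet:
    """K localized contacts of one array.

    L is the K x 3 world-mm coordinate matrix.  ``indices`` (a permutation
    of 1..K) and ``names`` are unset until numbering/naming has run; row
    order is arbitrary before then.
    """

    L: np.ndarray
    spec: ElectrodeArraySpec
    indices: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.L).all():
            raise ValueError("coordinates must be finite")
        if len(self.L) != self.spec.K:
            raise ValueError(f"expected {self.spec.K} contacts, got {len(self.L)}")
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int)
            if sorted(self.indices) != list(range(1, self.spec.K + 1)):
                raise ValueError("indices must be a permutation of 1..K")

    @property
    def K(self) -> int:
        return self.spec.K

    def ordered(self) -> np.ndarray:
        """Coordinates sorted by contact index (requires indices set)."""
        if self.indices is None:
            raise ValueError("indices not set")
        return self.L[np.argsort(self.indices)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.L, columns=["x_mm", "y_mm", "z_mm"])
        if self.indices is not None:
            df.insert(0, "index", self.indices)
        if self.names is not None:
            df.insert(0, "name", self.names)
        if self.indices is not None:
            df = df.sort_values("index").reset_index(drop=True)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "spec": {"kind": self.spec.kind, "rows": self.spec.rows,
                     "cols": self.spec.cols, "pitch": self.spec.pitch,
                     "prefix": self.spec.prefix},
            "contacts": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def cluster_voxels(cloud: VoxelCloud, K: int, seed: int = 0,
                   n_init: int = 10) -> list[np.ndarray]:
    """Partition the cloud into K clusters by K-means on world coordinates.

    Clustering is unweighted (intensity enters only in the centre-of-mass
    step) and uses k-means++ with ``n_init`` restarts, keeping the best
    within-cluster sum of squares; deterministic for a fixed seed.
    Returns K arrays of voxel indices into the cloud.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if cloud.count < K:
        raise ValueError(f"cannot form {K} clusters from {cloud.count} voxels")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    labels = km.fit_predict(cloud.coords)
    clusters = [np.flatnonzero(labels == k) for k in range(K)]
    if any(len(c) == 0 for c in clusters):  # sklearn relocates empties; guard anyway
        raise RuntimeError("empty cluster after convergence")
    return clusters


def center_of_mass(cluster: np.ndarray, cloud: VoxelCloud) -> np.ndarray:
    """Intensity-weighted mean coordinate of a cluster's voxels."""
    cluster = np.asarray(cluster, dtype=int)
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    w = cloud.intensities[cluster]
    if np.any(w <= 0):
        raise ValueError("intensities must be positive to act as weights")
    total = w.sum()
    return (cloud.coords[cluster] * w[:, None]).sum(axis=0) / total


def localize_array(cloud: VoxelCloud, spec: ElectrodeArraySpec,
                   seed: int = 0) -> ElectrodeSet:
    """Cluster an array's voxels and return its contact coordinates.

    Row order of the result follows cluster label order and carries no
    meaning until numbering assigns indices.
    """
    clusters = cluster_voxels(cloud, spec.K, seed=seed)
    L = np.vstack([center_of_mass(c, cloud) for c in clusters])
    return ElectrodeSet(L=L, spec=spec)
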