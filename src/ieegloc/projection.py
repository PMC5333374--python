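"""Brain-shift correction: smoothed cortical envelope and grid projection.

After implantation, fluid build-up displaces subdural grids inward
relative to the pre-implantation anatomy.  Correction proceeds in three
stages:

1. build a smoothed cortical envelope (SCE) — a closed surface hugging
   the brain mask with sulci bridged by morphological closing;
2. project grid contacts onto the envelope by minimizing an energy that
   trades off each contact's displacement against deformation of the
   spring-like lattice connecting neighbouring contacts,

       sum_k ||L_k - L_k0||^2  +  sum_{i<j} a_ij (d_ij - d_ij0)^2

   subject to every contact coinciding with a mesh node (a_ij = 1 for
   lattice neighbours);
3. translate depth contacts by a displacement field interpolated from
   the grid projection vectors D_k with Gaussian weights, attenuated for
   contacts far from the envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .io_volumes import BinaryMask
from .localization import ElectrodeSet

__all__ = ["SurfaceMesh", "ProjectionResult", "build_sce", "project_grid",
           "displacement_field", "lattice_adjacency"]


@dataclass
class SurfaceMesh:
    """Triangulated closed surface: nodes (mm) and triangle faces."""

    nodes: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.nodes):
            raise ValueError("faces reference nonexistent nodes")

    @property
    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.nodes, faces=self.faces,
                               process=False)

    def save(self, path: str | Path) -> None:
        """Write the mesh; format chosen by extension (.off or .stl)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        m = trimesh.load_mesh(str(path))
        return cls(nodes=np.asarray(m.vertices), faces=np.asarray(m.faces))


def _ball_closing(mask: np.ndarray, radius_mm: float,
                  spacing: np.ndarray) -> np.ndarray:
    """Morphological closing with a Euclidean ball via two distance transforms."""
    pad = int(np.ceil(radius_mm / spacing.min())) + 2
    m = np.pad(mask, pad)
    dil = ndimage.distance_transform_edt(~m, sampling=spacing) <= radius_mm
    closed = ndimage.distance_transform_edt(dil, sampling=spacing) > radius_mm
    closed |= m  # closing is extensive: never lose original voxels
    return closed[pad:-pad, pad:-pad, pad:-pad]


def build_sce(brain_mask: BinaryMask, hemisphere: str = "both",
              closing_radius_mm: float = 8.0, smooth_iterations: int = 20,
              smooth_factor: float = 0.5) -> SurfaceMesh:
    """Construct the smoothed cortical envelope from a brain mask.

    The mask (optionally split at the x = 0 midline: 'left' keeps world
    x <= 0) is closed with an 8 mm ball to bridge sulci, iso-surfaced at
    0.5 by marching cubes, and Laplacian-smoothed (20 iterations, factor
    0.5).  The largest connected surface component is returned; the mesh
    is subdivided if node density falls below 1 node per 4 mm^2 so the
    node-coincidence constraint discretizes positions to within ~1 mm.
    """
    from skimage.measure import marching_cubes

    if not brain_mask.data.any():
        raise ValueError("empty brain mask")
    data = brain_mask.data
    if hemisphere != "both":
        if hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        # world x per voxel from the affine (midline convention x = 0)
        aff = brain_mask.affine
        i = np.arange(data.shape[0])[:, None, None]
        j = np.arange(data.shape[1])[None, :, None]
        k = np.arange(data.shape[2])[None, None, :]
        x = aff[0, 0] * i + aff[0, 1] * j + aff[0, 2] * k + aff[0, 3]
        data = data & ((x <= 0) if hemisphere == "left" else (x >= 0))
        if not data.any():
            raise ValueError(f"no voxels on the {hemisphere} side of x = 0")
    spacing = np.linalg.norm(brain_mask.affine[:3, :3], axis=0)
    closed = _ball_closing(data, closing_radius_mm, spacing)
    verts, faces, _, _ = marching_cubes(closed.astype(np.float32), level=0.5)
    # verts are fractional voxel indices; map through the affine
    world = verts @ brain_mask.affine[:3, :3].T + brain_mask.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.vertices))
    trimesh.smoothing.filter_laplacian(mesh, lamb=smooth_factor,
                                       iterations=smooth_iterations,
                                       volume_constraint=False)
    # density target: >= 1 node per 4 mm^2
    while len(mesh.vertices) / max(mesh.area, 1e-9) < 0.25:
        mesh = mesh.subdivide()
    return SurfaceMesh(nodes=np.asarray(mesh.vertices),
                       faces=np.asarray(mesh.faces))


def lattice_adjacency(es: ElectrodeSet) -> np.ndarray:
    """Pairs of contact rows holding lattice-adjacent indices (|dr|+|dc| = 1)."""
    if es.indices is None:
        raise ValueError("indices must be set to derive grid adjacency")
    cols = es.spec.cols
    rc = {int(i): divmod(int(i) - 1, cols) for i in es.indices}
    pos = {int(i): r for r, i in enumerate(es.indices)}
    pairs = []
    for i in sorted(rc):
        for j in sorted(rc):
            if j <= i:
                continue
            dr = abs(rc[i][0] - rc[j][0])
            dc = abs(rc[i][1] - rc[j][1])
            if dr + dc == 1:
                pairs.append((pos[i], pos[j]))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


@dataclass
class ProjectionResult:
    """Outcome of projecting a grid onto the envelope."""

    L0: np.ndarray          # original coordinates
    L: np.ndarray           # projected coordinates (mesh nodes)
    node_ids: np.ndarray    # mesh node per contact
    energy: float
    converged: bool
    energy_trace: list = field(default_factory=list)

    @property
    def D(self) -> np.ndarray:
        """Projection vectors D_k = L_k - L_k0."""
        return self.L - self.L0

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.D, axis=1)


def _energy_and_grad(L: np.ndarray, L0: np.ndarray, pairs: np.ndarray,
                     d0: np.ndarray):
    disp = L - L0
    E = float((disp ** 2).sum())
    g = 2.0 * disp
    if len(pairs):
        diff = L[pairs[:, 0]] - L[pairs[:, 1]]
        d = np.linalg.norm(diff, axis=1)
        E += float(((d - d0) ** 2).sum())
        coef = 2.0 * (d - d0) / np.maximum(d, 1e-12)
        np.add.at(g, pairs[:, 0], coef[:, None] * diff)
        np.add.at(g, pairs[:, 1], -coef[:, None] * diff)
    return E, g


def grid_energy(L: np.ndarray, L0: np.ndarray, pairs: np.ndarray,
                d0: np.ndarray) -> float:
    """Displacement + spring energy of a candidate configuration."""
    return _energy_and_grad(np.asarray(L, dtype=float), L0, pairs, d0)[0]


def project_grid(es: ElectrodeSet, sce: SurfaceMesh,
                 max_outer: int = 40, n_candidates: int = 16) -> ProjectionResult:
    """Project grid contacts onto the envelope by constrained energy minimization.

    The node-coincidence constraint is handled by alternating
    minimization: snap each contact to its nearest mesh node, then
    continuously minimize the energy with a quadratic attachment to the
    snapped nodes whose weight is ramped up across outer iterations,
    repeating until the node assignment is stable.  A final discrete
    coordinate-descent pass over each contact's nearest candidate nodes
    polishes the assignment; its energy is non-increasing by
    construction.  If the assignment never stabilizes the best iterate is
    returned with ``converged=False``.
    """
    L0 = es.L.copy()
    K = len(L0)
    nodes = sce.nodes
    tree = cKDTree(nodes)
    if es.spec.kind == "grid" and K > 1:
        pairs = lattice_adjacency(es)
    else:
        pairs = np.empty((0, 2), dtype=int)
    d0 = (np.linalg.norm(L0[pairs[:, 0]] - L0[pairs[:, 1]], axis=1)
          if len(pairs) else np.empty(0))

    if K == 1 or len(pairs) == 0:
        _, ids = tree.query(L0)
        ids = np.atleast_1d(ids)
        L = nodes[ids]
        E = grid_energy(L, L0, pairs, d0)
        return ProjectionResult(L0=L0, L=L, node_ids=ids, energy=E,
                                converged=True, energy_trace=[E])

    L = L0.copy()
    assign = None
    converged = False
    lam = 1.0
    for _ in range(max_outer):
        _, ids = tree.query(L)
        if assign is not None and np.array_equal(ids, assign) and lam >= 64:
            converged = True
            break
        assign = ids
        snapped = nodes[ids]

        def fun(x):
            Lx = x.reshape(K, 3)
            E, g = _energy_and_grad(Lx, L0, pairs, d0)
            E += lam * float(((Lx - snapped) ** 2).sum())
            g = g + 2.0 * lam * (Lx - snapped)
            return E, g.ravel()

        res = minimize(fun, L.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        L = res.x.reshape(K, 3)
        lam = min(lam * 2.0, 256.0)

    # discrete polish: exact node coincidence, monotone energy
    _, ids = tree.query(L)
    L = nodes[ids].copy()
    trace = [grid_energy(L, L0, pairs, d0)]
    for _ in range(50):
        changed = False
        for k in range(K):
            _, cand = tree.query(L[k], k=min(n_candidates, len(nodes)))
            cand = np.atleast_1d(cand)
            best_e, best_c = trace[-1], ids[k]
            for c in cand:
                if c == ids[k]:
                    continue
                old = L[k].copy()
                L[k] = nodes[c]
                e = grid_energy(L, L0, pairs, d0)
                if e < best_e - 1e-12:
                    best_e, best_c = e, c
                L[k] = old
            if best_c != ids[k]:
                ids[k] = best_c
                L[k] = nodes[best_c]
                trace.append(best_e)
                changed = True
        if not changed:
            converged = True
            break
    if not converged:
        warnings.warn("grid projection did not fully converge; "
                      "returning best iterate")
    return ProjectionResult(L0=L0, L=L, node_ids=ids,
                            energy=trace[-1], converged=converged,
                            energy_trace=trace)


def displacement_field(depth_es: ElectrodeSet, proj: ProjectionResult,
                       sce: SurfaceMesh, sigma_R: float | None = None,
                       grid_pitch: float | None = None,
                       attenuation: str = "pairwise"):
    """Translate depth contacts by the grid-derived displacement field.

    For depth contact j and grid contact k (at its projected position),
    the regularization weight is w_jk = exp(-||L_j - L_k||^2 / sigma_R^2)
    and the attenuation weight w'_jk = exp(-||L_j - L_k||^2 / sigma_D^2),
    where 2 sigma_D is the mean distance of the grid contacts to the SCE
    centroid.  The field is F_j = sum_k w_jk w'_jk D_k / sum_k w_jk; the
    convex combination (times w' <= 1) bounds ||F_j|| by max_k ||D_k||.

    sigma_R defaults to half the grid pitch.  ``attenuation='centroid'``
    selects the variant where w' depends on the depth contact's own
    distance to the envelope centroid instead of pairwise distances.

    Returns (translated ElectrodeSet, F) with F the (K_depth, 3) field.
    """
    Lg = proj.L
    D = proj.D
    Lj = depth_es.L
    if len(Lg) == 0:
        warnings.warn("no grid contacts: identity displacement field")
        return depth_es, np.zeros_like(Lj)
    if sigma_R is None:
        sigma_R = 0.5 * (grid_pitch if grid_pitch is not None else 10.0)
    if sigma_R <= 0:
        raise ValueError("sigma_R must be positive")
    centroid = sce.centroid
    sigma_D = 0.5 * float(np.linalg.norm(Lg - centroid, axis=1).mean())
    dist2 = ((Lj[:, None, :] - Lg[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-dist2 / sigma_R ** 2)
    if attenuation == "pairwise":
        wp = np.exp(-dist2 / sigma_D ** 2)
    elif attenuation == "centroid":
        dc2 = ((Lj - centroid) ** 2).sum(axis=1)
        wp = np.exp(-dc2 / sigma_D ** 2)[:, None] * np.ones_like(w)
    else:
        raise ValueError(f"unknown attenuation {attenuation!r}")
    denom = w.sum(axis=1)
    num = (w * wp) @ D
    F = np.where(denom[:, None] > 0, num / np.maximum(denom, 1e-300)[:, None], 0.0)
    moved = ElectrodeSet(L=Lj + F, spec=depth_es.spec,
                         indices=depth_es.indices, names=depth_es.names)
    return moved, F
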