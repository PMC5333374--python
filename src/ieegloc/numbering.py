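"""Automatic contact numbering for depth arrays, strips, and subdural grids.

Depth arrays and strips are numbered along the first principal axis of
their coordinates, contact 1 at the deep end.  Grids use a geometric
procedure: project to the top-2 PCA plane, find the four grid corners as
the convex-hull vertices with the largest transition angles, model an
ideal rows x cols grid by bilinear interpolation of the corners, project
it radially onto the best-fit sphere of the real contacts, assign indices
greedily from shortest real-ideal distance, and refine by pairwise
permutation of lattice-neighbour indices.  A final manual flip/rotate
resolves the global orientation (which requires the implantation diagram
and cannot be inferred from the image alone).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull

from .io_volumes import BinaryMask, world_to_voxel
from .localization import ElectrodeSet

__all__ = ["ConvexOutline", "IdealGrid", "SphereFit", "number_depth",
           "project_pca2", "hull_corners", "build_ideal_grid", "fit_sphere",
           "radial_project", "assign_indices", "permute_refine", "flip_rotate",
           "name_electrodes", "number_grid", "deep_end_from_mask"]


# ---------------------------------------------------------------- depth/strip

def _first_pc(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centre and return (unit first principal axis, projections)."""
    mean = L.mean(axis=0)
    X = L - mean
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("degenerate array: all contacts coincide")
    axis = vt[0]
    return axis, X @ axis


def number_depth(es: ElectrodeSet, deep_end: np.ndarray) -> ElectrodeSet:
    """Number a depth array or strip 1..K along its principal axis.

    Contacts are projected onto the first principal component of L and
    numbered by ordinal position, with contact 1 at the end nearer the
    ``deep_end`` hint (the deepest contact; see deep_end_from_mask for a
    mask-based default).
    """
    if es.spec.kind not in ("depth", "strip"):
        raise ValueError("number_depth applies to depth arrays and strips")
    if es.K < 2:
        raise ValueError("need at least 2 contacts to order")
    _, t = _first_pc(es.L)
    order = np.argsort(t, kind="stable")
    deep_end = np.asarray(deep_end, dtype=float)
    lo_end, hi_end = es.L[order[0]], es.L[order[-1]]
    if np.linalg.norm(deep_end - hi_end) < np.linalg.norm(deep_end - lo_end):
        order = order[::-1]
    indices = np.empty(es.K, dtype=int)
    indices[order] = np.arange(1, es.K + 1)
    return ElectrodeSet(L=es.L, spec=es.spec, indices=indices, names=es.names)


def deep_end_from_mask(es: ElectrodeSet, mask: BinaryMask) -> np.ndarray:
    """Pick the array endpoint lying deeper in the brain mask.

    Depth is measured as Euclidean distance to the mask boundary (distance
    transform in mm); the endpooint with the larger depth is the tip.
    """
    _, t = _first_pc(es.L)
    ends = es.L[[int(np.argmin(t)), int(np.argmax(t))]]
    spacing = np.linalg.norm(mask.affine[:3, :3], axis=0)
    dist = ndimage.distance_transform_edt(mask.data, sampling=spacing)
    ijk = np.round(world_to_voxel(mask, ends)).astype(int)
    ijk = np.clip(ijk, 0, np.array(mask.shape) - 1)
    depths = dist[tuple(ijk.T)]
    return ends[int(np.argmax(depths))]


# ----------------------------------------------------------------- grid steps

def project_pca2(L: np.ndarray) -> np.ndarray:
    """Mean-centred projection of K x 3 coordinates onto the top-2 PCA plane."""
    L = np.asarray(L, dtype=float)
    if len(L) < 3:
        raise ValueError("need at least 3 points")
    X = L - L.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; 2D projection is degenerate")
    # canonical axis signs (largest-magnitude component positive) so the
    # projection, and everything downstream, is independent of row order
    axes = vt[:2].copy()
    for a in axes:
        if a[np.argmax(np.abs(a))] < 0:
            a *= -1.0
    return X @ axes.T


@dataclass
class ConvexOutline:
    """Convex hull of the PCA-plane contacts with per-vertex turn angles."""

    points2d: np.ndarray          # (M, 2) hull vertices, counter-clockwise
    vertex_ids: np.ndarray        # (M,) indices into the input point array
    transition_angles: np.ndarray  # (M,) degrees of turn at each vertex


def hull_corners(p2: np.ndarray) -> tuple[ConvexOutline, np.ndarray]:
    """Find the four grid corners on the convex hull of the 2D contacts.

    The transition angle at each hull vertex is the absolute turn between
    the incoming and outgoing hull segments, in degrees; the four largest
    angles mark the corners of a (noisy) rectangular grid.  Ties are
    broken by distance from the hull centroid, corners being extremal.
    Corner ids are returned in counter-clockwise hull order.
    """
    p2 = np.asarray(p2, dtype=float)
    if len(p2) < 4:
        raise ValueError("need at least 4 points")
    hull = ConvexHull(p2)
    vid = hull.vertices            # counter-clockwise in 2D
    pts = p2[vid]
    M = len(pts)
    if M < 4:
        raise ValueError("convex hull has fewer than 4 vertices")
    prev = pts - np.roll(pts, 1, axis=0)    # incoming segment at each vertex
    nxt = np.roll(pts, -1, axis=0) - pts    # outgoing segment
    dot = (prev * nxt).sum(axis=1)
    cross = prev[:, 0] * nxt[:, 1] - prev[:, 1] * nxt[:, 0]
    angles = np.degrees(np.abs(np.arctan2(cross, dot)))
    centroid = pts.mean(axis=0)
    r = np.linalg.norm(pts - centroid, axis=1)
    rank = np.lexsort((-r, -angles))        # angle desc, then radius desc
    corner_pos = np.sort(rank[:4])          # hull order = counter-clockwise
    outline = ConvexOutline(points2d=pts, vertex_ids=vid,
                            transition_angles=angles)
    return outline, vid[corner_pos]


@dataclass
class IdealGrid:
    """Idealized rows x cols grid interpolated from four corner contacts."""

    corners: np.ndarray   # (4, 3) adjacent-ordered corner coordinates
    coords: np.ndarray    # (rows, cols, 3) lattice coordinates
    rows: int
    cols: int

    def flat(self) -> np.ndarray:
        """Row-major (K, 3) coordinates; contact index = position + 1."""
        return self.coords.reshape(-1, 3)

    def row_col(self, index: int) -> tuple[int, int]:
        return divmod(index - 1, self.cols)


def build_ideal_grid(corners: np.ndarray, rows: int, cols: int) -> IdealGrid:
    """Bilinear interpolation of 4 adjacent-ordered corners over a lattice.

    Corner order is c0 -> c1 along the column direction and c0 -> c3 along
    the row direction; corner lattice points coincide exactly with the
    given corners.  Index 1 sits at c0 and indices fill row-major.
    """
    corners = np.asarray(corners, dtype=float).reshape(4, 3)
    if rows * cols < 4:
        raise ValueError("rows*cols must be >= 4")
    if rows < 2 or cols < 2:
        raise ValueError("grids need rows >= 2 and cols >= 2")
    c0, c1, c2, c3 = corners
    u = np.linspace(0.0, 1.0, cols)[None, :, None]
    v = np.linspace(0.0, 1.0, rows)[:, None, None]
    coords = ((1 - u) * (1 - v) * c0 + u * (1 - v) * c1
              + u * v * c2 + (1 - u) * v * c3)
    return IdealGrid(corners=corners, coords=coords, rows=rows, cols=cols)


@dataclass
class SphereFit:
    """Least-squares sphere through the grid contacts.

    Near-planar grids (fitted radius > 10x the grid extent) fall back to
    a plane: ``is_planar`` is set and radial projection becomes orthogonal
    projection onto the best-fit plane.
    """

    center: np.ndarray
    radius: float
    rms_residual: float
    is_planar: bool = False
    plane_point: np.ndarray | None = None
    plane_normal: np.ndarray | None = None


def _plane_fallback(L: np.ndarray) -> SphereFit:
    mean = L.mean(axis=0)
    X = L - mean
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    normal = vt[2]
    res = X @ normal
    return SphereFit(center=mean, radius=np.inf,
                     rms_residual=float(np.sqrt(np.mean(res ** 2))),
                     is_planar=True, plane_point=mean, plane_normal=normal)


def fit_sphere(L: np.ndarray) -> SphereFit:
    """Fit a sphere to K >= 4 points: algebraic seed + geometric refinement."""
    L = np.asarray(L, dtype=float)
    if len(L) < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    extent = float(np.linalg.norm(L.max(axis=0) - L.min(axis=0)))
    plane = _plane_fallback(L)
    # algebraic fit: ||p||^2 = 2 p.c + (r^2 - ||c||^2); for (near-)coplanar
    # points this system is rank-deficient and yields a bogus small sphere,
    # so the plane model competes on rms residual below
    A = np.column_stack([2 * L, np.ones(len(L))])
    b = (L ** 2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return plane
    c0 = sol[:3]
    r2 = sol[3] + c0 @ c0
    if r2 <= 0 or not np.isfinite(r2):
        return plane

    def resid(c):
        return np.linalg.norm(L - c, axis=1) - np.linalg.norm(L - c, axis=1).mean()

    try:
        opt = least_squares(resid, c0, method="lm")
        center = opt.x
    except Exception:
        center = c0
    d = np.linalg.norm(L - center, axis=1)
    radius = float(d.mean())
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    if (not np.isfinite(radius) or radius > 10.0 * max(extent, 1e-9)
            or rms >= plane.rms_residual):
        return plane
    return SphereFit(center=center, radius=radius, rms_residual=rms)


def radial_project(ideal: IdealGrid, sf: SphereFit) -> np.ndarray:
    """Project ideal lattice coordinates onto the fitted sphere (or plane).

    Spherical case: p -> center + radius * (p - center)/||p - center||.
    Planar fallback: orthogonal projection onto the best-fit plane.
    """
    pts = ideal.flat()
    if sf.is_planar:
        X = pts - sf.plane_point
        out = pts - np.outer(X @ sf.plane_normal, sf.plane_normal)
        return out.reshape(ideal.rows, ideal.cols, 3)
    vec = pts - sf.center
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("ideal point coincides with sphere center")
    out = sf.center + sf.radius * vec / norms[:, None]
    return out.reshape(ideal.rows, ideal.cols, 3)


def assign_indices(real: np.ndarray, ideal_proj: np.ndarray) -> np.ndarray:
    """Greedy short-to-long distance matching of real contacts to ideal indices.

    All real-ideal pairs are sorted by Euclidean distance ascending (ties
    by real row then ideal index) and indices are assigned one by one,
    skipping pairs whose real contact or ideal index is already taken.
    Returns mapping[real_row] = ideal index (1-based), a bijection.
    """
    real = np.asarray(real, dtype=float)
    ideal = np.asarray(ideal_proj, dtype=float).reshape(-1, 3)
    K = len(real)
    if len(ideal) != K:
        raise ValueError("real and ideal must have the same length")
    d = np.linalg.norm(real[:, None, :] - ideal[None, :, :], axis=2)
    ri, ii = np.unravel_index(np.lexsort((np.tile(np.arange(K), K),
                                          np.repeat(np.arange(K), K),
                                          d.ravel())), d.shape)
    mapping = np.zeros(K, dtype=int)
    used_ideal = np.zeros(K, dtype=bool)
    n_done = 0
    for r, i in zip(ri, ii):
        if mapping[r] or used_ideal[i]:
            continue
        mapping[r] = i + 1
        used_ideal[i] = True
        n_done += 1
        if n_done == K:
            break
    return mapping


def _lattice_neighbour_index_pairs(rows: int, cols: int) -> list[tuple[int, int]]:
    """1-based row-major index pairs adjacent in the lattice (|dr|+|dc| = 1)."""
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c + 1
            if c + 1 < cols:
                pairs.append((i, i + 1))
            if r + 1 < rows:
                pairs.append((i, i + cols))
    return pairs


def permute_refine(mapping: np.ndarray, real: np.ndarray,
                   ideal_proj: np.ndarray, spec) -> np.ndarray:
    """Refine a grid numbering by swapping lattice-neighbour index pairs.

    Two hill-climbing passes, each restarting its sweep after any accepted
    swap and stopping when a full sweep accepts nothing:

    1. minimise the sum of real-to-ideal distances;
    2. minimise the sum of distances between real contacts holding
       lattice-adjacent indices (neighbour smoothness of the real grid).

    Each pass strictly decreases its objective, so both terminate.
    """
    real = np.asarray(real, dtype=float)
    ideal = np.asarray(ideal_proj, dtype=float).reshape(-1, 3)
    mapping = np.asarray(mapping, dtype=int).copy()
    rows, cols = spec.rows, spec.cols
    pairs = _lattice_neighbour_index_pairs(rows, cols)

    def pos_of(mapping):
        pos = np.zeros(len(mapping) + 1, dtype=int)
        pos[mapping] = np.arange(len(mapping))
        return pos

    def obj_ideal(mapping):
        return float(np.linalg.norm(real - ideal[mapping - 1], axis=1).sum())

    def obj_neigh(mapping):
        pos = pos_of(mapping)
        tot = 0.0
        for i, j in pairs:
            tot += float(np.linalg.norm(real[pos[i]] - real[pos[j]]))
        return tot

    for objective in (obj_ideal, obj_neigh):
        current = objective(mapping)
        improved = True
        while improved:
            improved = False
            pos = pos_of(mapping)
            for i, j in pairs:
                a, b = pos[i], pos[j]
                mapping[a], mapping[b] = j, i
                trial = objective(mapping)
                if trial < current - 1e-12:
                    current = trial
                    improved = True
                    break
                mapping[a], mapping[b] = i, j
    return mapping


def number_grid(es: ElectrodeSet) -> ElectrodeSet:
    """Run the full grid-numbering procedure and set contact indices.

    The resulting numbering is correct up to the lattice symmetries of the
    grid (global flips/rotations), which are resolved manually with
    :func:`flip_rotate` against the implantation diagram.
    """
    if es.spec.kind != "grid":
        raise ValueError("number_grid applies to grid arrays")
    spec = es.spec
    p2 = project_pca2(es.L)
    _, corner_ids = hull_corners(p2)
    # traverse counter-clockwise from a canonical corner (lexicographically
    # smallest 2D coordinates) so numbering ignores storage order; the
    # residual ambiguity is the usual manual flip/rotate
    start = int(np.lexsort((p2[corner_ids, 1], p2[corner_ids, 0]))[0])
    corner_ids = np.roll(corner_ids, -start)
    corners = es.L[corner_ids]
    # orient so the c0->c1 edge is the column direction (pitch-consistent)
    e01 = np.linalg.norm(corners[0] - corners[1])
    e03 = np.linalg.norm(corners[0] - corners[3])
    p = spec.pitch
    keep = (abs(e01 - (spec.cols - 1) * p) + abs(e03 - (spec.rows - 1) * p))
    swap = (abs(e01 - (spec.rows - 1) * p) + abs(e03 - (spec.cols - 1) * p))
    if swap < keep:
        corners = corners[[0, 3, 2, 1]]  # reverse traversal: other edge first
    ideal = build_ideal_grid(corners, spec.rows, spec.cols)
    sf = fit_sphere(es.L)
    proj = radial_project(ideal, sf).reshape(-1, 3)
    mapping = assign_indices(es.L, proj)
    mapping = permute_refine(mapping, es.L, proj, spec)
    return ElectrodeSet(L=es.L, spec=spec, indices=mapping, names=es.names)


# ------------------------------------------------------- orientation & naming

def flip_rotate(es: ElectrodeSet, op: str) -> ElectrodeSet:
    """Re-index a numbered grid by a lattice symmetry; coordinates untouched.

    op is one of flip_ud, flip_lr, rot_cw, rot_ccw.  Rotating a non-square
    grid swaps rows and cols in the spec.
    """
    if es.indices is None:
        raise ValueError("indices not set")
    if es.spec.kind != "grid":
        raise ValueError("flip_rotate applies to grids")
    rows, cols = es.spec.rows, es.spec.cols
    rc = np.array([divmod(i - 1, cols) for i in es.indices])
    r, c = rc[:, 0], rc[:, 1]
    spec = es.spec
    if op == "flip_ud":
        r2, c2, nrows, ncols = rows - 1 - r, c, rows, cols
    elif op == "flip_lr":
        r2, c2, nrows, ncols = r, cols - 1 - c, rows, cols
    elif op == "rot_cw":
        r2, c2, nrows, ncols = c, rows - 1 - r, cols, rows
    elif op == "rot_ccw":
        r2, c2, nrows, ncols = cols - 1 - c, r, cols, rows
    else:
        raise ValueError(f"unknown op {op!r}")
    if (nrows, ncols) != (rows, cols):
        spec = replace(spec, rows=nrows, cols=ncols)
    indices = r2 * ncols + c2 + 1
    return ElectrodeSet(L=es.L, spec=spec, indices=indices, names=es.names)


def name_electrodes(es: ElectrodeSet, labels) -> ElectrodeSet:
    """Name contacts as prefix+index, or from an ordered list matched by index."""
    if es.indices is None:
        raise ValueError("indices not set; number the array first")
    if isinstance(labels, str):
        names = [f"{labels}{i}" for i in es.indices]
    else:
        labels = list(labels)
        if len(labels) != es.K:
            raise ValueError(f"expected {es.K} names, got {len(labels)}")
        names = [labels[i - 1] for i in es.indices]
    return ElectrodeSet(L=es.L, spec=es.spec, indices=es.indices, names=names)
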