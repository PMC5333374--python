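"""Synthetic CT phantoms with known contact positions.

The generator emulates the imaging situation the localization pipeline
faces: a spherical brain at soft-tissue intensity (~50 HU) surrounded by
a high-intensity skull shell, with each metal contact rendered as a
bright compact artifact — a truncated Gaussian intensity kernel peaking
in the 2,200-3,200 HU range — plus additive Gaussian noise.  Grids are
laid on a spherical cap at fixed pitch (10 mm standard) via the sphere's
exponential map; depth arrays are collinear at 5, 6 or 10 mm pitch with
contact 1 at the deep tip.  Ground truth (coordinates in index order,
surface parameters) is emitted alongside the volume so every pipeline
stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_volumes import BinaryMask, Volume
from .atlas import Atlas
from .localization import ElectrodeArraySpec
from .metrics import RaterLocalizations

__all__ = ["GridPlacement", "DepthPlacement", "ArrayTruth", "PhantomTruth",
           "make_phantom", "make_synthetic_atlas", "simulate_raters",
           "grid_cap_coordinates", "depth_line_coordinates"]


@dataclass(frozen=True)
class GridPlacement:
    """A grid on a spherical cap: sphere center/radius, pole direction,
    in-plane rotation (degrees).  radius=None lays the grid flat in the
    plane tangent at ``center + extent*pole``."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float | None = 80.0
    pole: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_deg: float = 0.0


@dataclass(frozen=True)
class DepthPlacement:
    """A collinear depth array: tip coordinate (contact 1, deepest) and
    unit direction from tip towards the entry point."""

    tip: tuple[float, float, float]
    direction: tuple[float, float, float]


def _orthonormal_frame(pole: np.ndarray, rotation_deg: float):
    w = pole / np.linalg.norm(pole)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ w) * w
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    th = np.radians(rotation_deg)
    f1 = np.cos(th) * e1 + np.sin(th) * e2
    f2 = -np.sin(th) * e1 + np.cos(th) * e2
    return f1, f2, w


def grid_cap_coordinates(spec: ElectrodeArraySpec,
                         place: GridPlacement) -> np.ndarray:
    """Ground-truth grid coordinates on the spherical cap (or flat plane).

    Contacts are placed with the sphere's exponential map at the cap
    pole: the lattice offset (a, b) in mm maps to the point at geodesic
    distance sqrt(a^2+b^2) from the pole, so pitch is exact along the two
    central geodesic axes.  Row-major index order (contact 1 first).
    """
    f1, f2, w = _orthonormal_frame(np.asarray(place.pole, dtype=float),
                                   place.rotation_deg)
    center = np.asarray(place.center, dtype=float)
    rows, cols, p = spec.rows, spec.cols, spec.pitch
    a = (np.arange(cols) - (cols - 1) / 2) * p
    b = (np.arange(rows) - (rows - 1) / 2) * p
    A, B = np.meshgrid(a, b)               # row-major: row r varies b
    tangent = A[..., None] * f1 + B[..., None] * f2
    if place.radius is None:
        pts = center + tangent
        return pts.reshape(-1, 3)
    R = float(place.radius)
    dist = np.sqrt(A ** 2 + B ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        that = np.where(dist[..., None] > 0, tangent / np.maximum(dist, 1e-300)[..., None], 0.0)
    ang = dist / R
    pts = center + R * (np.cos(ang)[..., None] * w + np.sin(ang)[..., None] * that)
    return pts.reshape(-1, 3)


def depth_line_coordinates(spec: ElectrodeArraySpec,
                           place: DepthPlacement) -> np.ndarray:
    """Ground-truth collinear depth coordinates, contact 1 at the tip."""
    tip = np.asarray(place.tip, dtype=float)
    d = np.asarray(place.direction, dtype=float)
    d = d / np.linalg.norm(d)
    return tip + np.outer(np.arange(spec.K) * spec.pitch, d)


@dataclass
class ArrayTruth:
    """One array's ground truth: spec, coordinates in index order, and the
    generating surface (sphere parameters for grids, axis for depths)."""

    spec: ElectrodeArraySpec
    coords: np.ndarray            # (K, 3), row k holds contact k+1
    surface: dict

    def as_dict(self) -> dict:
        return {"spec": {"kind": self.spec.kind, "rows": self.spec.rows,
                         "cols": self.spec.cols, "pitch": self.spec.pitch,
                         "prefix": self.spec.prefix},
                "coords": self.coords.tolist(),
                "surface": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in self.surface.items()}}


@dataclass
class PhantomTruth:
    """Full phantom ground truth, reproducible from its seed."""

    arrays: list[ArrayTruth]
    brain_center: np.ndarray
    brain_radius: float
    noise_sd: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {"arrays": [a.as_dict() for a in self.arrays],
                   "brain_center": self.brain_center.tolist(),
                   "brain_radius": self.brain_radius,
                   "noise_sd": self.noise_sd, "seed": self.seed}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


_BACKGROUND_HU = 50.0
_SKULL_HU = 1500.0
_GRID_PEAK_HU = 3200.0
_DEPTH_PEAK_HU = 3200.0
_MARKER_PEAK_HU = 2800.0
# Kernel radii are sized so that every contact keeps at least one voxel
# above 2,200 HU at the worst-case half-voxel alignment on a 1 mm grid,
# neighbouring contacts at 5 mm pitch stay separable down to 1,200 HU,
# and merge below ~800 HU — the operating envelope of a threshold sweep
# on real depth-electrode artifacts.
_GRID_KERNEL_RADIUS = 2.4    # mm; blooming artifact of 4 mm grid contacts
_DEPTH_KERNEL_RADIUS = 3.0   # mm; blooming artifact of 1.1-1.3 mm shafts
_MARKER_KERNEL_RADIUS = 2.0


def _render_kernel(data: np.ndarray, affine_inv: np.ndarray, center: np.ndarray,
                   peak: float, radius_mm: float) -> None:
    """Add one truncated-Gaussian artifact (sd = radius/2, cut at 2.5 sd).

    The smooth intensity falloff mimics partial-volume blur around metal
    and is what exercises the intensity-weighted centroid.
    """
    sd = radius_mm / 2.0
    cut = 2.5 * sd
    cvox = affine_inv[:3, :3] @ center + affine_inv[:3, 3]
    # voxel extent of the truncation sphere (assumes near-isotropic affine)
    step = np.linalg.norm(np.linalg.inv(affine_inv)[:3, :3], axis=0)
    lo = np.maximum(np.floor(cvox - cut / step - 1).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + cut / step + 2).astype(int), data.shape)
    if np.any(lo >= hi):
        raise ValueError("contact placement outside volume")
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    aff = np.linalg.inv(affine_inv)
    xyz = (aff[:3, :3] @ np.stack([ii, jj, kk]).reshape(3, -1)).T + aff[:3, 3]
    d2 = ((xyz - center) ** 2).sum(axis=1)
    vals = np.where(d2 <= cut ** 2, peak * np.exp(-d2 / (2 * sd ** 2)), 0.0)
    block = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(block, vals.reshape(block.shape), out=block)


def make_phantom(arrays, shape=(200, 200, 200), noise_sd: float = 0.0,
                 seed: int = 0, brain_radius: float = 80.0,
                 marker: bool = False):
    """Render a CT phantom with known electrode positions.

    ``arrays`` is a list of (ElectrodeArraySpec, placement) pairs where
    the placement is a GridPlacement (grids) or DepthPlacement
    (depths/strips).  Returns (Volume, BinaryMask, PhantomTruth); the
    volume's affine puts the brain center at world (0, 0, 0) with 1 mm
    isotropic voxels.  ``marker=True`` adds a bright marker blob between
    contacts 1 and 2 of each grid, a spurious component the selection
    step must remove.
    """
    shape = tuple(int(s) for s in shape)
    center_vox = (np.array(shape) - 1) / 2.0
    affine = np.eye(4)
    affine[:3, 3] = -center_vox
    affine_inv = np.linalg.inv(affine)

    ii = np.arange(shape[0])[:, None, None] - center_vox[0]
    jj = np.arange(shape[1])[None, :, None] - center_vox[1]
    kk = np.arange(shape[2])[None, None, :] - center_vox[2]
    r2 = ii ** 2 + jj ** 2 + kk ** 2
    brain = r2 <= brain_radius ** 2
    # skull shell sits 12 mm out so that cube-kernel mask dilation (which
    # reaches sqrt(3) x iterations along diagonals) cannot swallow it
    skull = (r2 >= (brain_radius + 12.0) ** 2) & (r2 <= (brain_radius + 15.0) ** 2)
    data = np.zeros(shape, dtype=float)
    data[brain] = _BACKGROUND_HU
    data[skull] = _SKULL_HU

    truths: list[ArrayTruth] = []
    kernels: list[tuple[np.ndarray, float, float]] = []
    for spec, place in arrays:
        if isinstance(place, GridPlacement):
            coords = grid_cap_coordinates(spec, place)
            surface = {"type": "sphere_cap",
                       "center": np.asarray(place.center, dtype=float),
                       "radius": place.radius,
                       "pole": np.asarray(place.pole, dtype=float)}
            peak, rad = _GRID_PEAK_HU, _GRID_KERNEL_RADIUS
        elif isinstance(place, DepthPlacement):
            coords = depth_line_coordinates(spec, place)
            surface = {"type": "line",
                       "tip": np.asarray(place.tip, dtype=float),
                       "direction": np.asarray(place.direction, dtype=float)}
            peak, rad = _DEPTH_PEAK_HU, _DEPTH_KERNEL_RADIUS
        else:
            raise TypeError(f"unsupported placement {type(place).__name__}")
        kernels.extend((c, peak, rad) for c in coords)
        if marker and isinstance(place, GridPlacement):
            mid = 0.5 * (coords[0] + coords[1])
            kernels.append((mid, _MARKER_PEAK_HU, _MARKER_KERNEL_RADIUS))
        truths.append(ArrayTruth(spec=spec, coords=coords, surface=surface))

    all_coords = np.vstack([t.coords for t in truths])
    if len(all_coords) > 1:
        from scipy.spatial.distance import pdist
        min_spacing = pdist(all_coords).min()
        if min_spacing < 2.0:
            raise ValueError(
                f"contacts overlap: min spacing {min_spacing:.2f} mm < 2 mm")
    for c, peak, rad in kernels:
        _render_kernel(data, affine_inv, c, peak, rad)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=shape)

    vol = Volume(data=data, affine=affine, units="HU")
    mask = BinaryMask(data=brain, affine=affine)
    truth = PhantomTruth(arrays=truths, brain_center=np.zeros(3),
                         brain_radius=brain_radius, noise_sd=noise_sd,
                         seed=seed)
    return vol, mask, truth


def make_synthetic_atlas(regions, shape, affine, scale: float = 100.0) -> Atlas:
    """Build a probabilistic atlas from geometric predicates.

    ``regions`` is a list of (name, predicate) where the predicate maps
    an (N, 3) array of world coordinates to membership in [0, 1] (bool
    arrays are accepted).  Probabilities are stored on a 0-``scale`` map.
    """
    if not regions:
        raise ValueError("need at least one region")
    affine = np.asarray(affine, dtype=float)
    shape = tuple(int(s) for s in shape)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    xyz = idx @ affine[:3, :3].T + affine[:3, 3]
    maps = np.zeros(shape + (len(regions),), dtype=float)
    names = []
    for n, (name, pred) in enumerate(regions):
        vals = np.asarray(pred(xyz), dtype=float).reshape(shape)
        maps[..., n] = np.clip(vals, 0.0, 1.0) * scale
        names.append(name)
    return Atlas(maps=maps, affine=affine, region_names=names)


def simulate_raters(truth: np.ndarray, R: int, jitter_sd: float,
                    seed: int = 0, method_tag: str = "manual") -> RaterLocalizations:
    """Simulate R raters localizing K contacts with isotropic Gaussian jitter."""
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    if R < 1:
        raise ValueError("need at least one rater")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    coords = truth[:, None, :] + rng.normal(0.0, jitter_sd,
                                            size=(len(truth), R, 3))
    return RaterLocalizations(coords=coords, method_tag=method_tag)
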