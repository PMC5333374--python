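"""Probabilistic-atlas anatomical labeling of contact coordinates.

A 4D atlas stores one 3D probability map per region (values 0-100 or
0-1, e.g. the Harvard-Oxford cortical atlas as distributed with FSL)
plus an ordered region-name table.  Each contact is labeled by nearest-
voxel lookup of every region map at its coordinate; probabilities are
reported exactly as sampled, ranked descending, with lexicographic
tie-breaking.  Interpolation is deliberately avoided: labels are
categorical evidence and blending across region boundaries misleads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .localization import ElectrodeSet

__all__ = ["Atlas", "load_atlas", "save_atlas", "label_point", "label_set"]


@dataclass
class Atlas:
    """4D probabilistic atlas: one probability map per named region."""

    maps: np.ndarray          # (i, j, k, n_regions)
    affine: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("atlas maps must be 4D")
        if self.maps.shape[3] != len(self.region_names):
            raise ValueError("region_names length must match 4th dimension")
        if np.any(self.maps < 0):
            raise ValueError("probabilities must be non-negative")


def load_atlas(nifti_path: str | Path, names_path: str | Path) -> Atlas:
    """Load a 4D NIfTI atlas and its sidecar TSV of (index, name) rows."""
    img = nib.load(str(nifti_path))
    maps = np.asanyarray(img.dataobj)
    if maps.ndim != 4:
        raise ValueError("expected 4D atlas image")
    table = pd.read_csv(names_path, sep="\t")
    names = table.sort_values(table.columns[0])[table.columns[1]].tolist()
    return Atlas(maps=maps, affine=np.asarray(img.affine, dtype=float),
                 region_names=names)


def save_atlas(atlas: Atlas, nifti_path: str | Path, names_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.maps.astype(np.float32), atlas.affine),
             str(nifti_path))
    pd.DataFrame({"index": range(len(atlas.region_names)),
                  "name": atlas.region_names}).to_csv(names_path, sep="\t",
                                                      index=False)


def label_point(atlas: Atlas, xyz, top_n: int = 3) -> list[tuple[str, float]]:
    """Rank regions by sampled probability at a world-mm coordinate.

    Nearest-voxel lookup; regions with probability zero are dropped.
    Out-of-bounds coordinates return an empty list (flagged upstream as
    outside the atlas); a point where every map is zero returns [].
    """
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(atlas.affine)
    ijk = np.round(inv[:3, :3] @ xyz + inv[:3, 3]).astype(int)
    shape = np.array(atlas.maps.shape[:3])
    if np.any(ijk < 0) or np.any(ijk >= shape):
        return []
    probs = atlas.maps[ijk[0], ijk[1], ijk[2], :]
    hits = [(atlas.region_names[i], float(probs[i]))
            for i in np.flatnonzero(probs > 0)]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits[:top_n]


def label_set(atlas: Atlas, es: ElectrodeSet, top_n: int = 3) -> pd.DataFrame:
    """Label every contact of a named ElectrodeSet.

    Returns one row per contact with the best label, its probability, and
    up to top_n-1 ranked alternates.  Contacts outside the atlas are
    flagged 'outside atlas'; contacts where all maps are zero are
    'unlabeled'.  Per-row failures never abort the table.
    """
    if es.names is None:
        raise ValueError("electrodes must be named before labeling")
    rows = []
    inv = np.linalg.inv(atlas.affine)
    shape = np.array(atlas.maps.shape[:3])
    for name, idx, xyz in zip(es.names, es.indices, es.L):
        ijk = np.round(inv[:3, :3] @ xyz + inv[:3, 3]).astype(int)
        outside = bool(np.any(ijk < 0) or np.any(ijk >= shape))
        ranked = [] if outside else label_point(atlas, xyz, top_n=top_n)
        if outside:
            best, prob, alt = "outside atlas", np.nan, ""
        elif not ranked:
            best, prob, alt = "unlabeled", 0.0, ""
        else:
            best, prob = ranked[0]
            alt = "; ".join(f"{n} ({p:g})" for n, p in ranked[1:])
        rows.append({"name": name, "index": int(idx),
                     "x_mm": xyz[0], "y_mm": xyz[1], "z_mm": xyz[2],
                     "label": best, "probability": prob, "alternates": alt})
    df = pd.DataFrame(rows)
    return df.sort_values("index").reset_index(drop=True)
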