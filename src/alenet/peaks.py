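"""Network-node extraction from thresholded statistic maps.

Nodes of the meta-analytic network are local maxima of thresholded z maps,
restricted to grey matter, with a minimum inter-peak distance (15 mm by
default).  Peaks from different maps closer than that distance collapse to
the one with the higher z score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .ale import StatMap

__all__ = ["Peak", "NodeSet", "extract_peaks", "merge_across_maps",
           "read_node_table", "write_node_table", "load_reference_nodes"]


@dataclass(frozen=True)
class Peak:
    xyz: tuple
    z: float
    source_map: str = ""


@dataclass(frozen=True)
class NodeSet:
    """An ordered set of network nodes (MNI mm coordinates with labels)."""

    coords: np.ndarray  # (n, 3) mm
    regions: tuple = ()
    hemispheres: tuple = ()
    z: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = len(coords)
        regions = tuple(self.regions) if self.regions else tuple(f"node{i:02d}" for i in range(n))
        hemis = tuple(self.hemispheres) if self.hemispheres else ("",) * n
        if len(regions) != n or len(hemis) != n:
            raise ValueError("labels do not match number of coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "hemispheres", hemis)
        if self.z is not None:
            object.__setattr__(self, "z", np.asarray(self.z, dtype=float))

    def __len__(self):
        return len(self.coords)

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d ** 2).sum(axis=-1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"region": self.regions, "hemisphere": self.hemispheres,
             "x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2]}
        )
        return df


def _local_maxima(data: np.ndarray, eligible: np.ndarray) -> np.ndarray:
    """Voxels >= all 26 neighbours, restricted to eligible nonzero voxels."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = data >= ndimage.maximum_filter(data, footprint=footprint, mode="constant", cval=-np.inf)
    return np.argwhere(local_max & eligible & (data > 0))


def extract_peaks(zmap: StatMap, gm_mask: np.ndarray | None = None,
                  min_distance: float = 15.0, source: str = "") -> list:
    """Greedy peak selection in descending z with a minimum spacing in mm.

    The input z map must be thresholded (zeros outside significant clusters).
    Only grey-matter voxels are eligible.  Plateaus: the lexicographically
    first voxel of a plateau wins (deterministic tie rule).
    """
    grid = zmap.grid
    eligible = grid.mask if gm_mask is None else (grid.mask & gm_mask)
    cand = _local_maxima(zmap.data, eligible)
    if len(cand) == 0:
        return []
    zs = zmap.data[cand[:, 0], cand[:, 1], cand[:, 2]]
    # sort by z descending, then lexicographic voxel index
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -zs))
    accepted_mm, peaks = [], []
    for idx in order:
        xyz = grid.vox_to_mm(cand[idx])[0]
        if accepted_mm:
            d = np.sqrt(((np.array(accepted_mm) - xyz) ** 2).sum(axis=1))
            if (d < min_distance).any():
                continue
        accepted_mm.append(xyz)
        peaks.append(Peak(xyz=tuple(xyz), z=float(zs[idx]), source_map=source))
    return peaks


def merge_across_maps(peak_lists, min_distance: float = 15.0) -> NodeSet:
    """Merge peak lists from several maps into one node set.

    Cross-map pairs closer than `min_distance` collapse to the higher-z peak.
    z ties: the peak from the earlier-listed map wins, then lexicographic
    coordinate order.
    """
    flat = []
    for m, plist in enumerate(peak_lists):
        for p in plist:
            flat.append((p, m))
    if not flat:
        return NodeSet(coords=np.empty((0, 3)))
    keys = sorted(
        range(len(flat)),
        key=lambda i: (-flat[i][0].z, flat[i][1], flat[i][0].xyz),
    )
    accepted = []
    for i in keys:
        p = flat[i][0]
        xyz = np.array(p.xyz)
        if accepted:
            d = np.sqrt(((np.array([a.xyz for a in accepted]) - xyz) ** 2).sum(axis=1))
            if (d < min_distance).any():
                continue
        accepted.append(p)
    coords = np.array([a.xyz for a in accepted])
    return NodeSet(coords=coords,
                   regions=tuple(a.source_map or f"node{i:02d}" for i, a in enumerate(accepted)),
                   z=np.array([a.z for a in accepted]))


NODE_COLUMNS = ["region", "hemisphere", "x", "y", "z"]


def read_node_table(path) -> NodeSet:
    """Read a node TSV (region, hemisphere, x, y, z), preserving file order."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty node table") from None
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a node table, missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty node table")
    coords = np.empty((len(df), 3))
    for k, col in enumerate(["x", "y", "z"]):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise ValueError(f"{path}: non-numeric coordinate in column '{col}' at line {row}")
        coords[:, k] = vals
    return NodeSet(coords=coords, regions=tuple(df["region"].fillna("")),
                   hemispheres=tuple(df["hemisphere"].fillna("")))


def write_node_table(nodes: NodeSet, path) -> None:
    nodes.to_frame().to_csv(path, sep="\t", index=False)


def load_reference_nodes() -> NodeSet:
    """The 21 meta-analytic impulsivity-network nodes shipped with the package."""
    with resources.as_file(resources.files("alenet.data") / "impulsivity_nodes.tsv") as p:
        return read_node_table(p)
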