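"""Receptor/annotation-map association testing with a spatial null model.

Volumetric annotation maps (e.g. PET-derived receptor density) are resampled
to the analysis grid, rescaled to [0, 100], and sampled at the network nodes
(mean within small spheres).  Node-wise graph metrics are screened against
the density profiles by Spearman correlation in two datasets; survivors are
tested against a distance-constrained random-network null: random node sets
from grey matter whose pairwise-distance summaries (min / mean / max) match
the empirical network's within one standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .grid import VolumeGrid, sphere_voxels
from .peaks import NodeSet

__all__ = [
    "resample_map", "rescale_map", "sample_node_density", "screen_correlations",
    "random_network_null", "null_test", "NullEnsemble",
]


def resample_map(img, target_grid: VolumeGrid, interpolation: str = "linear"):
    """Resample a nibabel image onto `target_grid` (trilinear by default;
    'nearest' for label maps).  Errors if the fields of view do not overlap."""
    from nilearn.image import resample_img

    src_shape = img.shape[:3]
    inv = np.linalg.inv(img.affine)
    centers = target_grid.masked_mm()
    vox = centers @ inv[:3, :3].T + inv[:3, 3]
    inside = np.all((vox > -0.5) & (vox < np.array(src_shape) - 0.5), axis=1)
    if not inside.any():
        raise ValueError("source and target fields of view do not overlap")
    out = resample_img(
        img, target_affine=target_grid.affine, target_shape=target_grid.shape,
        interpolation=interpolation, force_resample=True, copy_header=True,
    )
    return out


def rescale_map(data: np.ndarray, mask: np.ndarray | None = None):
    """Linearly rescale values over the mask to min 0 / max 100.

    Returns (rescaled, record) where record holds the original extremes.
    Idempotent; errors on constant input.
    """
    data = np.asarray(data, dtype=float)
    sel = np.ones(data.shape, dtype=bool) if mask is None else mask
    lo, hi = float(data[sel].min()), float(data[sel].max())
    if hi == lo:
        raise ValueError("map is constant over the mask; cannot rescale")
    out = np.zeros_like(data)
    out[sel] = (data[sel] - lo) / (hi - lo) * 100.0
    return out, {"original_min": lo, "original_max": hi}


def sample_node_density(data: np.ndarray, grid: VolumeGrid, nodes: NodeSet,
                        gm_mask: np.ndarray | None = None,
                        radius_mm: float = 2.5) -> np.ndarray:
    """Mean map value within a sphere (default 5 mm *diameter*) around each node."""
    gm = grid.mask if gm_mask is None else (grid.mask & gm_mask)
    out = np.empty(len(nodes))
    for i, xyz in enumerate(nodes.coords):
        idx = sphere_voxels(grid, xyz, radius_mm, restrict_mask=gm)
        if len(idx) == 0:
            raise ValueError(f"node {i} ({nodes.regions[i]}): sampling sphere is empty")
        out[i] = data[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
    return out


def screen_correlations(metric_by_dataset: dict, profiles_by_map: dict,
                        threshold: float = 0.3) -> pd.DataFrame:
    """Spearman rho of each density profile against the node metric in each
    dataset; a map passes iff |rho| > threshold in *both* datasets with
    matching sign.

    Returns a tidy frame with one row per map: rho_<dataset> columns plus a
    boolean `passes`.  Constant inputs yield NaN and fail the screen.
    """
    if len(metric_by_dataset) != 2:
        raise ValueError("screen requires exactly two datasets (discovery + replication)")
    names = list(metric_by_dataset)
    rows = []
    for map_name, profile in profiles_by_map.items():
        profile = np.asarray(profile, dtype=float)
        rhos = {}
        for ds in names:
            metric = np.asarray(metric_by_dataset[ds], dtype=float)
            if len(metric) != len(profile):
                raise ValueError(f"{map_name}/{ds}: node orders not aligned")
            if np.ptp(metric) == 0 or np.ptp(profile) == 0:
                import warnings
                warnings.warn(f"{map_name}/{ds}: constant vector, rho undefined", stacklevel=2)
                rhos[ds] = np.nan
            else:
                rhos[ds] = stats.spearmanr(metric, profile).statistic
        r = np.array([rhos[ds] for ds in names])
        passes = bool(np.all(np.abs(r) > threshold) and np.all(np.isfinite(r))
                      and np.sign(r[0]) == np.sign(r[1]))
        rows.append({"map": map_name, **{f"rho_{ds}": rhos[ds] for ds in names},
                     "passes": passes})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NullEnsemble:
    """Distance-constrained random node sets with their null correlations."""

    node_sets: np.ndarray = field(repr=False)  # (n_networks, n_nodes, 3) mm
    null_rho: np.ndarray = field(repr=False)
    constraints: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.node_sets)


def _distance_summary(coords: np.ndarray):
    d = pdist(coords)
    return d.min(), d.mean(), d.max(), d.std()


def _sphere_offsets(grid: VolumeGrid, radius_mm: float) -> np.ndarray:
    """Voxel-index offsets whose centres fall within radius of a voxel centre."""
    span = np.ceil(radius_mm / grid.voxel_sizes).astype(int)
    ax = [np.arange(-s, s + 1) for s in span]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    off = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    mm = off * grid.voxel_sizes
    keep = (mm ** 2).sum(axis=1) <= radius_mm ** 2
    return off[keep]


def random_network_null(
    empirical_nodes: NodeSet,
    grid: VolumeGrid,
    map_data: np.ndarray,
    metric: np.ndarray,
    gm_mask: np.ndarray | None = None,
    n_networks: int = 1000,
    radius_mm: float = 2.5,
    sd_band: float | None = None,
    seed=None,
    max_attempts_factor: int = 10000,
) -> NullEnsemble:
    """Build the distance-constrained random-network null distribution.

    Node sets of the empirical size are rejection-sampled from grey-matter
    voxel centres; a set is accepted iff its minimum, mean and maximum
    pairwise Euclidean distance each lie within one standard deviation (the
    SD of the empirical network's pairwise-distance distribution, or an
    explicit `sd_band` in mm) of the empirical min/mean/max.  For each
    accepted network the Spearman rho between `metric` and that network's
    density profile is stored.
    """
    gm = grid.mask if gm_mask is None else (grid.mask & gm_mask)
    metric = np.asarray(metric, dtype=float)
    n_nodes = len(empirical_nodes)
    if len(metric) != n_nodes:
        raise ValueError("metric length must match node count")
    emp_min, emp_mean, emp_max, emp_sd = _distance_summary(empirical_nodes.coords)
    band = emp_sd if sd_band is None else float(sd_band)

    gm_idx = np.argwhere(gm)
    gm_mm = grid.vox_to_mm(gm_idx)
    offsets = _sphere_offsets(grid, radius_mm)
    rng = np.random.default_rng(seed)

    sets = np.empty((n_networks, n_nodes, 3))
    rhos = np.empty(n_networks)
    got = 0
    attempts = 0
    fails = {"min": 0, "mean": 0, "max": 0}
    max_attempts = max_attempts_factor * n_networks
    while got < n_networks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rejection sampling acceptance rate below 1/{max_attempts_factor}; "
                f"constraint failure counts: {fails} (band={band:.2f} mm)"
            )
        attempts += 1
        pick = rng.choice(len(gm_idx), size=n_nodes, replace=False)
        coords = gm_mm[pick]
        dmin, dmean, dmax, _ = _distance_summary(coords)
        ok = True
        if abs(dmin - emp_min) > band:
            fails["min"] += 1
            ok = False
        if abs(dmean - emp_mean) > band:
            fails["mean"] += 1
            ok = False
        if abs(dmax - emp_max) > band:
            fails["max"] += 1
            ok = False
        if not ok:
            continue
        profile = np.empty(n_nodes)
        centers = gm_idx[pick]
        for i, c in enumerate(centers):
            vox = c + offsets
            inb = np.all((vox >= 0) & (vox < grid.shape), axis=1)
            vox = vox[inb]
            ingm = gm[vox[:, 0], vox[:, 1], vox[:, 2]]
            vox = vox[ingm]
            profile[i] = map_data[vox[:, 0], vox[:, 1], vox[:, 2]].mean()
        sets[got] = coords
        rhos[got] = stats.spearmanr(metric, profile).statistic
        got += 1

    return NullEnsemble(
        node_sets=sets, null_rho=rhos,
        constraints={"empirical_min": emp_min, "empirical_mean": emp_mean,
                     "empirical_max": emp_max, "band_mm": band,
                     "acceptance_rate": n_networks / attempts},
    )


def null_test(empirical_rho: float, ensemble: NullEnsemble, tail: str = "greater"):
    """Permutation p against the random-network null.

    Default (`tail='greater'`): p is the fraction of null correlations at or
    above the empirical one (add-one estimator), and the association is
    significant iff the empirical rho exceeds the 95th percentile of the
    null.  `tail='less'` and `tail='two-sided'` are available.
    """
    null = np.asarray(ensemble.null_rho, dtype=float)
    if null.size == 0:
        raise ValueError("empty null ensemble")
    n = len(null)
    if tail == "greater":
        b = np.sum(null >= empirical_rho)
        significant = empirical_rho > np.quantile(null, 0.95)
    elif tail == "less":
        b = np.sum(null <= empirical_rho)
        significant = empirical_rho < np.quantile(null, 0.05)
    elif tail == "two-sided":
        b = np.sum(np.abs(null) >= abs(empirical_rho))
        significant = abs(empirical_rho) > np.quantile(np.abs(null), 0.95)
    else:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")
    p = (b + 1) / (n + 1)
    return float(p), bool(significant)
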