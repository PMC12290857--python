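"""Resting-state connectivity from minimally-preprocessed 4D volumes.

Covers motion-based subject exclusion (mean framewise displacement), nuisance
denoising (tissue/global regression, detrend, 0.01-0.1 Hz bandpass, spatial
smoothing), node-sphere time-series extraction, Fisher-z node-to-node FC, and
seed-to-voxel connectivity maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .grid import VolumeGrid, sphere_voxels
from .peaks import NodeSet

__all__ = [
    "fd_filter", "framewise_displacement", "denoise", "sphere_timeseries",
    "fc_matrix", "seed_to_voxel", "NodeTimeSeries", "SeedMapSet", "fisher_z",
]

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class NodeTimeSeries:
    """Node-by-timepoint matrix of sphere-averaged BOLD series."""

    data: np.ndarray = field(repr=False)  # (n_nodes, n_timepoints)
    tr_seconds: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("need a (nodes, >=2 timepoints) matrix")
        if not np.all(np.isfinite(data)):
            raise ValueError("node time series contain non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_nodes(self):
        return self.data.shape[0]


@dataclass(frozen=True)
class SeedMapSet:
    """Per-node group-average Fisher-z seed-to-voxel maps over grey matter."""

    grid: VolumeGrid
    gm_mask: np.ndarray = field(repr=False)
    maps: np.ndarray = field(repr=False)  # (n_nodes, n_gm_voxels)

    def map_volume(self, node: int) -> np.ndarray:
        vol = np.zeros(self.grid.shape)
        vol[self.gm_mask] = self.maps[node]
        return vol


def framewise_displacement(motion_params: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power-convention FD from 6 rigid-body parameters (3 translations mm,
    3 rotations rad): sum of absolute frame-to-frame differences with
    rotations converted to arc length on a 50 mm sphere.  First frame is 0."""
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion_params must be (frames, 6)")
    mp = mp.copy()
    mp[:, 3:] *= rotation_radius_mm
    diffs = np.abs(np.diff(mp, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], diffs])


def fd_filter(fd_traces, threshold_mm: float):
    """Indices of subjects whose mean framewise displacement is <= threshold.

    The boundary is inclusive: a subject at exactly the threshold is kept.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    kept = []
    for i, trace in enumerate(fd_traces):
        trace = np.asarray(trace, dtype=float)
        if trace.size == 0:
            raise ValueError(f"subject {i}: empty motion trace")
        if (trace < 0).any():
            raise ValueError(f"subject {i}: negative framewise displacement")
        if trace.mean() <= threshold_mm:
            kept.append(i)
    return kept


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Drop columns until X has full column rank (warns when dropping)."""
    keep = list(range(X.shape[1]))
    while len(keep) > 1 and np.linalg.matrix_rank(X[:, keep]) < len(keep):
        # drop the last column involved in the deficiency
        for j in range(len(keep) - 1, -1, -1):
            trial = keep[:j] + keep[j + 1:]
            if np.linalg.matrix_rank(X[:, trial]) == np.linalg.matrix_rank(X[:, keep]):
                warnings.warn(f"dropping collinear confound column {keep[j]}", stacklevel=3)
                keep = trial
                break
    return X[:, keep]


def denoise(
    bold: np.ndarray,
    confounds: np.ndarray | None,
    tr_seconds: float,
    band_hz: tuple = (0.01, 0.1),
    smooth_fwhm_mm: float = 5.0,
    voxel_sizes_mm=(2.0, 2.0, 2.0),
) -> np.ndarray:
    """Nuisance-denoise a 4D volume.

    Steps, in order: voxel-wise regression on the confound traces (with
    intercept), linear detrending, zero-phase Butterworth (order 2) bandpass
    within `band_hz`, then spatial Gaussian smoothing at `smooth_fwhm_mm`.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("bold must be 4D (x, y, z, t)")
    n_t = bold.shape[-1]
    flat = bold.reshape(-1, n_t)

    if confounds is not None:
        C = np.atleast_2d(np.asarray(confounds, dtype=float))
        if C.shape[0] != n_t:
            C = C.T
        if C.shape[0] != n_t:
            raise ValueError("confound traces do not match timepoint count")
        X = np.column_stack([np.ones(n_t), C])
        X = _drop_collinear(X)
        beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
        flat = (flat.T - X @ beta).T

    flat = signal.detrend(flat, axis=1, type="linear")

    if band_hz is not None:
        nyq = 0.5 / tr_seconds
        lo, hi = band_hz[0] / nyq, min(band_hz[1] / nyq, 0.999)
        b, a = signal.butter(2, [lo, hi], btype="bandpass")
        # long reflect padding: the 0.01 Hz edge has a slow impulse response
        padlen = min(n_t - 1, max(3 * max(len(a), len(b)), int(3.0 / (band_hz[0] * tr_seconds))))
        flat = signal.filtfilt(b, a, flat, axis=1, padlen=padlen)

    out = flat.reshape(bold.shape)
    if smooth_fwhm_mm and smooth_fwhm_mm > 0:
        sigma = smooth_fwhm_mm * _FWHM_TO_SD / np.asarray(voxel_sizes_mm, dtype=float)
        out = ndimage.gaussian_filter(out, sigma=tuple(sigma) + (0.0,))
    return out


def sphere_timeseries(
    bold: np.ndarray,
    grid: VolumeGrid,
    nodes: NodeSet,
    gm_mask: np.ndarray | None = None,
    radius_mm: float = 5.0,
    tr_seconds: float = 1.0,
) -> NodeTimeSeries:
    """Average the series of grey-matter voxels within `radius_mm` of each node."""
    gm = grid.mask if gm_mask is None else (grid.mask & gm_mask)
    out = np.empty((len(nodes), bold.shape[-1]))
    for i, xyz in enumerate(nodes.coords):
        idx = sphere_voxels(grid, xyz, radius_mm, restrict_mask=gm)
        if len(idx) == 0:
            raise ValueError(f"node {i} ({nodes.regions[i]}): sphere contains no grey-matter voxels")
        out[i] = bold[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)
    return NodeTimeSeries(data=out, tr_seconds=tr_seconds)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 - 1e-7 (degenerate-correlation guard)."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _subject_corr(ts: NodeTimeSeries) -> np.ndarray:
    data = ts.data
    sd = data.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"zero-variance node series at nodes {np.nonzero(dead)[0].tolist()}; "
                      "their edges are undefined (NaN)", stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    return r


def fc_matrix(ts_per_subject) -> np.ndarray:
    """Group FC: per-subject Pearson -> Fisher z, element-wise mean across subjects.

    Diagonal is set to 0 by convention (self-connections excluded).
    """
    ts_per_subject = list(ts_per_subject)
    if not ts_per_subject:
        raise ValueError("need at least one subject")
    n = ts_per_subject[0].n_nodes
    acc = np.zeros((n, n))
    for ts in ts_per_subject:
        if ts.n_nodes != n:
            raise ValueError("subjects disagree on node count")
        acc += fisher_z(_subject_corr(ts))
    z = acc / len(ts_per_subject)
    np.fill_diagonal(z, 0.0)
    return z


def seed_to_voxel(
    bold_per_subject,
    grid: VolumeGrid,
    nodes: NodeSet,
    gm_mask: np.ndarray | None = None,
    radius_mm: float = 5.0,
) -> SeedMapSet:
    """Group-average Fisher-z seed-to-voxel maps for each node.

    `bold_per_subject` yields 4D arrays; per subject the node sphere-mean
    series is correlated with every grey-matter voxel, Fisher z-transformed,
    and maps are averaged across subjects.
    """
    gm = grid.mask if gm_mask is None else (grid.mask & gm_mask)
    gm_idx = np.argwhere(gm)
    acc = None
    n_sub = 0
    for bold in bold_per_subject:
        ts = sphere_timeseries(bold, grid, nodes, gm_mask=gm, radius_mm=radius_mm)
        vox = bold[gm_idx[:, 0], gm_idx[:, 1], gm_idx[:, 2], :]
        vox_c = vox - vox.mean(axis=1, keepdims=True)
        vox_sd = vox_c.std(axis=1)
        node_c = ts.data - ts.data.mean(axis=1, keepdims=True)
        node_sd = node_c.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (node_c @ vox_c.T) / bold.shape[-1] / np.outer(node_sd, vox_sd)
        dead = vox_sd == 0
        if dead.any():
            warnings.warn(f"{int(dead.sum())} zero-variance grey-matter voxels; "
                          "their correlations are undefined (NaN)", stacklevel=2)
            r[:, dead] = np.nan
        z = fisher_z(r)
        acc = z if acc is None else acc + z
        n_sub += 1
    if n_sub == 0:
        raise ValueError("need at least one subject")
    return SeedMapSet(grid=grid, gm_mask=gm, maps=acc / n_sub)
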