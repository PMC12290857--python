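"""Meta-analytic contrast and conjunction analyses.

Contrasts compare the voxel-wise ALE scores of two experiment sets against a
permutation null built by pooling all experiments and randomly re-splitting
them into groups of the original sizes; conjunctions intersect two
cluster-thresholded result maps.  A subsampling balancer equalizes power when
one set is much larger than the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ale import (ExperimentSet, KernelSpec, StatMap, _ma_array, label_clusters)
from .grid import VolumeGrid

__all__ = ["conjunction", "contrast_permutation", "balanced_contrast",
           "ContrastResult", "ConjunctionResult"]


@dataclass(frozen=True)
class ConjunctionResult:
    label_map: StatMap
    clusters: pd.DataFrame


@dataclass(frozen=True)
class ContrastResult:
    p_map_a_gt_b: StatMap
    p_map_b_gt_a: StatMap
    label_a_gt_b: StatMap
    label_b_gt_a: StatMap
    clusters_a_gt_b: pd.DataFrame = field(repr=False)
    clusters_b_gt_a: pd.DataFrame = field(repr=False)
    n_permutations: int = 0


def _cluster_table(binary: np.ndarray, values: np.ndarray, grid: VolumeGrid,
                   min_extent: int, connectivity: int = 26):
    lab, n = label_clusters(binary, connectivity)
    keep = np.zeros(binary.shape)
    rows = []
    new = 0
    for c in range(1, n + 1):
        vox = np.argwhere(lab == c)
        if len(vox) < min_extent:
            continue
        new += 1
        keep[lab == c] = new
        vals = values[vox[:, 0], vox[:, 1], vox[:, 2]]
        peak = vox[np.argmax(vals)]
        pk = grid.vox_to_mm(peak)[0]
        rows.append(dict(label=new, extent=len(vox), peak_x=pk[0], peak_y=pk[1],
                         peak_z=pk[2], peak_value=float(vals.max())))
    table = pd.DataFrame(rows, columns=["label", "extent", "peak_x", "peak_y",
                                        "peak_z", "peak_value"])
    return keep, table


def conjunction(map_a: StatMap, map_b: StatMap, min_extent: int = 5,
                connectivity: int = 26) -> ConjunctionResult:
    """Voxel-wise intersection of two thresholded maps; connected components
    smaller than `min_extent` voxels are removed."""
    grid = map_a.grid
    if map_b.grid.shape != grid.shape or not np.allclose(map_b.grid.affine, grid.affine):
        raise ValueError("maps are on different grids")
    inter = (map_a.data > 0) & (map_b.data > 0) & grid.mask
    minimum = np.minimum(map_a.data, map_b.data)
    keep, table = _cluster_table(inter, minimum, grid, min_extent, connectivity)
    return ConjunctionResult(label_map=StatMap(grid=grid, data=keep, kind="label"),
                             clusters=table)


def _stack_ma(experiments, grid, spec, mask_flat_idx):
    """(n_experiments, n_eval_voxels) MA values at the evaluation voxels."""
    buf = np.empty(grid.shape)
    out = np.empty((len(experiments), len(mask_flat_idx)))
    for i, e in enumerate(experiments):
        _ma_array(grid, e.foci, e.n_subjects, spec, out=buf)
        out[i] = buf.reshape(-1)[mask_flat_idx]
    return out


def _ale_rows(ma: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return 1.0 - np.prod(1.0 - ma[rows], axis=0)


def contrast_permutation(
    set_a: ExperimentSet,
    set_b: ExperimentSet,
    grid: VolumeGrid,
    spec: KernelSpec = KernelSpec(),
    n_perm: int = 25000,
    p: float = 0.05,
    min_extent: int = 5,
    restrict_mask: np.ndarray | None = None,
    seed=None,
    connectivity: int = 26,
) -> ContrastResult:
    """Permutation contrast of two ALE analyses.

    Observed statistic: voxel-wise ALE_a - ALE_b.  Null: pool the experiments
    and redraw group labels preserving group sizes, `n_perm` times.  Voxel
    p values use the add-one estimator (b+1)/(n+1) per direction, thresholded
    at `p` with a cluster extent threshold of `min_extent` voxels.
    Evaluation is restricted to `restrict_mask` (default: the grid mask;
    standard practice restricts to the union of the two cFWE-significant
    masks).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both experiment sets must be non-empty")
    if n_perm < 1.0 / p:
        warnings.warn(f"n_perm={n_perm} cannot resolve p={p} (granularity)", stacklevel=2)
    rng = np.random.default_rng(seed)
    eval_mask = grid.mask if restrict_mask is None else (grid.mask & restrict_mask)
    flat_idx = np.flatnonzero(eval_mask.reshape(-1))

    pooled = list(set_a) + list(set_b)
    na = len(set_a)
    ma = _stack_ma(pooled, grid, spec, flat_idx)
    idx_a = np.arange(na)
    idx_b = np.arange(na, len(pooled))
    observed = _ale_rows(ma, idx_a) - _ale_rows(ma, idx_b)

    count_ge = np.zeros(len(flat_idx))   # perm diff >= observed
    count_le = np.zeros(len(flat_idx))
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        diff = _ale_rows(ma, perm[:na]) - _ale_rows(ma, perm[na:])
        count_ge += diff >= observed
        count_le += diff <= observed
    p_a = (count_ge + 1.0) / (n_perm + 1.0)  # small p: observed a>b larger than null
    p_b = (count_le + 1.0) / (n_perm + 1.0)

    def _embed(vals):
        full = np.ones(np.prod(grid.shape))
        full[flat_idx] = vals
        return full.reshape(grid.shape)

    p_map_a = _embed(p_a)
    p_map_b = _embed(p_b)
    obs_map = _embed(observed)
    lab_a, tab_a = _cluster_table((p_map_a < p) & eval_mask, obs_map, grid,
                                  min_extent, connectivity)
    lab_b, tab_b = _cluster_table((p_map_b < p) & eval_mask, -obs_map, grid,
                                  min_extent, connectivity)
    return ContrastResult(
        p_map_a_gt_b=StatMap(grid=grid, data=p_map_a, kind="P"),
        p_map_b_gt_a=StatMap(grid=grid, data=p_map_b, kind="P"),
        label_a_gt_b=StatMap(grid=grid, data=lab_a, kind="label"),
        label_b_gt_a=StatMap(grid=grid, data=lab_b, kind="label"),
        clusters_a_gt_b=tab_a, clusters_b_gt_a=tab_b,
        n_permutations=n_perm,
    )


def balanced_contrast(
    set_large: ExperimentSet,
    set_small: ExperimentSet,
    grid: VolumeGrid,
    spec: KernelSpec = KernelSpec(),
    n_subsamples: int = 25,
    agreement_fraction: float = 0.5,
    n_perm: int = 1000,
    p: float = 0.05,
    min_extent: int = 5,
    restrict_mask: np.ndarray | None = None,
    seed=None,
    connectivity: int = 26,
) -> ContrastResult:
    """Size-balanced contrast for unequal experiment counts.

    Repeats :func:`contrast_permutation` on `n_subsamples` random subsets of
    the larger set matched to the smaller set's size; a voxel survives iff it
    is significant in at least `agreement_fraction` of the subsamples.
    Equal sizes delegate to a single plain contrast.
    """
    if len(set_large) < len(set_small):
        raise ValueError("set_large must have more experiments than set_small")
    if len(set_large) == len(set_small):
        warnings.warn("equal set sizes: delegating to contrast_permutation", stacklevel=2)
        return contrast_permutation(set_large, set_small, grid, spec, n_perm, p,
                                    min_extent, restrict_mask, seed, connectivity)
    rng = np.random.default_rng(seed)
    votes_a = np.zeros(grid.shape)
    votes_b = np.zeros(grid.shape)
    obs_acc = np.zeros(grid.shape)
    for _ in range(n_subsamples):
        sub = set_large.subset(rng.choice(len(set_large), size=len(set_small), replace=False))
        res = contrast_permutation(sub, set_small, grid, spec, n_perm, p, min_extent,
                                   restrict_mask, rng.integers(2 ** 31), connectivity)
        votes_a += res.label_a_gt_b.data > 0
        votes_b += res.label_b_gt_a.data > 0
        obs_acc += res.p_map_a_gt_b.data  # for peak ordering only
    surv_a = votes_a / n_subsamples >= agreement_fraction
    surv_b = votes_b / n_subsamples >= agreement_fraction
    lab_a, tab_a = _cluster_table(surv_a, votes_a, grid, min_extent, connectivity)
    lab_b, tab_b = _cluster_table(surv_b, votes_b, grid, min_extent, connectivity)
    frac_a = votes_a / n_subsamples
    frac_b = votes_b / n_subsamples
    return ContrastResult(
        p_map_a_gt_b=StatMap(grid=grid, data=1.0 - frac_a, kind="P"),
        p_map_b_gt_a=StatMap(grid=grid, data=1.0 - frac_b, kind="P"),
        label_a_gt_b=StatMap(grid=grid, data=lab_a, kind="label"),
        label_b_gt_a=StatMap(grid=grid, data=lab_b, kind="label"),
        clusters_a_gt_b=tab_a, clusters_b_gt_a=tab_b,
        n_permutations=n_subsamples * n_perm,
    )
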