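"""Activation likelihood estimation (ALE) for coordinate-based meta-analysis.

Each reported activation focus is modelled as the centre of a 3D Gaussian
probability distribution whose width reflects the spatial uncertainty of the
report: a fixed between-template component plus a between-subject component
that shrinks with the experiment's sample size.  Per experiment the foci
kernels are combined non-additively (voxel-wise maximum) into a modelled
activation (MA) map; across experiments the MA maps are combined by the
probabilistic union ALE(v) = 1 - prod_i (1 - MA_i(v)).  Convergence is
assessed against an analytic null distribution of ALE scores under random
spatial association, with cluster-level family-wise error control by Monte
Carlo simulation of maximum cluster sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import VolumeGrid

__all__ = [
    "Experiment",
    "ExperimentSet",
    "KernelSpec",
    "StatMap",
    "NullDistribution",
    "read_experiment_table",
    "write_experiment_table",
    "kernel_sd",
    "ma_map",
    "ale_map",
    "analytic_null",
    "voxel_threshold",
    "cluster_fwe",
]

# Empirical spatial-uncertainty calibration: mean Euclidean displacement of
# 5.7 mm between templates and 11.6 mm between subjects, converted to the
# per-axis sigma of an isotropic 3D Gaussian via sigma = ED / (2*sqrt(2/pi)).
_ED_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 / np.pi))
SIGMA_TEMPLATE_MM = 5.7 * _ED_TO_SIGMA
SIGMA_SUBJECT_MM = 11.6 * _ED_TO_SIGMA

FOCI_COLUMNS = ["study_id", "experiment_id", "contrast", "n", "x", "y", "z", "pooling_group"]


@dataclass(frozen=True)
class Experiment:
    """One experiment: a set of activation foci plus its sample size."""

    study_id: str
    experiment_id: str
    contrast: str
    n_subjects: int
    foci: np.ndarray  # (n_foci, 3) MNI mm
    pooling_group: str | None = None

    def __post_init__(self):
        foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if foci.shape[0] < 1 or foci.shape[1] != 3:
            raise ValueError(f"experiment {self.experiment_id}: needs >=1 focus of 3 coordinates")
        if not np.all(np.isfinite(foci)):
            raise ValueError(f"experiment {self.experiment_id}: non-finite focus coordinates")
        if int(self.n_subjects) < 1:
            raise ValueError(f"experiment {self.experiment_id}: n_subjects must be >= 1")
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "n_subjects", int(self.n_subjects))


@dataclass(frozen=True)
class ExperimentSet:
    experiments: tuple
    provenance: str = ""

    def __post_init__(self):
        exps = tuple(self.experiments)
        ids = [e.experiment_id for e in exps]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment ids are not unique")
        object.__setattr__(self, "experiments", exps)

    def __len__(self):
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    def subset(self, indices) -> "ExperimentSet":
        return ExperimentSet(tuple(self.experiments[i] for i in indices), self.provenance)


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel width model: sd(n) = sqrt(sigma_template^2 + sigma_subject^2 / n)."""

    sigma_template_mm: float = SIGMA_TEMPLATE_MM
    sigma_subject_mm: float = SIGMA_SUBJECT_MM
    truncation_radius_sds: float = 4.0

    def __post_init__(self):
        if self.sigma_template_mm <= 0 or self.sigma_subject_mm < 0:
            raise ValueError("kernel sigmas must be positive")

    def sd(self, n_subjects: int) -> float:
        return kernel_sd(n_subjects, self)

    def truncation_radius_mm(self, n_subjects: int) -> float:
        return self.truncation_radius_sds * self.sd(n_subjects)


def kernel_sd(n_subjects: int, spec: KernelSpec) -> float:
    """Per-axis Gaussian sd (mm) for an experiment with `n_subjects` participants.

    Strictly decreasing in n: larger samples localize activation better.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return float(np.sqrt(spec.sigma_template_mm ** 2 + spec.sigma_subject_mm ** 2 / n_subjects))


@dataclass(frozen=True)
class StatMap:
    """A scalar statistic on a grid; values outside the mask are 0."""

    grid: VolumeGrid
    data: np.ndarray = field(repr=False)
    kind: str = "MA"  # MA | ALE | Z | P | label

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError("data shape does not match grid")
        object.__setattr__(self, "data", data)

    @property
    def masked_values(self) -> np.ndarray:
        return self.data[self.grid.mask]

    def to_image(self):
        return self.grid.to_image(self.data)


@dataclass(frozen=True)
class NullDistribution:
    """Discrete null distribution of ALE scores on a regular bin grid.

    Bin i carries the probability mass of ALE score ~= i * bin_width.
    `sf[i]` is the survival function P(ALE >= i * bin_width).
    """

    bin_width: float
    prob_mass: np.ndarray = field(repr=False)

    def __post_init__(self):
        pm = np.asarray(self.prob_mass, dtype=float)
        total = pm.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probability mass sums to {total}, not 1")
        object.__setattr__(self, "prob_mass", pm)

    @property
    def sf(self) -> np.ndarray:
        return np.cumsum(self.prob_mass[::-1])[::-1]

    def p_values(self, ale_values: np.ndarray) -> np.ndarray:
        """Survival probability P(null ALE >= observed) per value."""
        sf = self.sf
        idx = np.rint(np.asarray(ale_values, dtype=float) / self.bin_width).astype(int)
        idx = np.clip(idx, 0, len(sf))
        p = np.where(idx < len(sf), sf[np.minimum(idx, len(sf) - 1)], 0.0)
        # keep p in (0, 1]: values beyond the null's support get the smallest
        # representable tail mass rather than an exact zero
        tiny = self.prob_mass[self.prob_mass > 0].min()
        return np.clip(p, tiny, 1.0)

    def threshold(self, p_voxel: float) -> float:
        """Smallest ALE score whose survival probability is < p_voxel."""
        sf = self.sf
        idx = np.nonzero(sf < p_voxel)[0]
        if len(idx) == 0:
            return np.inf
        return float(idx[0] * self.bin_width)


# ---------------------------------------------------------------------------
# Foci table I/O


def read_experiment_table(path, pooling: bool = True) -> ExperimentSet:
    """Read a foci TSV (one focus per row) into an :class:`ExperimentSet`.

    Columns: study_id, experiment_id, contrast, n, x, y, z, pooling_group.
    Rows sharing a non-empty pooling_group are merged into a single
    experiment whose foci are concatenated; the *smaller* sample size of the
    merged experiments is used (overlapping-sample rule).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty foci table") from None
    missing = [c for c in FOCI_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a foci table, missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty foci table")
    if "pooling_group" not in df.columns:
        df["pooling_group"] = ""
    df["pooling_group"] = df["pooling_group"].fillna("")

    for col in ["n", "x", "y", "z"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = vals

    experiments = []
    for exp_id, g in df.groupby("experiment_id", sort=False):
        ns = g["n"].unique()
        if len(ns) > 1:
            raise ValueError(f"experiment {exp_id}: inconsistent sample sizes {sorted(ns)}")
        experiments.append(
            Experiment(
                study_id=str(g["study_id"].iloc[0]),
                experiment_id=str(exp_id),
                contrast=str(g["contrast"].iloc[0]),
                n_subjects=int(ns[0]),
                foci=g[["x", "y", "z"]].to_numpy(float),
                pooling_group=str(g["pooling_group"].iloc[0]) or None,
            )
        )

    if pooling:
        experiments = pool_experiments(experiments)
    return ExperimentSet(tuple(experiments), provenance=str(path))


def pool_experiments(experiments) -> list:
    """Merge experiments sharing a pooling_group (overlapping samples).

    Foci are concatenated and the smaller sample size of the merged
    experiments is retained.
    """
    out, groups, order = [], {}, []
    for exp in experiments:
        if exp.pooling_group is None:
            out.append(exp)
        else:
            groups.setdefault(exp.pooling_group, []).append(exp)
            if exp.pooling_group not in order:
                order.append(exp.pooling_group)
    for key in order:
        members = groups[key]
        if len(members) == 1:
            out.append(members[0])
            continue
        merged = Experiment(
            study_id="+".join(dict.fromkeys(m.study_id for m in members)),
            experiment_id="+".join(m.experiment_id for m in members),
            contrast=members[0].contrast,
            n_subjects=min(m.n_subjects for m in members),
            foci=np.vstack([m.foci for m in members]),
            pooling_group=key,
        )
        out.append(merged)
    return out


def write_experiment_table(experiments: ExperimentSet, path) -> None:
    rows = []
    for e in experiments:
        for x, y, z in e.foci:
            rows.append(
                dict(study_id=e.study_id, experiment_id=e.experiment_id, contrast=e.contrast,
                     n=e.n_subjects, x=x, y=y, z=z, pooling_group=e.pooling_group or "")
            )
    pd.DataFrame(rows, columns=FOCI_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MA / ALE maps

_KERNEL_CACHE: dict = {}


def _gaussian_kernel(sd_mm: float, voxel_mm: np.ndarray, trunc_mm: float) -> np.ndarray:
    """Discrete 3D Gaussian on the voxel lattice, unit total mass, spherically
    truncated at `trunc_mm`."""
    key = (round(sd_mm, 9), tuple(np.round(voxel_mm, 9)), round(trunc_mm, 9))
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    half = np.ceil(trunc_mm / voxel_mm).astype(int)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel_mm)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij")
    d2 = dx ** 2 + dy ** 2 + dz ** 2
    kern = np.exp(-d2 / (2.0 * sd_mm ** 2))
    kern[d2 > trunc_mm ** 2] = 0.0
    kern /= kern.sum()
    _KERNEL_CACHE[key] = kern
    return kern


def _paste_max(target: np.ndarray, kernel: np.ndarray, center_vox: np.ndarray) -> None:
    """Voxel-wise max of `kernel` centred at `center_vox` into `target`, cropped."""
    half = (np.array(kernel.shape) - 1) // 2
    lo = center_vox - half
    hi = center_vox + half + 1
    klo = np.maximum(-lo, 0)
    khi = np.array(kernel.shape) - np.maximum(hi - target.shape, 0)
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, target.shape)
    if np.any(lo_c >= hi_c):
        return
    view = target[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]]
    np.maximum(view, kernel[klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]], out=view)


def _ma_array(grid: VolumeGrid, foci_mm: np.ndarray, n_subjects: int,
              spec: KernelSpec, out: np.ndarray | None = None) -> np.ndarray:
    sd = kernel_sd(n_subjects, spec)
    kern = _gaussian_kernel(sd, grid.voxel_sizes, spec.truncation_radius_mm(n_subjects))
    if out is None:
        out = np.zeros(grid.shape)
    else:
        out.fill(0.0)
    centers = grid.nearest_voxel(foci_mm)
    for c in centers:
        _paste_max(out, kern, c)
    return out


def ma_map(experiment: Experiment, grid: VolumeGrid, spec: KernelSpec = KernelSpec()) -> StatMap:
    """Modelled-activation map of one experiment.

    Each focus contributes a discrete Gaussian of unit total mass (width from
    :func:`kernel_sd`); foci are combined by voxel-wise maximum so several
    nearby foci from the same experiment cannot inflate the score.  Foci are
    snapped to the nearest voxel centre.  Foci outside the grid mask are kept
    (their kernels may still overlap the mask) but trigger a warning.
    """
    centers = grid.nearest_voxel(experiment.foci)
    inb = grid.in_bounds(centers)
    if not inb.all():
        raise ValueError(
            f"experiment {experiment.experiment_id}: foci outside the grid bounding box: "
            f"{experiment.foci[~inb].tolist()}"
        )
    outside = ~grid.mask[centers[:, 0], centers[:, 1], centers[:, 2]]
    if outside.any():
        warnings.warn(
            f"experiment {experiment.experiment_id}: {int(outside.sum())} focus/foci "
            "outside the analysis mask; kernels retained", stacklevel=2,
        )
    data = _ma_array(grid, experiment.foci, experiment.n_subjects, spec)
    return StatMap(grid=grid, data=data, kind="MA")


def ale_map(ma_maps) -> StatMap:
    """ALE map: probabilistic union ALE(v) = 1 - prod_i (1 - MA_i(v))."""
    ma_maps = list(ma_maps)
    if not ma_maps:
        raise ValueError("need at least one MA map")
    grid = ma_maps[0].grid
    prod = np.ones(grid.shape)
    for m in ma_maps:
        if m.grid is not grid and (m.grid.shape != grid.shape or not np.allclose(m.grid.affine, grid.affine)):
            raise ValueError("MA maps are on different grids")
        prod *= 1.0 - m.data
    return StatMap(grid=grid, data=1.0 - prod, kind="ALE")


# ---------------------------------------------------------------------------
# Analytic null of the ALE statistic


def _hist_masses(values: np.ndarray, bin_width: float) -> np.ndarray:
    idx = np.rint(values / bin_width).astype(int)
    return np.bincount(idx) / len(values)


def _combine_null(a: np.ndarray, b: np.ndarray, bin_width: float) -> np.ndarray:
    """Distribution of s = 1-(1-x)(1-y) for independent x~a, y~b on the bin grid."""
    nz_b = np.nonzero(b)[0]
    i = np.arange(len(a))
    vi = i * bin_width
    max_bins = int(np.rint((1 - (1 - (len(a) - 1) * bin_width) * (1 - nz_b.max() * bin_width)) / bin_width)) + 2
    out = np.zeros(max_bins)
    chunk = 256
    for s in range(0, len(nz_b), chunk):
        j = nz_b[s:s + chunk]
        vj = j * bin_width
        score = vi[:, None] + vj[None, :] - vi[:, None] * vj[None, :]
        k = np.rint(score / bin_width).astype(int)
        w = a[:, None] * b[j]
        out += np.bincount(k.ravel(), weights=w.ravel(), minlength=max_bins)
    return out


def analytic_null(ma_maps, bin_width: float = 1e-5) -> NullDistribution:
    """Exact null distribution of ALE under independent random voxel association.

    Per experiment, the histogram of MA values over masked voxels (zeros
    included) is taken as that experiment's marginal; marginals are combined
    sequentially under s = 1 - (1-a)(1-b) with probability-mass products,
    re-binned at `bin_width`.
    """
    ma_maps = list(ma_maps)
    if not ma_maps:
        raise ValueError("need at least one MA map")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mass = _hist_masses(ma_maps[0].masked_values, bin_width)
    for m in ma_maps[1:]:
        b = _hist_masses(m.masked_values, bin_width)
        if len(b) == 1:  # all-zero MA map leaves the null unchanged
            continue
        if len(mass) == 1:
            mass = b
            continue
        mass = _combine_null(mass, b, bin_width)
    mass = mass / mass.sum()  # guard fp drift from re-binning
    return NullDistribution(bin_width=bin_width, prob_mass=mass)


# ---------------------------------------------------------------------------
# Thresholding and cluster-level FWE


def voxel_threshold(ale: StatMap, null: NullDistribution, p_voxel: float = 0.001):
    """Threshold an ALE map against its analytic null.

    Returns (label_map, p_map, z_map): label_map is 1 where the voxel's null
    survival probability is < p_voxel, the p map holds voxel-wise survival
    probabilities, and the z map their inverse-normal equivalents.
    """
    if not 0 < p_voxel <= 1:
        raise ValueError("p_voxel must be in (0, 1]")
    grid = ale.grid
    p = np.ones(grid.shape)
    p[grid.mask] = null.p_values(ale.data[grid.mask])
    retained = np.zeros(grid.shape)
    if p_voxel >= 1.0:  # degenerate limit: every masked voxel survives
        retained[grid.mask] = 1.0
    else:
        retained[grid.mask] = (p[grid.mask] < p_voxel).astype(float)
    z = np.zeros(grid.shape)
    z[grid.mask] = stats.norm.isf(p[grid.mask])
    return (
        StatMap(grid=grid, data=retained, kind="label"),
        StatMap(grid=grid, data=p, kind="P"),
        StatMap(grid=grid, data=z, kind="Z"),
    )


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def label_clusters(binary: np.ndarray, connectivity: int = 26):
    return ndimage.label(binary, structure=_STRUCTURES[connectivity])


def _cluster_sizes(binary: np.ndarray, connectivity: int) -> np.ndarray:
    lab, n = label_clusters(binary, connectivity)
    if n == 0:
        return np.zeros(0, dtype=int)
    return np.bincount(lab.ravel())[1:]


def _uniform_mask_foci(grid: VolumeGrid, n_foci: int, rng: np.random.Generator,
                       masked_mm: np.ndarray) -> np.ndarray:
    idx = rng.integers(0, len(masked_mm), size=n_foci)
    return masked_mm[idx]


def cluster_fwe(
    experiments: ExperimentSet,
    grid: VolumeGrid,
    spec: KernelSpec = KernelSpec(),
    p_voxel: float = 0.001,
    p_cluster: float = 0.05,
    n_iter: int = 1000,
    seed: int | None = None,
    connectivity: int = 26,
    bin_width: float = 1e-5,
):
    """Full ALE inference with cluster-level family-wise error correction.

    The Monte-Carlo null redraws every experiment's foci uniformly within the
    mask (same foci counts, same sample sizes), recomputes the ALE map,
    applies the voxel threshold and records the maximum cluster size.
    Observed clusters are kept iff their extent exceeds the (1 - p_cluster)
    quantile of that null.

    Returns (cluster_table, label_map, ale_stat, null, z_map).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if n_iter < 1.0 / p_cluster:
        warnings.warn(
            f"n_iter={n_iter} is small for p_cluster={p_cluster}: the extent "
            "quantile is coarse", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ma_maps = [ma_map(e, grid, spec) for e in experiments]
    ale = ale_map(ma_maps)
    null = analytic_null(ma_maps, bin_width=bin_width)
    label_map, p_map, z_map = voxel_threshold(ale, null, p_voxel)
    cutoff = null.threshold(p_voxel)

    masked_mm = grid.masked_mm()
    buf = np.empty(grid.shape)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        prod = np.ones(grid.shape)
        for e in experiments:
            foci = _uniform_mask_foci(grid, len(e.foci), rng, masked_mm)
            _ma_array(grid, foci, e.n_subjects, spec, out=buf)
            prod *= 1.0 - buf
        sim_ale = 1.0 - prod
        supra = (sim_ale >= cutoff) & grid.mask
        sizes = _cluster_sizes(supra, connectivity)
        max_sizes[it] = sizes.max() if len(sizes) else 0

    extent_cut = np.quantile(max_sizes, 1.0 - p_cluster)
    lab, n_clust = label_clusters(label_map.data > 0, connectivity)
    rows = []
    keep = np.zeros(grid.shape)
    new_label = 0
    for c in range(1, n_clust + 1):
        vox = np.argwhere(lab == c)
        extent = len(vox)
        if extent <= extent_cut:
            continue
        vals = ale.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        peak = vox[np.argmax(vals)]
        new_label += 1
        keep[lab == c] = new_label
        p_clust = (np.sum(max_sizes >= extent) + 1) / (n_iter + 1)
        rows.append(dict(
            label=new_label, extent=extent,
            peak_x=grid.vox_to_mm(peak)[0][0], peak_y=grid.vox_to_mm(peak)[0][1],
            peak_z=grid.vox_to_mm(peak)[0][2],
            peak_ale=float(vals.max()), p_cluster=float(p_clust),
        ))
    table = pd.DataFrame(rows, columns=["label", "extent", "peak_x", "peak_y", "peak_z",
                                        "peak_ale", "p_cluster"])
    return table, StatMap(grid=grid, data=keep, kind="label"), ale, null, z_map
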