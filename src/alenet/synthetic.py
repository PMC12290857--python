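"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators:

* foci corpora — experiments with planted spatial convergence (Gaussian
  jitter around cluster centres) plus uniform noise foci, for exercising the
  ALE chain;
* multi-subject 4D BOLD — node spheres carrying a planted block-community
  covariance, for exercising connectivity and community detection;
* annotation maps — smooth 3D volumes whose node-sphere means carry a target
  rank correlation with a node metric, for exercising the receptor chain.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .ale import Experiment, ExperimentSet
from .grid import VolumeGrid, sphere_voxels
from .peaks import NodeSet

__all__ = [
    "FociGenConfig", "BoldGenConfig", "AnnotationGenConfig",
    "gen_foci_corpus", "gen_bold", "gen_annotation_map", "gen_motion_trace",
    "BoldDataset", "lattice_nodes",
]

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Foci corpora


@dataclass(frozen=True)
class FociGenConfig:
    """Configuration for a synthetic foci corpus.

    Each experiment hits each planted cluster independently with probability
    `prob_experiment_hits_cluster`; a hit contributes
    `foci_per_cluster_per_experiment` foci jittered isotropically (sd
    `jitter_sd_mm`, default 5 mm — the scale of ALE spatial uncertainty)
    around the cluster centre.  Noise foci are uniform over masked voxel
    centres.
    """

    mask: VolumeGrid
    n_experiments: int = 20
    cluster_centers: tuple = ()
    foci_per_cluster_per_experiment: int = 2
    prob_experiment_hits_cluster: float = 1.0
    noise_foci_per_experiment: int = 2
    subjects_range: tuple = (15, 30)
    jitter_sd_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if min(self.foci_per_cluster_per_experiment, self.noise_foci_per_experiment) < 0:
            raise ValueError("foci counts must be non-negative")
        if not 0.0 <= self.prob_experiment_hits_cluster <= 1.0:
            raise ValueError("prob_experiment_hits_cluster must be in [0, 1]")
        if self.subjects_range[0] < 1 or self.subjects_range[1] < self.subjects_range[0]:
            raise ValueError("subjects_range must be a non-empty integer interval with min >= 1")
        centers = tuple(tuple(float(v) for v in c) for c in self.cluster_centers)
        object.__setattr__(self, "cluster_centers", centers)
        grid = self.mask
        for c in centers:
            ijk = grid.nearest_voxel(c)[0]
            if not grid.in_bounds(ijk[None, :])[0] or not grid.mask[tuple(ijk)]:
                raise ValueError(f"cluster center {c} lies outside the mask")


def _jittered_in_mask(grid: VolumeGrid, center, sd, n, rng) -> np.ndarray:
    """n foci ~ N(center, sd^2 I), rejection-sampled to lie inside the mask."""
    out = np.empty((n, 3))
    got = 0
    for _ in range(1000):
        if got == n:
            break
        cand = np.asarray(center) + rng.normal(0.0, sd, size=(n - got, 3))
        ijk = grid.nearest_voxel(cand)
        ok = grid.in_bounds(ijk)
        ijk_ok = ijk[ok]
        if len(ijk_ok):
            ok[ok.nonzero()[0]] = grid.mask[ijk_ok[:, 0], ijk_ok[:, 1], ijk_ok[:, 2]]
        take = cand[ok]
        out[got:got + len(take)] = take
        got += len(take)
    if got < n:
        raise RuntimeError("rejection sampling of jittered foci failed; mask too small?")
    return out


def gen_foci_corpus(cfg: FociGenConfig) -> ExperimentSet:
    """Generate a foci corpus with planted convergence plus uniform noise."""
    grid = cfg.mask
    rng = np.random.default_rng(cfg.seed)
    masked_mm = grid.masked_mm()
    experiments = []
    for i in range(cfg.n_experiments):
        foci = []
        for center in cfg.cluster_centers:
            if rng.random() < cfg.prob_experiment_hits_cluster and cfg.foci_per_cluster_per_experiment:
                foci.append(_jittered_in_mask(grid, center, cfg.jitter_sd_mm,
                                              cfg.foci_per_cluster_per_experiment, rng))
        if cfg.noise_foci_per_experiment:
            idx = rng.integers(0, len(masked_mm), size=cfg.noise_foci_per_experiment)
            foci.append(masked_mm[idx])
        if not foci:
            raise ValueError(
                f"experiment {i}: zero foci generated; increase noise_foci_per_experiment "
                "or prob_experiment_hits_cluster"
            )
        n = int(rng.integers(cfg.subjects_range[0], cfg.subjects_range[1] + 1))
        experiments.append(Experiment(
            study_id=f"synth{i:03d}", experiment_id=f"synth{i:03d}_e1",
            contrast="synthetic", n_subjects=n, foci=np.vstack(foci),
        ))
    return ExperimentSet(tuple(experiments), provenance=f"gen_foci_corpus(seed={cfg.seed})")


# ---------------------------------------------------------------------------
# Block-community BOLD


def lattice_nodes(n_nodes: int = 21, grid: VolumeGrid | None = None,
                  spacing_mm: float = 14.0) -> tuple:
    """Place `n_nodes` synthetic nodes on a lattice inside a compact grid.

    Returns (nodes, grid).  Used when no empirical node table is wanted.
    """
    if grid is None:
        from .grid import mni_like_grid
        side = int(np.ceil(n_nodes ** (1 / 2)))
        extent = spacing_mm * (side + 1)
        shape = (int(extent / 2.0) + 8, int(extent / 2.0) + 8, 14)
        grid = mni_like_grid(shape=shape, voxel_mm=2.0)
    coords = []
    side = int(np.ceil(np.sqrt(n_nodes)))
    for i in range(n_nodes):
        r, c = divmod(i, side)
        coords.append([
            (c - (side - 1) / 2.0) * spacing_mm,
            (r - (side - 1) / 2.0) * spacing_mm,
            0.0,
        ])
    nodes = NodeSet(coords=np.array(coords))
    for xyz in nodes.coords:
        ijk = grid.nearest_voxel(xyz)[0]
        if not grid.in_bounds(ijk[None, :])[0]:
            raise ValueError("lattice node falls outside grid; enlarge the grid")
    return nodes, grid


@dataclass(frozen=True)
class BoldGenConfig:
    """Planted block-community BOLD: node spheres share a latent node signal.

    Latent model: node signal = sqrt(between_r) * global factor +
    sqrt(within_r - between_r) * community factor + sqrt(1 - within_r) *
    node factor, all iid standard normal over time — the simplest model with
    exact target within/between correlations (requires 0 <= between_r <=
    within_r; arbitrary admissible covariances go through the matrix
    factorization, which errors if non-PSD).
    """

    nodes: NodeSet
    grid: VolumeGrid
    partition: tuple
    within_r: float = 0.5
    between_r: float = 0.05
    n_timepoints: int = 2000
    tr_seconds: float = 1.4
    noise_sd: float = 1.0
    n_subjects: int = 20
    sphere_radius_mm: float = 5.0
    fd_mean_mm: float = 0.15
    seed: int = 0

    def __post_init__(self):
        part = tuple(int(p) for p in self.partition)
        if len(part) != len(self.nodes):
            raise ValueError("partition length must match number of nodes")
        if not (-1.0 < self.between_r <= self.within_r < 1.0):
            raise ValueError("require -1 < between_r <= within_r < 1")
        object.__setattr__(self, "partition", part)

    def covariance(self) -> np.ndarray:
        part = np.asarray(self.partition)
        same = part[:, None] == part[None, :]
        cov = np.where(same, self.within_r, self.between_r).astype(float)
        np.fill_diagonal(cov, 1.0)
        return cov


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-10:
        raise ValueError(
            "implied node covariance is not positive semi-definite; "
            "use a smaller between_r"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def gen_motion_trace(n_frames: int, fd_mean_mm: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. half-normal framewise-displacement values with the given mean."""
    sigma = fd_mean_mm / np.sqrt(2.0 / np.pi)
    return np.abs(rng.normal(0.0, sigma, size=n_frames))


@dataclass
class BoldDataset:
    """Lazily generated per-subject 4D volumes with shared ground truth."""

    cfg: BoldGenConfig
    sphere_idx: list = field(repr=False)

    def __len__(self):
        return self.cfg.n_subjects

    def _rng(self, subject: int) -> np.random.Generator:
        return np.random.default_rng([self.cfg.seed, subject])

    def latent_signals(self, subject: int) -> np.ndarray:
        """(n_nodes, n_timepoints) latent node signals for one subject."""
        cfg = self.cfg
        rng = self._rng(subject)
        factor = _covariance_factor(cfg.covariance())
        white = rng.standard_normal((len(cfg.nodes), cfg.n_timepoints))
        return factor @ white

    def subject(self, subject: int) -> tuple:
        """Return (bold4d, fd_trace) for one subject, deterministically.

        bold4d has shape grid.shape + (n_timepoints,): node latent signal
        inside each node sphere plus white voxel noise everywhere.
        """
        cfg = self.cfg
        rng = self._rng(subject)
        factor = _covariance_factor(cfg.covariance())
        white = rng.standard_normal((len(cfg.nodes), cfg.n_timepoints))
        latent = factor @ white
        shape = cfg.grid.shape + (cfg.n_timepoints,)
        if cfg.noise_sd > 0:
            bold = rng.normal(0.0, cfg.noise_sd, size=shape)
        else:
            bold = np.zeros(shape)
        for node, idx in enumerate(self.sphere_idx):
            bold[idx[:, 0], idx[:, 1], idx[:, 2], :] += latent[node]
        fd = gen_motion_trace(cfg.n_timepoints, cfg.fd_mean_mm, rng)
        return bold, fd

    def node_timeseries(self, subject: int) -> np.ndarray:
        """(n_nodes, n_timepoints) sphere-mean series without materializing 4D.

        Statistically identical to averaging the 4D volume over each sphere:
        latent + noise_sd / sqrt(n_voxels) * white.
        """
        cfg = self.cfg
        rng = self._rng(subject)
        factor = _covariance_factor(cfg.covariance())
        white = rng.standard_normal((len(cfg.nodes), cfg.n_timepoints))
        latent = factor @ white
        ts = np.empty_like(latent)
        for node, idx in enumerate(self.sphere_idx):
            noise = rng.standard_normal(cfg.n_timepoints) * (cfg.noise_sd / np.sqrt(len(idx)))
            ts[node] = latent[node] + noise
        return ts

    @property
    def gm_mask(self) -> np.ndarray:
        return self.cfg.grid.mask


def gen_bold(cfg: BoldGenConfig) -> BoldDataset:
    """Build the dataset handle; volumes are generated per subject on demand."""
    _covariance_factor(cfg.covariance())  # validate PSD up front
    sphere_idx = []
    for i, xyz in enumerate(cfg.nodes.coords):
        idx = sphere_voxels(cfg.grid, xyz, cfg.sphere_radius_mm)
        if len(idx) == 0:
            raise ValueError(f"node {i} sphere contains no masked voxels")
        sphere_idx.append(idx)
    return BoldDataset(cfg=cfg, sphere_idx=sphere_idx)


# ---------------------------------------------------------------------------
# Annotation (receptor-like) maps


@dataclass(frozen=True)
class AnnotationGenConfig:
    """Smooth 3D map whose node-sphere means rank-correlate with a node metric.

    Node target values are drawn from a Gaussian copula at the requested
    coupling against the metric's normal scores; the generator rebuilds the
    map (new draw) until the realized sphere-mean Spearman rho is within
    `tolerance` of `coupling`.
    """

    nodes: NodeSet
    grid: VolumeGrid
    node_metric: tuple
    coupling: float = 0.8
    smoothness_fwhm: float = 0.0
    background_level: float = 50.0
    background_sd: float = 1.0
    sphere_radius_mm: float = 5.0
    tolerance: float = 0.15
    max_tries: int = 100
    seed: int = 0

    def __post_init__(self):
        metric = tuple(float(v) for v in self.node_metric)
        if len(metric) != len(self.nodes):
            raise ValueError("node_metric length must match number of nodes")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [-1, 1]")
        if np.ptp(metric) == 0:
            raise ValueError("node_metric is constant: rank correlation undefined")
        object.__setattr__(self, "node_metric", metric)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def gen_annotation_map(cfg: AnnotationGenConfig) -> np.ndarray:
    """Generate the annotation volume (3D array on cfg.grid)."""
    grid = cfg.grid
    rng = np.random.default_rng(cfg.seed)
    zm = _normal_scores(np.asarray(cfg.node_metric))
    sphere_idx = [sphere_voxels(grid, xyz, cfg.sphere_radius_mm) for xyz in cfg.nodes.coords]
    if any(len(s) == 0 for s in sphere_idx):
        raise ValueError("a node sphere contains no masked voxels")
    # Pearson coupling on normal scores that induces the target Spearman rho
    r = 2.0 * np.sin(np.pi * cfg.coupling / 6.0)
    sd_vox = grid.voxel_sizes
    for _ in range(cfg.max_tries):
        if abs(cfg.coupling) == 1.0:
            v = np.sign(cfg.coupling) * zm
        else:
            v = r * zm + np.sqrt(1.0 - r ** 2) * rng.standard_normal(len(zm))
        data = cfg.background_level + cfg.background_sd * rng.standard_normal(grid.shape)
        for node, idx in enumerate(sphere_idx):
            data[idx[:, 0], idx[:, 1], idx[:, 2]] = cfg.background_level + v[node]
        if cfg.smoothness_fwhm > 0:
            sigma = cfg.smoothness_fwhm * _FWHM_TO_SD / sd_vox
            data = ndimage.gaussian_filter(data, sigma=sigma)
        means = np.array([data[idx[:, 0], idx[:, 1], idx[:, 2]].mean() for idx in sphere_idx])
        rho = stats.spearmanr(means, cfg.node_metric).statistic
        if abs(rho - cfg.coupling) <= cfg.tolerance:
            return data
    raise RuntimeError(
        f"could not realize coupling {cfg.coupling} within +-{cfg.tolerance} "
        f"in {cfg.max_tries} tries (smoothing too strong?)"
    )
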