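"""Simulation studies validating the statistical machinery.

Each function runs a self-contained synthetic experiment at a documented
problem size and returns the measured quantities: correctness of the
analytic ALE null against a Monte-Carlo oracle, voxel-threshold and contrast
calibration, planted-cluster and planted-community recovery, and
receptor-null calibration and power.  These are the studies the test suite
and the reproduction script both run.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import ale as _ale
from .ale import KernelSpec, analytic_null, cluster_fwe, ma_map
from .connectivity import fc_matrix
from .grid import mni_like_grid
from .inference import contrast_permutation
from .network import consensus_communities
from .peaks import NodeSet
from .receptor import null_test, random_network_null, sample_node_density
from .synthetic import (AnnotationGenConfig, BoldGenConfig, FociGenConfig,
                        gen_annotation_map, gen_bold, gen_foci_corpus,
                        lattice_nodes)

__all__ = [
    "analytic_null_vs_monte_carlo", "voxel_threshold_calibration",
    "planted_cluster_recovery", "contrast_calibration", "community_recovery",
    "receptor_null_calibration", "receptor_null_power",
]


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(2 ** 31))


# ---------------------------------------------------------------------------
# 1. Analytic null vs Monte-Carlo voxel pairing


def analytic_null_vs_monte_carlo(seed: int = 0, shape=(30, 36, 30),
                                 n_experiments: int = 5, n_draws: int = 1_000_000):
    """Max abs deviation between the analytic ALE null's survival function and
    a Monte-Carlo random-voxel-pairing oracle."""
    grid = mni_like_grid(shape=shape)
    cfg = FociGenConfig(mask=grid, n_experiments=n_experiments,
                        cluster_centers=((0.0, 0.0, 0.0),),
                        foci_per_cluster_per_experiment=2,
                        noise_foci_per_experiment=3, seed=_sub_seed(seed, 1))
    corpus = gen_foci_corpus(cfg)
    ma_maps = [ma_map(e, grid) for e in corpus]
    null = analytic_null(ma_maps)

    rng = np.random.default_rng(_sub_seed(seed, 2))
    prod = np.ones(n_draws)
    for m in ma_maps:
        vals = m.masked_values
        prod *= 1.0 - vals[rng.integers(0, len(vals), size=n_draws)]
    ale_draws = 1.0 - prod

    bw = null.bin_width
    idx = np.rint(ale_draws / bw).astype(int)
    mc_mass = np.bincount(idx, minlength=len(null.prob_mass)) / n_draws
    n_bins = max(len(mc_mass), len(null.prob_mass))
    mc_sf = np.cumsum(np.pad(mc_mass, (0, n_bins - len(mc_mass)))[::-1])[::-1]
    an_sf = np.cumsum(np.pad(null.prob_mass, (0, n_bins - len(null.prob_mass)))[::-1])[::-1]
    return {"max_abs_sf_deviation": float(np.abs(mc_sf - an_sf).max()),
            "n_draws": n_draws, "n_experiments": n_experiments}


# ---------------------------------------------------------------------------
# 2. Voxel-threshold calibration under spatially homogeneous random foci


def _padded_random_ma(core_shape, spec: KernelSpec, n_foci, n_subjects, rng):
    """MA values over a core grid, foci uniform over the core padded by the
    kernel support, so every core voxel has identical coverage geometry."""
    sd_max = spec.sd(min(n_subjects))
    pad = int(np.ceil(spec.truncation_radius_sds * sd_max / 2.0))
    pad_shape = tuple(s + 2 * pad for s in core_shape)
    grid = mni_like_grid(shape=pad_shape)
    core = tuple(slice(pad, pad + s) for s in core_shape)
    mas = []
    for nf, n in zip(n_foci, n_subjects):
        ijk = np.column_stack([rng.integers(0, pad_shape[a], size=nf) for a in range(3)])
        foci = grid.vox_to_mm(ijk)
        arr = _ale._ma_array(grid, foci, n, spec)
        mas.append(arr[core])
    return mas


def voxel_threshold_calibration(seed: int = 0, shape=(30, 36, 30),
                                n_experiments: int = 20, n_reps: int = 200,
                                n_foci: int = 8, p_voxel: float = 0.001):
    """Fraction of voxels passing the voxel threshold under fully random foci.

    Foci are uniform over the analysis box padded by the kernel truncation
    radius, making the marginal MA distribution identical at every analysis
    voxel — the regime in which the analytic null is exact.  Returns the
    mean fraction over reps and its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    core_grid = mni_like_grid(shape=shape)
    spec = KernelSpec()
    fractions = np.empty(n_reps)
    for r in range(n_reps):
        ns = rng.integers(15, 31, size=n_experiments)
        mas = _padded_random_ma(shape, spec, [n_foci] * n_experiments, ns, rng)
        stat_maps = [_ale.StatMap(grid=core_grid, data=m, kind="MA") for m in mas]
        null = analytic_null(stat_maps)
        prod = np.ones(shape)
        for m in mas:
            prod *= 1.0 - m
        ale_vals = (1.0 - prod)[core_grid.mask]
        p = null.p_values(ale_vals)
        fractions[r] = np.mean(p < p_voxel)
    return {"mean_fraction": float(fractions.mean()),
            "se": float(fractions.std(ddof=1) / np.sqrt(n_reps)),
            "target": p_voxel, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# 3. Planted-cluster recovery through the full cFWE chain


def planted_cluster_recovery(seed: int = 1, shape=(40, 48, 40),
                             n_iter: int = 200, n_null_seeds: int = 20):
    """cFWE on a corpus with one planted convergence centre vs plant-free corpora.

    Returns the surviving-cluster count and whether the planted centre lies
    inside a surviving cluster, plus the number of plant-free seeds (out of
    `n_null_seeds`) with zero surviving clusters.
    """
    grid = mni_like_grid(shape=shape)
    center = (0.0, 0.0, 0.0)
    cfg = FociGenConfig(mask=grid, cluster_centers=(center,), seed=seed)
    corpus = gen_foci_corpus(cfg)
    table, label_map, *_ = cluster_fwe(corpus, grid, n_iter=n_iter, seed=_sub_seed(seed, 0))
    cvox = grid.nearest_voxel(center)[0]
    contains = bool(label_map.data[tuple(cvox)] > 0)

    clean = 0
    for k in range(n_null_seeds):
        cfg0 = FociGenConfig(mask=grid, cluster_centers=(), noise_foci_per_experiment=4,
                             seed=_sub_seed(seed, 100 + k))
        corpus0 = gen_foci_corpus(cfg0)
        t0, *_ = cluster_fwe(corpus0, grid, n_iter=n_iter, seed=_sub_seed(seed, 200 + k))
        clean += int(len(t0) == 0)
    return {"planted_n_clusters": int(len(table)), "planted_center_recovered": contains,
            "null_seeds_clean": clean, "n_null_seeds": n_null_seeds}


# ---------------------------------------------------------------------------
# 4. Contrast permutation calibration


def contrast_calibration(seed: int = 0, shape=(20, 24, 20), n_per_set: int = 15,
                         n_perm: int = 500, n_reps: int = 8, alpha: float = 0.05):
    """Voxel-wise false-positive rate of the permutation contrast when both
    sets come from the same generator (uniform noise foci).

    Evaluation is restricted to voxels covered by the pooled corpus (voxels
    never touched by any kernel have a degenerate all-zero permutation
    distribution and p = 1 by construction).  Returns mean FPR over
    independent replicate dataset pairs and its standard error.
    """
    grid = mni_like_grid(shape=shape)
    fprs = np.empty(n_reps)
    for r in range(n_reps):
        sets = []
        for half in range(2):
            cfg = FociGenConfig(mask=grid, n_experiments=n_per_set, cluster_centers=(),
                                noise_foci_per_experiment=8,
                                seed=_sub_seed(seed, 10 * r + half))
            sets.append(gen_foci_corpus(cfg))
        pooled_ma = [ma_map(e, grid) for s in sets for e in s]
        coverage = np.zeros(shape, dtype=bool)
        for m in pooled_ma:
            coverage |= m.data > 0
        res = contrast_permutation(sets[0], sets[1], grid, n_perm=n_perm, p=alpha,
                                   restrict_mask=coverage, seed=_sub_seed(seed, 500 + r))
        eval_mask = coverage & grid.mask
        fprs[r] = np.mean(res.p_map_a_gt_b.data[eval_mask] < alpha)
    return {"mean_fpr": float(fprs.mean()),
            "se": float(fprs.std(ddof=1) / np.sqrt(n_reps)),
            "target": alpha, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# 7. Planted-community recovery


def planted_partition(n_nodes: int = 21, n_communities: int = 4) -> np.ndarray:
    base = n_nodes // n_communities
    sizes = [base + (1 if i < n_nodes % n_communities else 0) for i in range(n_communities)]
    return np.repeat(np.arange(1, n_communities + 1), sizes)


def community_recovery(seed: int = 0, n_nodes: int = 21, n_subjects: int = 20,
                       n_timepoints: int = 2000, within_r: float = 0.5,
                       between_r: float = 0.05, n_seeds: int = 20,
                       n_reps: int = 100):
    """Recover a planted 4-community structure from synthetic BOLD.

    One 4D dataset is generated; node time series are sphere means of the
    volumes; the group Fisher-z FC feeds consensus Louvain, repeated under
    `n_seeds` different detection seeds.  Returns the adjusted Rand index of
    each consensus partition against the plant and agreement-matrix checks.
    """
    nodes, grid = lattice_nodes(n_nodes, spacing_mm=12.0)
    plant = planted_partition(n_nodes)
    cfg = BoldGenConfig(nodes=nodes, grid=grid, partition=tuple(plant),
                        within_r=within_r, between_r=between_r,
                        n_timepoints=n_timepoints, n_subjects=n_subjects,
                        seed=_sub_seed(seed, 1))
    ds = gen_bold(cfg)
    from .connectivity import sphere_timeseries
    ts = []
    for s in range(n_subjects):
        bold, _fd = ds.subject(s)
        ts.append(sphere_timeseries(bold, grid, nodes, radius_mm=cfg.sphere_radius_mm,
                                    tr_seconds=cfg.tr_seconds))
    fc = fc_matrix(ts)

    aris = np.empty(n_seeds)
    agreement_ok = True
    for k in range(n_seeds):
        part, agreement, _freq = consensus_communities(fc, n_reps=n_reps,
                                                       seed=_sub_seed(seed, 50 + k))
        aris[k] = adjusted_rand_score(plant, part.labels)
        agreement_ok &= np.allclose(agreement, agreement.T) and np.allclose(np.diag(agreement), 1.0)
    return {"ari": aris, "min_ari": float(aris.min()), "mean_ari": float(aris.mean()),
            "agreement_symmetric_unit_diagonal": bool(agreement_ok), "fc": fc,
            "plant": plant}


# ---------------------------------------------------------------------------
# 9. Receptor-null calibration and power


def _toy_receptor_world(seed: int, shape=(30, 36, 30), n_nodes: int = 21,
                        min_mutual_mm: float = 10.0):
    """An ellipsoid grey-matter grid plus an 'empirical' node set drawn from it
    with a minimum mutual distance (greedy)."""
    from .grid import ellipsoid_mask_grid
    grid = ellipsoid_mask_grid(shape=shape)
    rng = np.random.default_rng(seed)
    gm_mm = grid.masked_mm()
    chosen = []
    for idx in rng.permutation(len(gm_mm)):
        cand = gm_mm[idx]
        if chosen and np.min(np.linalg.norm(np.array(chosen) - cand, axis=1)) < min_mutual_mm:
            continue
        chosen.append(cand)
        if len(chosen) == n_nodes:
            break
    if len(chosen) < n_nodes:
        raise RuntimeError("mask too small for requested node count")
    nodes = NodeSet(coords=np.array(chosen))
    metric = rng.standard_normal(n_nodes)
    return grid, nodes, metric


def receptor_null_calibration(seed: int = 0, n_sims: int = 100, n_networks: int = 199,
                              smoothness_fwhm: float = 6.0):
    """Rejection rate of the random-network null test under zero coupling."""
    grid, nodes, metric = _toy_receptor_world(_sub_seed(seed, 1))
    rejections = 0
    for s in range(n_sims):
        cfg = AnnotationGenConfig(nodes=nodes, grid=grid, node_metric=tuple(metric),
                                  coupling=0.0, smoothness_fwhm=smoothness_fwhm,
                                  seed=_sub_seed(seed, 1000 + s))
        data = gen_annotation_map(cfg)
        profile = sample_node_density(data, grid, nodes)
        emp_rho = stats.spearmanr(metric, profile).statistic
        ens = random_network_null(nodes, grid, data, metric, n_networks=n_networks,
                                  seed=_sub_seed(seed, 2000 + s))
        _p, sig = null_test(emp_rho, ens)
        rejections += int(sig)
    rate = rejections / n_sims
    return {"rejection_rate": rate, "se": float(np.sqrt(0.05 * 0.95 / n_sims)),
            "n_sims": n_sims}


def receptor_null_power(seed: int = 0, n_seeds: int = 20, n_networks: int = 499,
                        coupling: float = 0.8, smoothness_fwhm: float = 6.0):
    """Detection rate for a planted coupling between map and metric."""
    grid, nodes, metric = _toy_receptor_world(_sub_seed(seed, 1))
    detected = 0
    for s in range(n_seeds):
        cfg = AnnotationGenConfig(nodes=nodes, grid=grid, node_metric=tuple(metric),
                                  coupling=coupling, smoothness_fwhm=smoothness_fwhm,
                                  seed=_sub_seed(seed, 3000 + s))
        data = gen_annotation_map(cfg)
        profile = sample_node_density(data, grid, nodes)
        emp_rho = stats.spearmanr(metric, profile).statistic
        ens = random_network_null(nodes, grid, data, metric, n_networks=n_networks,
                                  seed=_sub_seed(seed, 4000 + s))
        _p, sig = null_test(emp_rho, ens)
        detected += int(sig)
    return {"detected": detected, "n_seeds": n_seeds,
            "detection_rate": detected / n_seeds}
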