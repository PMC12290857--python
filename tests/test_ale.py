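import numpy as np
import pytest

from alenet import (
    Experiment, ExperimentSet, KernelSpec, StatMap, ale_map, analytic_null,
    cluster_fwe, kernel_sd, ma_map, mni_like_grid, read_experiment_table,
    voxel_threshold, write_experiment_table,
)


# ---------------------------------------------------------------------------
# Kernel width model


def test_kernel_sd_closed_form():
    spec = KernelSpec(sigma_template_mm=3.0, sigma_subject_mm=4.0)
    assert kernel_sd(4, spec) == pytest.approx(np.sqrt(9 + 4))  # 3.6056


def test_kernel_sd_template_limit_and_monotonicity():
    spec = KernelSpec(sigma_template_mm=3.0, sigma_subject_mm=1e-9)
    assert kernel_sd(1, spec) == pytest.approx(3.0)
    spec = KernelSpec()
    sds = [kernel_sd(n, spec) for n in range(1, 101)]
    assert all(a > b for a, b in zip(sds, sds[1:]))
    with pytest.raises(ValueError):
        kernel_sd(0, spec)


# ---------------------------------------------------------------------------
# MA maps


def _single_focus_exp(xyz=(0.0, 0.0, 0.0), n=20, foci=None):
    return Experiment(study_id="s", experiment_id="e", contrast="c", n_subjects=n,
                      foci=np.atleast_2d(foci if foci is not None else xyz))


def test_ma_single_focus_peaks_at_focus_and_decays(small_grid):
    m = ma_map(_single_focus_exp(), small_grid)
    peak_vox = np.unravel_index(np.argmax(m.data), m.data.shape)
    assert np.array_equal(peak_vox, small_grid.nearest_voxel([0, 0, 0])[0])
    # radially non-increasing along an axis from the peak
    line = m.data[peak_vox[0]:, peak_vox[1], peak_vox[2]]
    assert np.all(np.diff(line) <= 1e-15)


def test_ma_two_identical_foci_non_additive(small_grid):
    one = ma_map(_single_focus_exp(), small_grid)
    two = ma_map(_single_focus_exp(foci=[[0, 0, 0], [0, 0, 0]]), small_grid)
    assert np.array_equal(one.data, two.data)


def test_ma_kernel_mass_sums_to_one():
    grid = mni_like_grid((40, 40, 40))  # large enough to hold full support
    m = ma_map(_single_focus_exp(n=10), grid)
    assert m.data.sum() == pytest.approx(1.0, abs=1e-6)


def test_ma_focus_outside_mask_warns():
    mask = np.zeros((20, 20, 20), bool)
    mask[5:15, 5:15, 5:15] = True
    grid = mni_like_grid((20, 20, 20), mask=mask)
    with pytest.warns(UserWarning, match="outside the analysis mask"):
        ma_map(_single_focus_exp(xyz=(-18.0, -18.0, -18.0)), grid)


# ---------------------------------------------------------------------------
# ALE union


def test_ale_union_formula(small_grid):
    def const_map(v):
        return StatMap(grid=small_grid, data=np.full(small_grid.shape, v), kind="MA")

    ale = ale_map([const_map(0.5), const_map(0.5)])
    assert np.allclose(ale.data, 0.75)
    ale = ale_map([const_map(0.2), const_map(0.3), const_map(0.4)])
    assert np.allclose(ale.data, 1 - 0.8 * 0.7 * 0.6)


def test_ale_single_experiment_identity(toy_ma_maps):
    ale = ale_map(toy_ma_maps[:1])
    assert np.allclose(ale.data, toy_ma_maps[0].data, atol=1e-15)


def test_ale_all_zero_map_is_neutral(toy_ma_maps, small_grid):
    zero = StatMap(grid=small_grid, data=np.zeros(small_grid.shape), kind="MA")
    a = ale_map(toy_ma_maps)
    b = ale_map(toy_ma_maps + [zero])
    assert np.allclose(a.data, b.data)


def test_ale_monotone_in_ma(toy_ma_maps):
    bumped = [StatMap(grid=m.grid, data=np.minimum(m.data * 1.1, 0.99), kind="MA")
              for m in toy_ma_maps]
    a = ale_map(toy_ma_maps)
    b = ale_map(bumped)
    assert np.all(b.data >= a.data - 1e-15)
    assert np.all(a.data >= 0) and np.all(a.data < 1)


# ---------------------------------------------------------------------------
# Analytic null


def test_analytic_null_single_experiment_two_values(small_grid):
    data = np.zeros(small_grid.shape)
    flat = data.reshape(-1)
    n_hit = int(0.25 * flat.size)
    flat[:n_hit] = 0.01
    null = analytic_null([StatMap(grid=small_grid, data=data, kind="MA")])
    f = n_hit / flat.size
    idx = int(round(0.01 / null.bin_width))
    assert null.prob_mass[0] == pytest.approx(1 - f)
    assert null.prob_mass[idx] == pytest.approx(f)


def test_analytic_null_all_zero_point_mass(small_grid):
    zero = StatMap(grid=small_grid, data=np.zeros(small_grid.shape), kind="MA")
    null = analytic_null([zero, zero])
    assert null.prob_mass[0] == pytest.approx(1.0)
    assert null.p_values(np.array([0.0]))[0] == pytest.approx(1.0)


def test_analytic_null_survival_non_increasing(toy_ma_maps):
    null = analytic_null(toy_ma_maps)
    assert np.all(np.diff(null.sf) <= 1e-15)
    assert null.prob_mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_analytic_null_matches_monte_carlo_pairing(toy_ma_maps):
    """Survival function agrees with brute-force random voxel pairing."""
    null = analytic_null(toy_ma_maps)
    rng = np.random.default_rng(11)
    n_draws = 200_000
    prod = np.ones(n_draws)
    for m in toy_ma_maps:
        vals = m.masked_values
        prod *= 1.0 - vals[rng.integers(0, len(vals), n_draws)]
    draws = 1.0 - prod
    # compare sf on a grid of probe points
    probes = np.quantile(draws[draws > 0], [0.5, 0.9, 0.99, 0.999])
    for q in probes:
        emp = np.mean(np.rint(draws / null.bin_width) >= np.rint(q / null.bin_width))
        ana = null.p_values(np.array([q]))[0]
        assert emp == pytest.approx(ana, abs=0.005)


# ---------------------------------------------------------------------------
# Thresholding + cFWE


def test_voxel_threshold_p1_retains_everything(toy_ma_maps, small_grid):
    ale = ale_map(toy_ma_maps)
    null = analytic_null(toy_ma_maps)
    lab, p, z = voxel_threshold(ale, null, p_voxel=1.0)
    assert lab.data[small_grid.mask].sum() == small_grid.n_masked
    assert np.all(p.masked_values > 0) and np.all(p.masked_values <= 1)


def test_voxel_threshold_low_ale_not_retained(toy_ma_maps, small_grid):
    ale = ale_map(toy_ma_maps)
    null = analytic_null(toy_ma_maps)
    lab, p, z = voxel_threshold(ale, null, p_voxel=0.001)
    zero_vox = ale.masked_values == 0
    assert np.all(p.masked_values[zero_vox] == pytest.approx(1.0))
    assert not lab.masked_values[zero_vox].any()


def test_planted_convergence_beats_background(small_grid):
    exps = [
        Experiment(study_id=f"s{i}", experiment_id=f"e{i}", contrast="c",
                   n_subjects=25, foci=[[0.0, 0.0, 0.0]])
        for i in range(3)
    ]
    mas = [ma_map(e, small_grid) for e in exps]
    ale = ale_map(mas)
    null = analytic_null(mas)
    _, p, _ = voxel_threshold(ale, null)
    center = tuple(small_grid.nearest_voxel([0, 0, 0])[0])
    corner = tuple(small_grid.nearest_voxel([-16, -20, -16])[0])
    assert p.data[center] < 0.001
    assert p.data[corner] > 0.1


def test_cluster_fwe_deterministic_and_recovers_plant(toy_corpus, small_grid):
    t1, lab1, *_ = cluster_fwe(toy_corpus, small_grid, n_iter=100, seed=5)
    t2, lab2, *_ = cluster_fwe(toy_corpus, small_grid, n_iter=100, seed=5)
    assert t1.equals(t2)
    assert np.array_equal(lab1.data, lab2.data)
    if len(t1):  # planted center inside a surviving cluster when any survive
        center = tuple(small_grid.nearest_voxel([0, 0, 0])[0])
        assert lab1.data[center] > 0


def test_cluster_fwe_rejects_small_n_iter(toy_corpus, small_grid):
    with pytest.raises(ValueError):
        cluster_fwe(toy_corpus, small_grid, n_iter=50)


# ---------------------------------------------------------------------------
# Foci table I/O


def _write(tmp_path, text, name="foci.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "study_id\texperiment_id\tcontrast\tn\tx\ty\tz\tpooling_group\n"


def test_read_two_distinct_experiments(tmp_path):
    p = _write(tmp_path, HEADER + "s1\te1\timpulsive\t20\t0\t0\t0\t\n"
                                  "s2\te2\tcontrolled\t15\t10\t10\t10\t\n")
    es = read_experiment_table(p)
    assert len(es) == 2


def test_pooling_uses_smaller_sample_size(tmp_path):
    p = _write(tmp_path, HEADER + "s1\te1\timpulsive\t20\t0\t0\t0\tg1\n"
                                  "s1\te1\timpulsive\t20\t4\t0\t0\tg1\n"
                                  "s2\te2\timpulsive\t15\t8\t0\t0\tg1\n")
    es = read_experiment_table(p, pooling=True)
    assert len(es) == 1
    exp = es.experiments[0]
    assert exp.n_subjects == 15
    assert len(exp.foci) == 3
    # pooling off keeps them separate
    es2 = read_experiment_table(p, pooling=False)
    assert len(es2) == 2


def test_node_table_rejected_by_foci_reader(tmp_path):
    p = _write(tmp_path, "region\themisphere\tx\ty\tz\nVS\tLeft\t-8\t10\t0\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_experiment_table(p)


def test_malformed_coordinate_reports_line(tmp_path):
    p = _write(tmp_path, HEADER + "s1\te1\tc\t20\t0\t0\t0\t\n"
                                  "s1\te1\tc\t20\tnope\t0\t0\t\n")
    with pytest.raises(ValueError, match="line 3"):
        read_experiment_table(p)


def test_empty_table_errors(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        read_experiment_table(_write(tmp_path, HEADER))


def test_roundtrip(tmp_path, toy_corpus):
    p = tmp_path / "out.tsv"
    write_experiment_table(toy_corpus, p)
    back = read_experiment_table(p)
    assert len(back) == len(toy_corpus)
    for a, b in zip(toy_corpus, back):
        assert np.allclose(a.foci, b.foci)
        assert a.n_subjects == b.n_subjects
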