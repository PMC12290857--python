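import numpy as np
import pytest

from alenet import (
    NodeSet, NodeTimeSeries, denoise, fc_matrix, fd_filter, fisher_z,
    framewise_displacement, mni_like_grid, seed_to_voxel, sphere_timeseries,
)


class TestMotion:
    def test_mean_fd_above_threshold_excluded(self):
        traces = [np.full(10, 0.6), np.full(10, 0.1)]
        assert fd_filter(traces, 0.5) == [1]

    def test_boundary_is_inclusive(self):
        assert fd_filter([np.full(10, 0.5)], 0.5) == [0]

    def test_all_below_threshold_identity(self):
        traces = [np.full(10, 0.1)] * 4
        assert fd_filter(traces, 0.5) == [0, 1, 2, 3]

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fd_filter([np.array([])], 0.5)

    def test_fd_power_convention(self):
        mp = np.zeros((3, 6))
        mp[1, 0] = 1.0           # 1 mm translation step
        mp[2, 3] = 0.02          # 0.02 rad rotation step -> 1 mm at 50 mm radius
        fd = framewise_displacement(mp)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(1.0)
        assert fd[2] == pytest.approx(2.0)  # undo translation (1) + rotation (1)


class TestDenoise:
    def test_global_signal_regression_removes_itself(self):
        rng = np.random.default_rng(0)
        gs = rng.standard_normal(100)
        bold = np.tile(gs, (2, 2, 2, 1))
        out = denoise(bold, confounds=gs[:, None], tr_seconds=1.4,
                      band_hz=None, smooth_fwhm_mm=0.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_bandpass_suppresses_out_of_band_sinusoid(self):
        # spectral check: the 0.2 Hz Fourier component (above the 0.1 Hz
        # edge) must come out at < 5% of its input amplitude
        tr = 1.4
        n = 300
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * 0.2 * t)
        bold = np.tile(sig, (2, 2, 2, 1))
        out = denoise(bold, confounds=None, tr_seconds=tr, smooth_fwhm_mm=0.0)
        k = np.argmin(np.abs(np.fft.rfftfreq(n, tr) - 0.2))
        ratio = np.abs(np.fft.rfft(out[0, 0, 0]))[k] / np.abs(np.fft.rfft(sig))[k]
        assert ratio < 0.05

    def test_in_band_sinusoid_survives(self):
        tr = 1.4
        t = np.arange(600) * tr
        sig = np.sin(2 * np.pi * 0.05 * t)
        bold = np.tile(sig, (1, 1, 1, 1))
        out = denoise(bold, confounds=None, tr_seconds=tr, smooth_fwhm_mm=0.0)
        assert np.abs(out).max() > 0.8 * np.abs(sig).max()

    def test_linear_ramp_removed_by_detrending(self):
        ramp = np.linspace(0, 5, 120)
        bold = np.tile(ramp, (2, 2, 2, 1))
        out = denoise(bold, confounds=None, tr_seconds=1.4, band_hz=None,
                      smooth_fwhm_mm=0.0)
        assert np.abs(out).max() < 1e-8

    def test_collinear_confounds_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(50)
        confounds = np.column_stack([c, 2 * c])
        bold = rng.standard_normal((2, 2, 2, 50))
        with pytest.warns(UserWarning, match="collinear"):
            denoise(bold, confounds=confounds, tr_seconds=1.4, band_hz=None,
                    smooth_fwhm_mm=0.0)


class TestSphereTimeseries:
    def test_radius5_averages_81_voxels(self):
        grid = mni_like_grid((21, 21, 21))
        nodes = NodeSet(coords=[[0.0, 0.0, 0.0]])
        bold = np.zeros(grid.shape + (3,))
        # mark exactly the 81 in-sphere voxels with 1
        from alenet import sphere_voxels
        idx = sphere_voxels(grid, [0, 0, 0], 5.0)
        assert len(idx) == 81
        bold[idx[:, 0], idx[:, 1], idx[:, 2], :] = 1.0
        ts = sphere_timeseries(bold, grid, nodes, radius_mm=5.0)
        assert np.allclose(ts.data, 1.0)
        # neighbouring shell excluded: widen bold, mean unchanged only if
        # sphere restricted to radius
        ts2 = sphere_timeseries(bold, grid, nodes, radius_mm=7.0)
        assert ts2.data.mean() < 1.0

    def test_tiny_radius_single_voxel(self):
        grid = mni_like_grid((21, 21, 21))
        nodes = NodeSet(coords=[[0.0, 0.0, 0.0]])
        rng = np.random.default_rng(0)
        bold = rng.standard_normal(grid.shape + (5,))
        ts = sphere_timeseries(bold, grid, nodes, radius_mm=0.1)
        center = grid.nearest_voxel([0, 0, 0])[0]
        assert np.array_equal(ts.data[0], bold[tuple(center)])

    def test_constant_volume_constant_series(self):
        grid = mni_like_grid((15, 15, 15))
        nodes = NodeSet(coords=[[0.0, 0.0, 0.0]])
        bold = np.full(grid.shape + (4,), 3.14)
        ts = sphere_timeseries(bold, grid, nodes)
        assert np.allclose(ts.data, 3.14)

    def test_empty_sphere_names_node(self):
        mask = np.zeros((15, 15, 15), bool)
        mask[0, 0, 0] = True
        grid = mni_like_grid((15, 15, 15), mask=mask)
        nodes = NodeSet(coords=[[0.0, 0.0, 0.0]], regions=("my node",))
        bold = np.zeros(grid.shape + (4,))
        with pytest.raises(ValueError, match="my node"):
            sphere_timeseries(bold, grid, nodes, radius_mm=2.0)


class TestFCMatrix:
    def test_fisher_z_closed_form(self):
        assert fisher_z(np.array([0.0]))[0] == 0.0
        assert fisher_z(np.array([0.5]))[0] == pytest.approx(0.5493, abs=1e-4)

    def test_fisher_z_roundtrip(self):
        r = np.linspace(-0.999, 0.999, 21)
        assert np.allclose(np.tanh(fisher_z(r)), r, atol=1e-12)

    def test_opposite_subjects_cancel(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 200))
        ts1 = NodeTimeSeries(data=x)
        ts2 = NodeTimeSeries(data=x * np.array([1, -1, 1, -1])[:, None])
        fc = fc_matrix([ts1, ts2])
        # edges between flipped/unflipped pairs cancel exactly
        assert fc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert fc[2, 3] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        fc = fc_matrix([NodeTimeSeries(data=rng.standard_normal((6, 100)))])
        assert np.allclose(fc, fc.T, atol=1e-12)
        assert np.all(np.diag(fc) == 0)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5, 150))
        perm = np.array([2, 0, 4, 1, 3])
        fc = fc_matrix([NodeTimeSeries(data=x)])
        fc_p = fc_matrix([NodeTimeSeries(data=x[perm])])
        assert np.allclose(fc_p, fc[np.ix_(perm, perm)], atol=1e-12)

    def test_zero_variance_node_warns(self):
        x = np.random.default_rng(5).standard_normal((3, 50))
        x[1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            fc = fc_matrix([NodeTimeSeries(data=x)])
        assert np.isnan(fc[0, 1])


@pytest.fixture(scope="module")
def setup():
    from alenet import BoldGenConfig, gen_bold, lattice_nodes
    nodes, grid = lattice_nodes(6, spacing_mm=14.0)
    cfg = BoldGenConfig(nodes=nodes, grid=grid, partition=(1, 1, 1, 2, 2, 2),
                        within_r=0.6, between_r=0.0, n_timepoints=300,
                        n_subjects=2, noise_sd=0.5, seed=8)
    ds = gen_bold(cfg)
    bolds = [ds.subject(s)[0] for s in range(2)]
    return nodes, grid, bolds, np.array(cfg.partition)


class TestSeedToVoxel:
    def test_seed_sphere_voxels_correlate_with_seed(self, setup):
        nodes, grid, bolds, part = setup
        maps = seed_to_voxel(bolds, grid, nodes)
        from alenet import sphere_voxels
        gm_flat = np.zeros(grid.shape)
        gm_flat[maps.gm_mask] = maps.maps[0]
        idx = sphere_voxels(grid, nodes.coords[0], 5.0)
        own = gm_flat[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert own.mean() > 1.0  # Fisher z of strong correlation

    def test_within_community_maps_more_similar(self, setup):
        nodes, grid, bolds, part = setup
        maps = seed_to_voxel(bolds, grid, nodes)
        sim = np.corrcoef(maps.maps)
        same = part[:, None] == part[None, :]
        off = ~np.eye(len(part), dtype=bool)
        assert sim[same & off].mean() > sim[~same].mean()

    def test_single_subject_identity(self, setup):
        nodes, grid, bolds, _ = setup
        one = seed_to_voxel(bolds[:1], grid, nodes)
        again = seed_to_voxel(bolds[:1], grid, nodes)
        assert np.array_equal(one.maps, again.maps)
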