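"""Ground-truth generator: motion statistics, nucleus geometry, rendering."""

import numpy as np
import pytest

from chromotion import (
    SimulationConfig,
    TextureParams,
    compute_msd,
    render_movie,
    render_psf_pair,
    simulate_nucleus,
    simulate_trajectories,
)
from chromotion.simulate import FWHM_TO_SIGMA, fbm_increments
from tests.conftest import trajectories_from_truth


class TestTrajectories:
    def test_zero_motion_is_constant(self):
        cfg = SimulationConfig(n_foci=10, n_frames=20, D=0.0, loc_noise_sigma=0.0,
                               seed=0, noise=False)
        truth = simulate_trajectories(cfg, None)
        assert np.all(truth.true_positions == truth.true_positions[:, :1, :])
        curve = compute_msd(trajectories_from_truth(truth), cfg.dt)
        assert np.allclose(curve.msd, 0.0)

    def test_brownian_msd_matches_closed_form(self, brownian_truth):
        # E[MSD(dt)] = 6 D dt + 6 sigma^2 = 0.0099 µm² at dt = 5 s
        curve = compute_msd(trajectories_from_truth(brownian_truth), 5.0, max_lag=5.0)
        expected = 6 * 14.99e-5 * 5.0 + 6 * 0.03 ** 2
        assert curve.msd[0] == pytest.approx(expected, rel=0.05)

    def test_brownian_msd_within_3se_at_every_lag(self, brownian_truth):
        # chi-square sampling: per-track time-avg MSD at lag k over N steps has
        # rel. variance ~ (2k/3)*(something <= 2k/(n_pairs)); use the empirical
        # bound var(msd_k) <= msd_k^2 * 2k / n_pairs_per_track, then /n_tracks.
        trs = trajectories_from_truth(brownian_truth)
        curve = compute_msd(trs, 5.0, max_lag=50.0)
        sigma2 = 0.03 ** 2
        expected = 6 * 14.99e-5 * curve.lags + 6 * sigma2
        n_tracks = 1000
        k = np.arange(1, len(curve.lags) + 1)
        per_track_pairs = 100 - k + 1
        se = expected * np.sqrt(2.0 * k / per_track_pairs / n_tracks)
        assert np.all(np.abs(curve.msd - expected) < 3 * se * 1.5 + 1e-6)

    def test_fbm_msd_closed_form(self):
        # ensemble MSD = 6 Gamma t^0.5 at lags {5, 10, 20} s, within 5 %
        cfg = SimulationConfig(n_foci=2000, n_frames=30, D=1e-4, alpha=0.5,
                               loc_noise_sigma=0.0, seed=2, noise=False)
        truth = simulate_trajectories(cfg, None)
        curve = compute_msd(trajectories_from_truth(truth), cfg.dt, max_lag=20.0)
        for lag in (5.0, 10.0, 20.0):
            i = int(np.argmin(np.abs(curve.lags - lag)))
            assert curve.msd[i] == pytest.approx(6 * 1e-4 * lag ** 0.5, rel=0.05)

    @pytest.mark.parametrize("alpha", [0.5, 1.5])
    def test_fbm_loglog_slope_recovers_alpha(self, alpha):
        cfg = SimulationConfig(n_foci=2000, n_frames=51, D=1e-4, alpha=alpha,
                               loc_noise_sigma=0.0, seed=7, noise=False)
        truth = simulate_trajectories(cfg, None)
        curve = compute_msd(trajectories_from_truth(truth), cfg.dt, max_lag=100.0)
        slope = np.polyfit(np.log(curve.lags), np.log(curve.msd), 1)[0]
        assert abs(slope - alpha) < 0.05

    def test_fbm_increment_variance(self):
        rng = np.random.default_rng(0)
        inc = fbm_increments(rng, 64, 5000, hurst=0.25, step_scale=2.0)
        assert inc.std() ** 2 == pytest.approx(2.0, rel=0.05)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            SimulationConfig(alpha=2.5)
        with pytest.raises(ValueError, match="alpha"):
            SimulationConfig(alpha=0.0)

    def test_nucleus_too_small_rejected(self):
        samp = simulate_nucleus((5, 16, 16), (0.17, 0.048, 0.048), seed=0)
        n_inside = int(samp.mask.mask.sum())
        cfg = SimulationConfig(n_foci=n_inside + 1, n_frames=5)
        with pytest.raises(ValueError, match="too small"):
            simulate_trajectories(cfg, samp.mask)

    def test_positions_stay_inside_nucleus(self):
        samp = simulate_nucleus((9, 64, 64), (0.15, 0.05, 0.05), seed=1)
        cfg = SimulationConfig(n_foci=30, n_frames=50, D=5e-4, loc_noise_sigma=0.0,
                               seed=1, image_shape=(9, 64, 64),
                               voxel_size=(0.15, 0.05, 0.05), noise=False)
        truth = simulate_trajectories(cfg, samp.mask)
        center = np.asarray(samp.mask.center_um)
        semi = np.asarray(samp.mask.semi_axes_um)
        u = (truth.true_positions - center) / semi
        assert np.all(np.linalg.norm(u, axis=-1) <= 1.0 + 1e-9)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_foci=5, n_frames=10, seed=42)
        a = simulate_trajectories(cfg, None)
        b = simulate_trajectories(cfg, None)
        assert np.array_equal(a.true_positions, b.true_positions)
        assert np.array_equal(a.observed_positions, b.observed_positions)


class TestNucleus:
    def test_two_component_texture_fractions(self, nucleus_sample):
        labels = nucleus_sample.labels
        inside = labels > 0
        frac1 = (labels[inside] == 1).mean()
        assert abs(frac1 - 0.5) < 0.05
        vals = nucleus_sample.dna[inside]
        # bimodality: means of the two halves are far apart relative to sds
        assert vals[labels[inside] == 2].mean() - vals[labels[inside] == 1].mean() > 150

    def test_ellipsoid_volume(self):
        # semi-axes (2, 4, 4) µm -> (4/3) pi 32 = 134.04 µm³
        vs = (0.2, 0.1, 0.1)
        samp = simulate_nucleus(
            (24, 90, 90), vs,
            TextureParams(semi_axes_um=(2.0, 4.0, 4.0)), seed=0,
        )
        vol = samp.mask.volume_um3
        true_vol = 4.0 / 3.0 * np.pi * 32.0
        # one voxel-shell tolerance: surface area x voxel size
        area = 4 * np.pi * (2 * 4 * 4) ** (2 / 3)  # ~ sphere-equivalent area
        shell = area * max(vs)
        assert abs(vol - true_vol) < shell

    def test_determinism(self):
        a = simulate_nucleus((8, 32, 32), (0.2, 0.1, 0.1), seed=5)
        b = simulate_nucleus((8, 32, 32), (0.2, 0.1, 0.1), seed=5)
        assert np.array_equal(a.dna, b.dna)
        assert np.array_equal(a.mask.mask, b.mask.mask)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            simulate_nucleus((1, 32, 32), (0.2, 0.1, 0.1))


class TestRenderMovie:
    def test_empty_scene_is_background(self):
        cfg = SimulationConfig(n_foci=0, n_frames=3, background=10.0, noise=False,
                               image_shape=(5, 32, 32))
        truth = simulate_trajectories(cfg, None)
        movie = render_movie(truth, cfg)
        assert np.all(movie.data[:, 1] == 10.0)

    def test_static_focus_at_argmax(self):
        cfg = SimulationConfig(n_foci=1, n_frames=4, D=0.0, loc_noise_sigma=0.0,
                               noise=False, motion_amplitude=0.0, seed=3,
                               image_shape=(5, 32, 32))
        truth = simulate_trajectories(cfg, None)
        truth.true_positions[:] = np.array([0.34, 0.72, 0.72])  # exact voxel center
        movie = render_movie(truth, cfg)
        for t in range(4):
            idx = np.unravel_index(np.argmax(movie.data[t, 1]), (5, 32, 32))
            assert idx == (2, 15, 15)

    def test_spot_integral_matches_gaussian(self):
        cfg = SimulationConfig(n_foci=1, n_frames=2, D=0.0, loc_noise_sigma=0.0,
                               noise=False, background=0.0, photon_scale=100.0,
                               focus_sigma=0.0, psf_fwhm=(0.4, 0.16, 0.16),
                               image_shape=(9, 64, 64), voxel_size=(0.15, 0.048, 0.048),
                               seed=0)
        truth = simulate_trajectories(cfg, None)
        truth.true_positions[:] = np.array([0.6, 1.5, 1.5])
        movie = render_movie(truth, cfg)
        sig = np.array(cfg.psf_fwhm) * FWHM_TO_SIGMA
        expected = 100.0 * (2 * np.pi) ** 1.5 * np.prod(sig) / np.prod(cfg.voxel_size)
        assert movie.data[0, 1].sum() == pytest.approx(expected, rel=0.02)

    def test_bleaching_decay_of_frame_sums(self):
        cfg = SimulationConfig(n_foci=3, n_frames=10, D=0.0, loc_noise_sigma=0.0,
                               noise=False, background=2.0, bleach_rate=0.01,
                               motion_amplitude=0.0, seed=4, image_shape=(5, 48, 48))
        truth = simulate_trajectories(cfg, None)
        truth.true_positions[:] = truth.true_positions[:, :1, :] * 0 + \
            np.array([[0.4, 1.1, 1.1], [0.4, 1.3, 0.9], [0.4, 0.9, 1.3]])[:, None, :]
        movie = render_movie(truth, cfg)
        sums = movie.data[:, 1].sum(axis=(1, 2, 3)) - 2.0 * 5 * 48 * 48
        t = np.arange(10) * cfg.dt
        assert np.allclose(sums, sums[0] * np.exp(-0.01 * t), rtol=1e-6)

    def test_seed_gives_bit_identical_movie(self):
        cfg = SimulationConfig(n_foci=5, n_frames=3, seed=6, image_shape=(5, 32, 32))
        t1 = simulate_trajectories(cfg, None)
        t2 = simulate_trajectories(cfg, None)
        m1 = render_movie(t1, cfg)
        m2 = render_movie(t2, cfg)
        assert np.array_equal(m1.data, m2.data)

    def test_motion_recorded_as_transforms(self):
        cfg = SimulationConfig(n_foci=2, n_frames=5, motion_amplitude=0.3, seed=1,
                               image_shape=(5, 32, 32), noise=False)
        truth = simulate_trajectories(cfg, None)
        render_movie(truth, cfg)
        assert truth.transforms is not None and len(truth.transforms) == 5
        assert truth.transforms[0].is_identity()
        assert np.linalg.norm(truth.transforms[4].translation) > 0.05


class TestRenderPsfPair:
    def test_equal_fwhm_gives_identical_images(self):
        pts = np.array([[1.0, 1.0], [1.0, 2.0]])
        a, b = render_psf_pair(pts, 0.2, 0.2, 0.02, noise=0.0, seed=0)
        assert np.array_equal(a, b)

    def test_single_point_profile_fwhm(self):
        a, _ = render_psf_pair(np.array([[1.5, 1.5]]), 0.30, 0.30, 0.02,
                               noise=0.0, seed=0, shape=(150, 150))
        row = a[75]  # horizontal profile through the emitter's row
        half = (row.min() + row.max()) / 2
        above = np.flatnonzero(row > half)
        fwhm = (above[-1] - above[0]) * 0.02
        assert fwhm == pytest.approx(0.30, abs=0.02)  # ± 1 pixel

    def test_seeded_noise_reproducible(self):
        grid = np.mgrid[1:8:1.0, 1:6:1.0].reshape(2, -1).T  # well separated
        pts = grid + np.random.default_rng(1).uniform(-0.1, 0.1, grid.shape)
        a1, b1 = render_psf_pair(pts, 0.14, 0.30, 0.02, noise=3.0, seed=9)
        a2, b2 = render_psf_pair(pts, 0.14, 0.30, 0.02, noise=3.0, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_overlapping_points_warn(self):
        with pytest.warns(UserWarning, match="mix"):
            render_psf_pair(np.array([[1.0, 1.0], [1.0, 1.1]]), 0.3, 0.3, 0.02)
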