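"""Synthetic-data generator: diffusion physics, photophysics, traces, patterns."""

import numpy as np
import pytest
from scipy import stats

from trnatrack import (CellGeometry, ImagingConfig, render_movie,
                       sample_spatial_pattern, simulate_bleach_traces,
                       simulate_localized_tracks, simulate_trajectory)
from trnatrack.config import ConfigError
from trnatrack.geometry import GeometryError, reflect_into
from trnatrack.simulate import bias_for_enrichment, true_periphery_fraction


class TestTrajectory:
    def test_zero_diffusion_is_static(self, geometry, imaging):
        path = simulate_trajectory(geometry, D=0.0, n_frames=20,
                                   config=imaging, seed=7)
        assert np.allclose(path.substep_positions,
                           path.substep_positions[0])
        assert np.allclose(path.frame_positions, path.frame_positions[0])

    def test_unconfined_step_variance_matches_brownian(self, geometry):
        # per-axis variance of raw substep increments must be 2 D dt
        D, n = 2.0, 10_000
        cfg = ImagingConfig(strobe_duration=0.005)  # full-frame strobe
        path = simulate_trajectory(geometry, D=D, n_frames=n, config=cfg,
                                   substeps_per_frame=1, seed=3,
                                   unconfined=True)
        steps = np.diff(path.substep_positions, axis=0)
        expected = 2 * D * cfg.frame_interval
        for ax in range(3):
            var = steps[:, ax].var(ddof=1)
            se = expected * np.sqrt(2.0 / (n - 1))
            assert abs(var - expected) < 3 * se

    def test_confinement_invariant(self, geometry, imaging):
        path = simulate_trajectory(geometry, D=8.0, n_frames=400,
                                   config=imaging, substeps_per_frame=25,
                                   seed=11)
        assert geometry.contains(path.substep_positions).all()
        # distance from the cell axis never exceeds the radius
        assert geometry.axial_distance(path.substep_positions).max() <= 0.5 + 1e-9

    def test_long_time_transverse_variance_is_uniform_disc(self, imaging):
        # equilibrium in the cylindrical part: per-axis transverse variance
        # -> r^2/4 (the caps are excluded: a hemisphere's is r^2/5)
        geom = CellGeometry(length=3.0, radius=0.5)
        path = simulate_trajectory(geom, D=8.0, n_frames=3000,
                                   config=imaging, substeps_per_frame=10,
                                   seed=5)
        pts = path.substep_positions
        cyl = np.abs(pts[:, 0]) <= geom.half_axis
        v = pts[cyl, 1].var()
        assert abs(v - 0.0625) / 0.0625 < 0.05

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            CellGeometry(length=0.8, radius=0.5)

    def test_reflection_keeps_points_inside(self, geometry, rng):
        pts = rng.normal(0, 2.0, size=(500, 3))
        folded = reflect_into(pts, geometry)
        assert geometry.contains(folded).all()


class TestRendering:
    def test_background_only_mean(self, geometry):
        cfg = ImagingConfig(background_rate=3.0, em_gain=10.0, read_noise=2.0)
        movie = render_movie([], geometry, cfg, frame_count=4, seed=0,
                             shape=(32, 32))
        mean = movie.frames.astype(float).mean()
        assert abs(mean - cfg.em_gain * cfg.background_rate) < 2.0

    def test_centroid_unbiased_without_noise(self, geometry):
        cfg = ImagingConfig(photons_per_strobe=1e4, background_rate=0.0,
                            em_gain=1.0, read_noise=0.0)
        path = simulate_trajectory(geometry, D=0.0, n_frames=1, config=cfg,
                                   seed=1, init=np.array([0.31, 0.07, 0.0]))
        movie = render_movie([path], geometry, cfg, seed=0, noise=False)
        frame = movie.frames[0].astype(float)
        yy, xx = np.mgrid[:frame.shape[0], :frame.shape[1]]
        cx = (frame * xx).sum() / frame.sum()
        cy = (frame * yy).sum() / frame.sum()
        ps = cfg.pixel_size
        true_x = (movie.truth["x_um"].iloc[0] - movie.origin[0]) / ps
        true_y = (movie.truth["y_um"].iloc[0] - movie.origin[1]) / ps
        assert abs(cx - true_x) < 1e-2
        assert abs(cy - true_y) < 1e-2

    def test_photon_conservation(self, geometry):
        cfg = ImagingConfig(photons_per_strobe=2000.0, background_rate=0.0,
                            em_gain=5.0, read_noise=0.0)
        path = simulate_trajectory(geometry, D=0.0, n_frames=20, config=cfg,
                                   seed=2, init=np.zeros(3))
        movie = render_movie([path], geometry, cfg, seed=3)
        per_frame = movie.frames.reshape(20, -1).astype(float).sum(axis=1) / cfg.em_gain
        # Poisson with doubled variance: sd = sqrt(2 N)
        se = np.sqrt(2 * cfg.photons_per_strobe / 20)
        assert abs(per_frame.mean() - cfg.photons_per_strobe) < 4 * se

    def test_zero_pixel_size_rejected(self):
        with pytest.raises(ConfigError):
            ImagingConfig(pixel_size=0.0)


class TestLocalizedTracks:
    def test_immobile_scatter_matches_loc_error(self, geometry, imaging):
        field = simulate_localized_tracks(geometry, [(0.0, 1.0)],
                                          mean_emitters_per_cell=2.0,
                                          n_cells=200, config=imaging,
                                          n_frames=10, seed=4)
        err = field.localizations["x_um"] - field.localizations["x_true_um"]
        n = len(err)
        se = 0.04 / np.sqrt(2 * (n - 1))
        assert abs(err.std(ddof=1) - 0.04) < 4 * se

    def test_poisson_emitter_count(self, geometry, imaging):
        field = simulate_localized_tracks(geometry, [(1.0, 1.0)],
                                          mean_emitters_per_cell=1.5,
                                          n_cells=500, config=imaging,
                                          n_frames=2, seed=5)
        n_emitters = field.localizations["emitter_id"].nunique()
        assert abs(n_emitters - 750) < 3 * np.sqrt(750)

    def test_noise_free_equals_truth(self, geometry):
        cfg = ImagingConfig(loc_error_axis=0.0)
        field = simulate_localized_tracks(geometry, [(2.0, 1.0)],
                                          n_cells=20, config=cfg,
                                          n_frames=5, seed=6)
        assert np.allclose(field.localizations["x_um"],
                           field.localizations["x_true_um"])

    def test_empty_mix_rejected(self, geometry):
        with pytest.raises(ConfigError):
            simulate_localized_tracks(geometry, [], n_cells=5)

    def test_seed_reproducibility(self, geometry, imaging):
        a = simulate_localized_tracks(geometry, [(8.0, 0.5), (0.5, 0.5)],
                                      n_cells=30, config=imaging, seed=42)
        b = simulate_localized_tracks(geometry, [(8.0, 0.5), (0.5, 0.5)],
                                      n_cells=30, config=imaging, seed=42)
        assert a.localizations.equals(b.localizations)


class TestBleachTraces:
    def test_noiseless_staircase(self):
        ts = simulate_bleach_traces(1, 3, unitary_intensity=10.0,
                                    bleach_rate=1.0, noise_sd=0.0,
                                    frame_interval=0.05, seed=1)
        tr = ts.traces[0]
        assert tr[0] == 30.0
        assert (np.diff(tr) <= 0).all()
        levels = np.unique(tr)
        assert set(levels).issubset({0.0, 10.0, 20.0, 30.0})

    def test_ensemble_mean_decays_with_stated_lifetime(self):
        rate = 1 / 3.4  # Cy5-like photobleaching rate
        ts = simulate_bleach_traces(1000, 2, unitary_intensity=8.7,
                                    bleach_rate=rate, noise_sd=0.0,
                                    frame_interval=0.05, seed=2)
        mean_trace = ts.traces.mean(axis=0)
        # E[trace] = N u exp(-t/tau): fit the log over the early window
        mask = mean_trace > mean_trace[0] * 0.05
        slope = np.polyfit(ts.time[mask], np.log(mean_trace[mask]), 1)[0]
        assert abs(-1 / slope - 3.4) / 3.4 < 0.1

    def test_empty_cell_trace(self):
        ts = simulate_bleach_traces(50, 0, unitary_intensity=8.7,
                                    bleach_rate=0.3, noise_sd=1.5,
                                    frame_interval=0.05, n_frames=100, seed=3)
        assert abs(ts.traces.mean()) < 0.1
        assert abs(ts.traces.std() - 1.5) < 0.1

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            simulate_bleach_traces(1, 1, 1.0, 1.0, noise_sd=-1.0,
                                   frame_interval=0.05)


class TestSpatialPattern:
    def test_uniform_radial_mass_in_cylinder(self, geometry):
        pts = sample_spatial_pattern(geometry, 100_000, seed=8)
        # restrict to the cylindrical part; P(rho > r/2) = 1 - (1/2)^2
        cyl = np.abs(pts[:, 0]) <= geometry.half_axis
        rho = np.hypot(pts[cyl, 1], pts[cyl, 2])
        frac = (rho > geometry.radius / 2).mean()
        se = np.sqrt(0.75 * 0.25 / cyl.sum())
        assert abs(frac - 0.75) < 3 * se

    def test_zero_bias_reduces_to_uniform(self, geometry):
        a = sample_spatial_pattern(geometry, 5000, mode="uniform", seed=9)
        b = sample_spatial_pattern(geometry, 5000, mode="periphery_biased",
                                   bias=0.0, seed=10)
        rho_a = np.hypot(a[:, 1], a[:, 2])
        rho_b = np.hypot(b[:, 1], b[:, 2])
        assert stats.ks_2samp(rho_a, rho_b).pvalue > 0.01

    def test_all_points_inside(self, geometry):
        for mode, bias in (("uniform", 0.0), ("periphery_biased", 2.0)):
            pts = sample_spatial_pattern(geometry, 2000, mode=mode,
                                         bias=bias, seed=11)
            assert geometry.contains(pts).all()

    def test_unknown_mode_rejected(self, geometry):
        with pytest.raises(ConfigError):
            sample_spatial_pattern(geometry, 10, mode="ring")

    def test_bias_oracle_monotone(self):
        # periphery mass grows with the bias exponent
        fracs = [true_periphery_fraction(b) for b in (0.0, 1.0, 3.0)]
        assert fracs[0] < fracs[1] < fracs[2]
        b33 = bias_for_enrichment(33.0)
        assert 0 < b33 < 10
        got = (true_periphery_fraction(b33) / true_periphery_fraction(0.0) - 1) * 100
        assert abs(got - 33.0) < 0.5
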