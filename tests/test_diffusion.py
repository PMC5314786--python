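"""Apparent-D estimation, mixture decomposition, calibration and the cycle budget."""

import numpy as np
import pytest
from scipy import stats

from trnatrack import (ImagingConfig, TrackingConfig,
                       apparent_D, apparent_D_table, cycle_budget, fit_cdf,
                       fit_gamma_mixture, link, msd, precision_from_fixed,
                       simulate_localized_tracks)
from trnatrack.linking import Trajectory


def make_traj(xy, frames=None, traj_id=0):
    xy = np.asarray(xy, dtype=float)
    frames = np.arange(len(xy)) if frames is None else np.asarray(frames)
    return Trajectory(traj_id=traj_id, frames=frames.astype(int), xy=xy,
                      loc_index=np.arange(len(xy)),
                      gap_after=np.zeros(len(xy), dtype=bool))


class TestMSD:
    def test_immobile_noise_floor(self, rng):
        s, dt, n = 0.04, 0.005, 20_000
        xy = rng.normal(0.0, s, size=(n, 2))
        curve = msd(make_traj(xy), max_lag=4, dt=dt)
        for val, se in zip(curve.msd_um2, curve.se_um2):
            assert abs(val - 4 * s ** 2) < 3 * se

    def test_ballistic_identity(self):
        v, dt = 2.0, 0.005
        t = np.arange(50) * dt
        xy = np.column_stack([v * t, np.zeros_like(t)])
        curve = msd(make_traj(xy), max_lag=4, dt=dt)
        assert np.allclose(curve.msd_um2, (v * curve.lags_s) ** 2)

    def test_free_2d_slope(self, rng):
        D, dt, n = 2.0, 0.005, 20_000
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n, 2))
        xy = np.cumsum(steps, axis=0)
        curve = msd(make_traj(xy), max_lag=4, dt=dt)
        for lag_s, val, se in zip(curve.lags_s, curve.msd_um2, curve.se_um2):
            assert abs(val - 4 * D * lag_s) < 3 * se

    def test_max_lag_truncated_with_warning(self):
        xy = np.zeros((3, 2))
        with pytest.warns(UserWarning):
            curve = msd(make_traj(xy), max_lag=10, dt=0.005)
        assert len(curve.lags_s) == 2


class TestApparentD:
    def test_hand_arithmetic(self):
        # 4 steps of squared displacement 0.016 um^2 at dt = 5 ms -> 0.8
        step = np.sqrt(0.016)
        xy = np.cumsum(np.vstack([[0, 0]] + [[step, 0]] * 4), axis=0)
        est = apparent_D(make_traj(xy), n_steps=4, dt=0.005)
        assert est.D_app == pytest.approx(0.8)
        assert est.mobility_class == "slow"

    def test_zero_steps(self):
        est = apparent_D(make_traj(np.zeros((5, 2))), dt=0.005)
        assert est.D_app == 0.0

    def test_short_trajectory_excluded(self):
        assert apparent_D(make_traj(np.zeros((4, 2))), dt=0.005) is None

    def test_gap_steps_excluded(self):
        # frames 0,1,2,3,5: the bridged 3->5 step cannot enter the sum,
        # leaving only 3 single-frame steps -> excluded
        xy = np.zeros((5, 2))
        est = apparent_D(make_traj(xy, frames=[0, 1, 2, 3, 5]), dt=0.005)
        assert est is None

    def test_fixed_cell_mean_is_noise_floor(self, geometry, imaging):
        # immobilized emitters: mean D_app = s^2/dt = 0.32 um^2/s
        field = simulate_localized_tracks(geometry, [(0.0, 1.0)], 2.0, 500,
                                          config=imaging, n_frames=6, seed=9)
        trajs = link(field.localizations)
        tab = apparent_D_table(trajs, dt=imaging.frame_interval)
        mean = tab["D_app_um2_s"].mean()
        se = tab["D_app_um2_s"].std(ddof=1) / np.sqrt(len(tab))
        assert abs(mean - 0.32) < 3 * se
        assert (tab["class"] == "slow").mean() >= 0.90

    def test_gamma_law_of_single_species(self, rng):
        # D_app of a free species with noise ~ Gamma(4, mean D + s^2/dt)
        D, s, dt, n = 2.0, 0.04, 0.005, 10_000
        sd = np.sqrt(2 * D * dt + 2 * s ** 2)
        steps = rng.normal(0.0, sd, size=(n, 4, 2))
        d_app = (steps ** 2).sum(axis=(1, 2)) / (16 * dt)
        mean = D + s ** 2 / dt
        res = stats.kstest(d_app, "gamma", args=(4, 0, mean / 4))
        assert res.pvalue > 0.01


class TestPrecision:
    @pytest.mark.parametrize("d_fixed,dt,expected", [
        (0.32, 0.005, 0.08),
        (0.0, 0.005, 0.0),
        (1.25, 0.005, 0.15811388),
    ])
    def test_values(self, d_fixed, dt, expected):
        assert precision_from_fixed(d_fixed, dt) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            precision_from_fixed(-1.0, 0.005)

    def test_consistency_with_fixed_cell_sims(self, geometry, imaging):
        field = simulate_localized_tracks(geometry, [(0.0, 1.0)], 2.0, 400,
                                          config=imaging, n_frames=6, seed=13)
        trajs = link(field.localizations)
        tab = apparent_D_table(trajs, dt=imaging.frame_interval)
        sigma = precision_from_fixed(tab["D_app_um2_s"].mean(),
                                     imaging.frame_interval)
        assert abs(sigma - 2 * imaging.loc_error_axis) / (
            2 * imaging.loc_error_axis) < 0.05


def _gamma_sample(rng, mean, n):
    return rng.gamma(4.0, mean / 4.0, size=n)


class TestGammaMixture:
    def test_single_species_recovery(self, rng):
        x = _gamma_sample(rng, 2.0, 2000)
        fit = fit_gamma_mixture(x, m=1)
        se = 2.0 / np.sqrt(4 * 2000)  # sd of gamma(4) mean estimate
        assert abs(fit.means[0] - 2.0) < 2 * se

    def test_two_species_on_single_species_data(self, rng):
        x = _gamma_sample(rng, 2.0, 2000)
        fit = fit_gamma_mixture(x, m=2)
        assert fit.weights.max() >= 0.9 or np.allclose(
            fit.means, fit.means[0], rtol=0.1)

    def test_constrained_recovery_at_operating_point(self, rng):
        # 95% fast at 3.6 / 5% slow pinned to the ribosomal 0.5 um^2/s
        n = 4000
        lab = rng.random(n) < 0.95
        x = np.where(lab, _gamma_sample(rng, 3.6, n), _gamma_sample(rng, 0.5, n))
        fit = fit_gamma_mixture(x, m=2, constraints={0: 0.5})
        assert fit.means[0] == 0.5  # constraint held exactly
        assert abs(fit.means[1] - 3.6) < 0.2
        assert abs(fit.weights[1] - 0.95) < 0.05

    def test_constrained_recovery_median_over_seeds(self):
        errs_mean, errs_w = [], []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            lab = r.random(4000) < 0.95
            x = np.where(lab, _gamma_sample(r, 3.6, 4000),
                         _gamma_sample(r, 0.5, 4000))
            fit = fit_gamma_mixture(x, m=2, constraints={0: 0.5})
            errs_mean.append(abs(fit.means[1] - 3.6))
            errs_w.append(abs(fit.weights[1] - 0.95))
        assert np.median(errs_mean) < 0.2
        assert np.median(errs_w) < 0.05

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gamma_mixture(_gamma_sample(rng, 1.0, 30), m=1)


class TestCDFFit:
    def test_degenerate_two_species_on_one(self, rng):
        D, dt, n = 2.0, 0.005, 5000
        u = rng.exponential(4 * D * dt, size=n)
        fit = fit_cdf(u, m=2, s_axis=0.0, dt=dt)
        close = np.abs(fit.D - 2.0) < 0.2
        assert close.all() or fit.weights.min() < 0.05

    def test_weights_sum_to_one(self, rng):
        u = rng.exponential(0.05, size=1000)
        fit = fit_cdf(u, m=2, s_axis=0.02, dt=0.005)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mixture_recovery_at_paper_operating_point(self, rng):
        # slow 0.12 / fast 7.6 um^2/s at weights 0.2/0.8
        dt, s, n = 0.005, 0.0, 10_000
        lab = rng.random(n) < 0.8
        tau_fast = 4 * 7.6 * dt
        tau_slow = 4 * 0.12 * dt
        u = np.where(lab, rng.exponential(tau_fast, n),
                     rng.exponential(tau_slow, n))
        fit = fit_cdf(u, m=2, s_axis=s, dt=dt)
        assert abs(fit.D[0] - 0.12) / 0.12 < 0.15
        assert abs(fit.D[1] - 7.6) / 7.6 < 0.15

    def test_all_equal_flagged(self):
        fit = fit_cdf(np.full(500, 0.01), m=2, s_axis=0.0, dt=0.005)
        assert not fit.ok


class TestCalibration:
    def test_ideal_limit_identity(self, geometry):
        # unconfined, no localization error, no blur, generous window:
        # the apparent D is the true D
        from trnatrack import calibrate
        cfg = ImagingConfig(loc_error_axis=0.0)
        trk = TrackingConfig(max_link_distance=3.0)
        curve = calibrate([1.0, 2.0], geometry, config=cfg, tracking=trk,
                          n_cells=300, replicates=3, seed=11,
                          unconfined=True, substeps_per_frame=1)
        se = max(curve.apparent_sd[1] / np.sqrt(3), 0.02)
        assert abs(curve.apparent_mean[1] - 2.0) < 3 * se

    def test_monotone_and_inverse_identity(self, geometry, imaging, tracking):
        from trnatrack import calibrate
        grid = [0.5, 2.0, 6.0, 12.0]
        curve = calibrate(grid, geometry, config=imaging, tracking=tracking,
                          n_cells=200, replicates=2, seed=12)
        assert (np.diff(curve.apparent_mean) > 0).all()
        for true_d, app, sd in zip(curve.true_D, curve.apparent_mean,
                                   curve.apparent_sd):
            inv, err = curve.accurate(app)
            assert abs(inv - true_d) <= max(3 * err, 0.3)

    def test_nonincreasing_grid_rejected(self, geometry):
        from trnatrack import calibrate
        with pytest.raises(ValueError):
            calibrate([2.0, 1.0], geometry)


class TestCycleBudget:
    def test_pool_partition(self):
        b = cycle_budget()
        assert b.bound == 100_000
        assert b.searching == 275_000

    def test_cycle_times(self):
        b = cycle_budget()
        assert b.bound_time_s == pytest.approx(0.100)
        assert b.cycle_time_s == pytest.approx(0.400)
        assert b.search_time_s == pytest.approx(0.300)

    def test_exploration_time(self):
        b = cycle_budget()
        assert b.exploration_time_s == pytest.approx(0.0625)
        assert b.exploration_time_s <= 0.070

    def test_zero_D_rejected(self):
        with pytest.raises(ValueError):
            cycle_budget(D=0.0)

    def test_pool_invariants(self):
        b = cycle_budget()
        assert b.bound + b.searching == b.pool
        assert b.cycle_time_s == pytest.approx(
            b.bound_time_s / b.bound_fraction_rounded)
        assert b.bound_fraction == pytest.approx(100_000 / 375_000)
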