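import numpy as np
import pytest

from pbcunwrap.core import BoxSeries, UnwrappedTrajectory
from pbcunwrap.diffusion import (
    MSDCurve,
    block_analysis,
    compressibility,
    cve_fit,
    cve_fit_array,
    msd,
    msd_array,
    ols_fit,
    pair_diffusion,
)
from pbcunwrap.sampling_bounds import KB


def walk_traj(rng, n_frames, n_particles, step_std, dt=1.0, noise_std=0.0, d=1):
    """Constant-box Gaussian walks, optionally observed with static noise."""
    steps = step_std * rng.standard_normal((n_frames - 1, n_particles, d))
    u = np.concatenate([np.zeros((1, n_particles, d)), np.cumsum(steps, axis=0)])
    if noise_std:
        u = u + noise_std * rng.standard_normal(u.shape)
    box = BoxSeries(np.full((n_frames, d), 1e6), dt=dt)
    return UnwrappedTrajectory(u, box, scheme_tag="tor")


class TestMSD:
    def test_matches_brute_force_double_loop(self, rng):
        u = np.cumsum(rng.standard_normal((200, 3, 2)), axis=0)
        curve = msd_array(u, dt=0.5, max_lag_index=30)
        for m in range(31):
            total = 0.0
            count = 0
            for i in range(200 - m):
                for p in range(3):
                    total += np.sum((u[i + m, p] - u[i, p]) ** 2)
                    count += 1
            expected = total / count if m else 0.0
            assert curve.values[m] == pytest.approx(expected, abs=1e-12)
        assert np.array_equal(curve.n_pairs, 200 - np.arange(31))

    def test_ballistic_line(self):
        c = 0.3
        u = c * np.arange(50)
        curve = msd_array(u, dt=1.0, max_lag_index=10)
        assert np.allclose(curve.values, (c * np.arange(11)) ** 2)

    def test_constant_trajectory_is_zero(self):
        curve = msd_array(np.full(40, 1.7), dt=1.0, max_lag_index=5)
        assert np.allclose(curve.values, 0.0)

    def test_rejects_wrapped_input(self, rng):
        traj = walk_traj(rng, 50, 1, 0.1)
        traj.scheme_tag = "native-wrapped"
        with pytest.raises(ValueError, match="unwrapped"):
            msd(traj, 5)

    def test_lag_bounds_enforced(self, rng):
        with pytest.raises(ValueError, match="max_lag_index"):
            msd_array(rng.standard_normal(10), dt=1.0, max_lag_index=10)


class TestOLSFit:
    def test_exact_line_recovered(self):
        d, D, a2 = 3, 1.0, 0.5
        tau = np.arange(21, dtype=float)
        curve = MSDCurve(lags=tau, values=2 * d * D * tau + a2,
                         n_pairs=100 - np.arange(21), dimension=d)
        fit = ols_fit(curve, 1, 20)
        assert fit.D == pytest.approx(D, abs=1e-12)
        assert fit.a2 == pytest.approx(a2, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)

    def test_negative_intercept_reported_unclipped(self):
        tau = np.arange(6, dtype=float)
        curve = MSDCurve(lags=tau, values=2 * tau - 0.3, n_pairs=10 - np.arange(6),
                         dimension=1)
        assert ols_fit(curve, 0, 5).a2 == pytest.approx(-0.3)

    def test_single_point_window_rejected(self):
        tau = np.arange(6, dtype=float)
        curve = MSDCurve(lags=tau, values=tau, n_pairs=np.ones(6), dimension=1)
        with pytest.raises(ValueError, match="two lag values"):
            ols_fit(curve, 3, 3)

    def test_recovers_known_diffusion_coefficient(self, rng):
        """Ensemble-mean OLS estimate agrees with D = step_var / (2 dt)."""
        step = 0.1
        D_true = step**2 / 2
        fits = []
        for p in range(80):
            traj = walk_traj(rng, 1500, 1, step)
            fits.append(ols_fit(msd(traj, 20), 1, 20).D)
        fits = np.array(fits)
        se = fits.std(ddof=1) / np.sqrt(len(fits))
        assert abs(fits.mean() - D_true) <= 3 * se


class TestCVE:
    def test_pure_walk_recovery(self, rng):
        step, n, P = 0.2, 4000, 100
        D_true = step**2 / 2
        traj = walk_traj(rng, n, P, step)
        fit = cve_fit(traj)
        assert abs(fit.D - D_true) <= 3 * fit.stderr

    def test_static_noise_recovery(self, rng):
        """CVE separates D from injected localization noise."""
        step, s_loc, n, P = 0.2, 0.3, 4000, 100
        D_true = step**2 / 2
        traj = walk_traj(rng, n, P, step, noise_std=s_loc)
        fit = cve_fit(traj)
        assert abs(fit.D - D_true) <= 3 * fit.stderr
        # intercept convention: a^2 = 2 d sigma_loc^2
        per_particle = [
            cve_fit_array(traj.positions[:, p : p + 1, :], 1.0).a2 for p in range(P)
        ]
        se_a2 = np.std(per_particle, ddof=1) / np.sqrt(P)
        assert abs(fit.a2 - 2 * s_loc**2) <= 3 * se_a2

    def test_constant_series(self):
        fit = cve_fit_array(np.full(100, 2.0), dt=1.0)
        assert fit.D == 0.0
        assert fit.a2 == 0.0

    def test_needs_three_frames(self):
        with pytest.raises(ValueError, match="3 frames"):
            cve_fit_array(np.zeros(2), dt=1.0)

    def test_ols_and_cve_agree_on_constant_box_walks(self, rng):
        traj = walk_traj(rng, 3000, 50, 0.1)
        cve = cve_fit(traj)
        fits = np.array([
            ols_fit(msd_array(traj.positions[:, p : p + 1, :], 1.0, 20), 1, 20).D
            for p in range(50)
        ])
        se = fits.std(ddof=1) / np.sqrt(50)
        assert abs(fits.mean() - cve.D) <= 3 * np.hypot(se, cve.stderr)


class TestBlockAnalysis:
    def test_identical_blocks_give_identical_fits(self, rng):
        block = np.cumsum(rng.standard_normal(50))
        u = np.concatenate([block, block])  # two copies
        traj = UnwrappedTrajectory(u[:, None, None], BoxSeries(np.full((100, 1), 10.0)))
        series = block_analysis(traj, 50.0, estimator="cve")
        assert series.fits[0].D == series.fits[1].D

    def test_stationary_walk_shows_no_trend(self, rng):
        traj = walk_traj(rng, 2000, 20, 0.1)
        series = block_analysis(traj, 200.0, estimator="cve", seed=3)
        assert series.p_value > 0.01

    def test_partial_block_dropped(self, rng):
        traj = walk_traj(rng, 110, 2, 0.1)
        series = block_analysis(traj, 50.0, estimator="cve")
        assert len(series.fits) == 2
        assert series.n_dropped_frames == 10

    def test_too_few_blocks_rejected(self, rng):
        with pytest.raises(ValueError, match="2 whole blocks"):
            block_analysis(walk_traj(rng, 60, 1, 0.1), 50.0)


class TestPairDiffusion:
    def test_additivity_for_independent_walks(self, rng):
        x = walk_traj(rng, 3000, 80, 0.1)
        y = walk_traj(rng, 3000, 80, 0.2)
        res = pair_diffusion(x, y, estimator="cve")
        assert abs(res.gap) <= 3 * res.gap_stderr
        assert res.D_pair == pytest.approx(res.D_x + res.D_y, abs=3 * res.gap_stderr)

    def test_identical_processes_have_zero_pair_diffusion(self, rng):
        x = walk_traj(rng, 500, 5, 0.1)
        res = pair_diffusion(x, x, estimator="cve")
        assert res.D_pair == 0.0
        assert res.gap == pytest.approx(-(res.D_x + res.D_y))

    def test_frame_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="share frame count"):
            pair_diffusion(walk_traj(rng, 100, 1, 0.1), walk_traj(rng, 99, 1, 0.1))


class TestCompressibility:
    def test_constant_volume_is_zero(self):
        assert compressibility(np.full(10, 8.0), 300.0) == 0.0

    def test_two_sample_closed_form(self):
        v1, v2, T = 7.9, 8.1, 300.0
        # unbiased two-sample variance is (v1 - v2)^2 / 2
        expected = ((v1 - v2) ** 2 / 2) / (KB * T * (v1 + v2) / 2)
        assert compressibility([v1, v2], T) == pytest.approx(expected, rel=1e-12)

    def test_gaussian_volumes_match_plug_in(self, rng):
        mu, sd, T, n = 100.0, 1.5, 300.0, 200_000
        v = rng.normal(mu, sd, size=n)
        chi = compressibility(v, T)
        expected = sd**2 / (KB * T * mu)
        # plug-in value within 3 standard errors of the variance estimate
        se = expected * np.sqrt(2.0 / (n - 1))
        assert abs(chi - expected) <= 3 * se

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compressibility([1.0, -1.0], 300.0)
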