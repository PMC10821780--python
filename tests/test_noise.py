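"""Noise models: analytic correlation noise, Gaussian ensembles, speckle
contrast terms, the dynamic speckle simulator, photon timestamps and the
multi-tau correlator."""

import math

import numpy as np
import pytest

from speckleflow.forward import CorrelationCurve, multitau_grid, speckle_contrast_from_g1
from speckleflow.noise import (
    DcsNoiseParams,
    dcs_noise_sigma,
    gaussian_noise_realizations,
    measured_contrast_stats,
    multitau_autocorrelation,
    photon_timestamps,
    shot_read_dark_contrast,
    speckle_field_sequence,
)


class TestDcsNoiseSigma:
    def params(self, **kw):
        base = dict(bin_width_T=1e-6, averaging_time_t=0.1, beta=0.5,
                    gamma=5e3, counts_per_bin_n=0.01)
        base.update(kw)
        return DcsNoiseParams(**base)

    def test_quadrupled_averaging_halves_sigma(self):
        tau = np.array([1e-6, 1e-5, 1e-4])
        s1 = dcs_noise_sigma(self.params(), tau)
        s4 = dcs_noise_sigma(self.params(averaging_time_t=0.4), tau)
        np.testing.assert_allclose(s1 / s4, 2.0, rtol=1e-12)

    def test_high_count_limit_keeps_only_speckle_term(self):
        tau = np.array([1e-6, 1e-4])
        p_inf = self.params(counts_per_bin_n=1e12)
        sig = dcs_noise_sigma(p_inf, tau)
        T, t, beta, g = 1e-6, 0.1, 0.5, 5e3
        e2gt = math.exp(-2 * g * T)
        first = (beta**2 * ((1 + e2gt) * (1 + np.exp(-2 * g * tau))
                            + 2 * (tau / T) * (1 - e2gt) * np.exp(-2 * g * tau))
                 / (1 - e2gt))
        np.testing.assert_allclose(sig**2 * (t / T), first, rtol=1e-6)

    def test_nonincreasing_in_tau(self):
        tau = np.logspace(-6, -2, 60)
        sig = dcs_noise_sigma(self.params(), tau)
        assert np.all(np.diff(sig) <= 1e-15)

    def test_rejects_degenerate_bin(self):
        with pytest.raises(ValueError):
            DcsNoiseParams(0.0, 0.1, 0.5, 5e3, 0.01)


class TestGaussianRealizations:
    def curve(self):
        tau = multitau_grid(tau_max=1e-3)
        return CorrelationCurve(tau, 1 + 0.5 * np.exp(-2e4 * tau),
                                kind="intensity_g2", beta=0.5)

    def test_zero_sigma_returns_input(self):
        c = self.curve()
        out = gaussian_noise_realizations(c, np.zeros_like(c.tau), 5, seed=1)
        np.testing.assert_array_equal(out, np.tile(c.values, (5, 1)))

    def test_sample_mean_recovers_curve(self):
        c = self.curve()
        sigma = np.full_like(c.tau, 0.05)
        out = gaussian_noise_realizations(c, sigma, 10_000, seed=2)
        se = 0.05 / math.sqrt(10_000)
        assert np.all(np.abs(out.mean(axis=0) - c.values) < 4 * se)

    def test_seed_determinism(self):
        c = self.curve()
        sigma = np.full_like(c.tau, 0.1)
        a = gaussian_noise_realizations(c, sigma, 7, seed=3)
        b = gaussian_noise_realizations(c, sigma, 7, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_grid_mismatch_rejected(self):
        c = self.curve()
        with pytest.raises(ValueError):
            gaussian_noise_realizations(c, np.ones(3), 5, seed=1)


class TestShotReadDark:
    def test_printed_example(self):
        ks2, kr2, kd2 = shot_read_dark_contrast(100.0, 2.5, 0.0)
        assert ks2 == pytest.approx(0.01)
        assert kr2 == pytest.approx(6.25e-4)
        assert kd2 == 0.0

    def test_shot_scaling_identity(self):
        for pe in (1.0, 37.0, 1e6):
            ks2, _, _ = shot_read_dark_contrast(pe)
            assert ks2 * pe == pytest.approx(1.0)

    def test_flat_frame_variance_oracle(self):
        """A Poisson+read flat frame reproduces Ks^2 + Kr^2."""
        rng = np.random.default_rng(11)
        pe, read = 200.0, 3.0
        frame = rng.poisson(pe, 300_000) + read * rng.standard_normal(300_000)
        k2 = frame.var(ddof=1) / frame.mean() ** 2
        ks2, kr2, _ = shot_read_dark_contrast(pe, read)
        assert k2 == pytest.approx(ks2 + kr2, rel=0.02)

    def test_rejects_nonpositive_signal(self):
        with pytest.raises(ValueError):
            shot_read_dark_contrast(0.0)


class TestSpeckleSimulator:
    def test_static_polarized_contrast_approaches_unity(self):
        """Fully developed static polarized speckle has unit contrast once
        pixels are much smaller than a speckle (Gaussian-correlation model:
        beta ~ 1/(1 + 2 (p/s)^2), so s/p = 8 sits within 3% of 1)."""
        stack = speckle_field_sequence(None, 8.0, grid_size=64, substeps=1,
                                       seed=4, n_exposures=200, polarized=True)
        stats = measured_contrast_stats(stack, 1e9, seed=5)
        assert stats.beta_est == pytest.approx(1.0, abs=0.05)

    def test_contrast_grows_with_speckle_to_pixel_ratio(self):
        betas = []
        for sp in (0.4, 1.0, 2.0, 8.0):
            stack = speckle_field_sequence(None, sp, grid_size=32, substeps=1,
                                           seed=4, n_exposures=80, polarized=True)
            betas.append(measured_contrast_stats(stack, 1e9, seed=5).beta_est)
        assert np.all(np.diff(betas) > 0)

    def test_field_correlation_tracks_target(self):
        """Lag correlation of substep fields matches the requested g1."""
        gamma_f = 1e3
        stack = speckle_field_sequence(gamma_f, 2.0, grid_size=24, substeps=24,
                                       seed=6, n_exposures=40, t_exp=4e-3,
                                       polarized=True)
        inten = stack.intensities  # (exp, sub, ny, nx)
        dt = stack.dt
        flat = inten.reshape(inten.shape[0], inten.shape[1], -1)
        for lag in (1, 4, 8):
            a = flat[:, :-lag].ravel()
            b = flat[:, lag:].ravel()
            g2m1 = np.mean(a * b) / (a.mean() * b.mean()) - 1.0
            g1_emp = math.sqrt(max(g2m1, 0.0) / stack_beta(stack))
            target = math.exp(-gamma_f * lag * dt)
            if target > 0.1:
                assert abs(g1_emp - target) < 0.02

    def test_seed_determinism(self):
        kw = dict(s_over_p=1.0, grid_size=16, substeps=8, n_exposures=8, t_exp=1e-3)
        a = speckle_field_sequence(2e3, seed=9, **kw)
        b = speckle_field_sequence(2e3, seed=9, **kw)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    @pytest.mark.parametrize("x, substeps, grid", [
        (0.1, 16, 32), (2.0, 16, 32), (20.0, 96, 32), (100.0, 400, 16),
    ])
    def test_exposure_integral_matches_contrast_model(self, x, substeps, grid):
        """Simulated mean Kf^2 follows the exposure-weighted g1^2 integral
        within 5% from 0.1 to 100 field decorrelation times (substeps obey
        the >= 4 per decorrelation time resolution requirement)."""
        gamma_f = 1e3
        t_exp = x / gamma_f
        stack = speckle_field_sequence(gamma_f, 1.0, grid_size=grid,
                                       substeps=substeps, seed=10,
                                       n_exposures=64, t_exp=t_exp)
        stats = measured_contrast_stats(stack, 1e7, seed=11)
        model = speckle_contrast_from_g1(
            lambda t: np.exp(-gamma_f * np.asarray(t)), stats.beta_est, t_exp)
        assert stats.kf2_mean == pytest.approx(model, rel=0.05)

    def test_independent_observations_saturate_at_small_speckle(self):
        """At s/p = 0.4 the effective number of independent observations
        approaches the pixel count (calibration point 0.95 n_pixels)."""
        stack = speckle_field_sequence(None, 0.4, grid_size=32, substeps=1,
                                       seed=12, n_exposures=400)
        stats = measured_contrast_stats(stack, 1e9, seed=13)
        npix = 32 * 32
        assert stats.nio_est == pytest.approx(0.95 * npix, rel=0.10)

    def test_requires_enough_exposures(self):
        stack = speckle_field_sequence(None, 1.0, grid_size=16, substeps=1,
                                       seed=1, n_exposures=10)
        with pytest.raises(ValueError):
            measured_contrast_stats(stack, 100.0, seed=1)


def stack_beta(stack):
    first = stack.intensities[:, 0].reshape(stack.n_exposures, -1)
    return float(np.mean(first.var(axis=1, ddof=1) / first.mean(axis=1) ** 2))


class TestPhotonTimestamps:
    def test_homogeneous_poisson_count_and_flat_correlogram(self):
        ts = photon_timestamps(1e6, None, duration=1.0, seed=21)
        n = ts.n_events
        assert abs(n - 1e6) < 4 * math.sqrt(1e6)
        g2, nbar = multitau_autocorrelation(ts, tau_max=1e-3)
        assert nbar == pytest.approx(1.0, rel=0.01)
        assert np.max(np.abs(g2.values - 1.0)) < 5.0 / math.sqrt(n)

    def test_hold_off_enforces_minimum_gap_and_rate_cap(self):
        ts = photon_timestamps(2e8, None, duration=0.01, hold_off=22e-9, seed=22)
        gaps = np.diff(ts.event_times)
        assert gaps.min() >= 22e-9
        assert ts.rate <= 4.5e7 * 1.01

    def test_speckle_driven_stream_recovers_siegert_intercept(self):
        gamma = 5e3  # intensity decay; field decays at gamma/2
        ts = photon_timestamps(2e6, gamma / 2, beta=0.5, duration=1.0,
                               seed=23, dt=1e-6)
        g2, _ = multitau_autocorrelation(ts, tau_max=2e-3)
        early = g2.values[g2.tau <= 3e-6]
        # finite bin width and sampling error soften the intercept slightly
        assert early.mean() == pytest.approx(1.5, abs=0.03)

    def test_dark_counts_dilute_the_intercept(self):
        kw = dict(beta=0.5, duration=1.0, seed=24, dt=2e-6)
        clean = photon_timestamps(5e5, 2.5e3, dark_rate=0.0, **kw)
        dark = photon_timestamps(5e5, 2.5e3, dark_rate=5e5, **kw)
        g2c, _ = multitau_autocorrelation(clean, tau_max=1e-3)
        g2d, _ = multitau_autocorrelation(dark, tau_max=1e-3)
        beta_c = g2c.values[g2c.tau <= 5e-6].mean() - 1
        beta_d = g2d.values[g2d.tau <= 5e-6].mean() - 1
        # half the flux is uncorrelated -> intercept falls by ~(1/2)^2
        assert beta_d / beta_c == pytest.approx(0.25, abs=0.07)

    def test_rejects_negative_hold_off(self):
        with pytest.raises(ValueError):
            photon_timestamps(1e4, None, hold_off=-1e-9, duration=0.1, seed=0)


class TestMultitauCorrelator:
    def test_matches_brute_force_pair_counting(self):
        """First-octave lags agree with a direct O(N^2) binned-pair count."""
        rng = np.random.default_rng(31)
        times = np.sort(rng.uniform(0, 0.01, 10_000))
        from speckleflow.noise import TimestampSeries

        series = TimestampSeries(times, duration=0.01)
        T = 1e-6
        g2, _ = multitau_autocorrelation(series, first_bin=T)

        bins = (times / T).astype(np.int64)
        n_bins = int(0.01 / T)
        counts = np.bincount(np.minimum(bins, n_bins - 1), minlength=n_bins)
        for k in range(1, 9):
            pairs = np.sum(counts[: n_bins - k] * counts[k:])
            ml = counts[: n_bins - k].mean()
            mr = counts[k:].mean()
            direct = pairs / (n_bins - k) / (ml * mr)
            idx = np.argmin(np.abs(g2.tau - k * T))
            assert g2.values[idx] == pytest.approx(direct, rel=1e-9)

    def test_mode_addition_halves_beta(self):
        """Superposing two independent speckle streams of equal rate keeps
        the decay shape and halves the intercept."""
        gamma_f = 2.5e3
        one = photon_timestamps(1e6, gamma_f, beta=1.0, duration=1.0, seed=41, dt=2e-6)
        two = photon_timestamps(1e6, gamma_f, beta=0.5, duration=1.0, seed=42, dt=2e-6)
        g2_one, _ = multitau_autocorrelation(one, tau_max=2e-3)
        g2_two, _ = multitau_autocorrelation(two, tau_max=2e-3)
        b1 = g2_one.values[g2_one.tau <= 5e-6].mean() - 1
        b2 = g2_two.values[g2_two.tau <= 5e-6].mean() - 1
        assert b2 / b1 == pytest.approx(0.5, abs=0.06)

    def test_insufficient_events_rejected(self):
        from speckleflow.noise import TimestampSeries

        series = TimestampSeries(np.linspace(0, 0.009, 50), duration=0.01)
        with pytest.raises(ValueError):
            multitau_autocorrelation(series)
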