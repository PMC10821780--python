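"""BFi inversion: decay-rate estimation, fit-range control,
forward-inverse identities and noise propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speckleflow.fitting import (
    DcsBfiModel,
    FitSettings,
    ScosBfiModel,
    estimate_decay_rate,
    fit_bfi_from_contrast,
    fit_bfi_from_g2,
    fit_ensemble_contrast,
    fit_ensemble_g2,
    fit_range_cutoff,
)
from speckleflow.forward import (
    CorrelationCurve,
    SemiInfiniteGeometry,
    multitau_grid,
    semi_infinite_g1,
    siegert_g2,
)

SETTINGS_850 = FitSettings.for_wavelength(850, beta=0.5)
TAU = multitau_grid(tau_max=1e-2)


def make_g2(bfi, sds_mm=25.0, beta=0.5, settings=SETTINGS_850, tau=TAU):
    geo = SemiInfiniteGeometry.from_measurement(sds_mm, settings.optics,
                                                settings.wavelength_nm)
    return siegert_g2(semi_infinite_g1(geo, settings.optics, bfi, tau), beta)


class TestDecayRate:
    def test_exact_single_exponential(self):
        tau = TAU[1:]
        g2 = CorrelationCurve(tau, 1 + 0.5 * np.exp(-1e4 * tau),
                              kind="intensity_g2", beta=0.5)
        assert estimate_decay_rate(g2) == pytest.approx(1e4, rel=1e-3)

    def test_unbiased_under_zero_mean_noise(self):
        tau = TAU[1:]
        clean = 1 + 0.5 * np.exp(-1e4 * tau)
        rng = np.random.default_rng(5)
        gammas = []
        for _ in range(100):
            noisy = clean + 0.01 * rng.standard_normal(tau.size)
            g2 = CorrelationCurve(tau, noisy, kind="intensity_g2", beta=0.5)
            gammas.append(estimate_decay_rate(g2))
        assert np.mean(gammas) == pytest.approx(1e4, rel=0.02)

    def test_near_linear_in_bfi(self):
        g_lo = estimate_decay_rate(make_g2(3e-8))
        g_hi = estimate_decay_rate(make_g2(6e-8))
        assert g_hi / g_lo == pytest.approx(2.0, rel=0.10)

    def test_flat_curve_rejected(self):
        tau = TAU[1:]
        g2 = CorrelationCurve(tau, np.full(tau.size, 1.001),
                              kind="intensity_g2", beta=0.5)
        with pytest.raises(ValueError):
            estimate_decay_rate(g2)


class TestFitRangeCutoff:
    def single_exp(self, gamma=1e4):
        tau = TAU[1:]
        return CorrelationCurve(tau, 1 + 0.5 * np.exp(-gamma * tau),
                                kind="intensity_g2", beta=0.5)

    def test_full_fraction_keeps_whole_grid(self):
        g2 = self.single_exp()
        assert fit_range_cutoff(g2, 1.0) == g2.tau[-1]

    def test_half_decay_of_single_exponential(self):
        g2 = self.single_exp(1e4)
        cutoff = fit_range_cutoff(g2, 0.5)
        # nearest grid delay above ln(2)/Gamma
        target = math.log(2) / 1e4
        grid_above = g2.tau[g2.tau >= target][0]
        assert cutoff == pytest.approx(grid_above, rel=0.15)

    def test_monotone_in_fraction(self):
        g2 = self.single_exp()
        cuts = [fit_range_cutoff(g2, f) for f in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert np.all(np.diff(cuts) >= 0)

    def test_rejects_nonpositive_fraction(self):
        with pytest.raises(ValueError):
            fit_range_cutoff(self.single_exp(), 0.0)


class TestDcsInversion:
    def test_noiseless_self_consistency(self):
        g2 = make_g2(6e-8)
        res = fit_bfi_from_g2(g2, SETTINGS_850, 25.0)
        assert res.converged
        assert res.bfi == pytest.approx(6e-8, rel=1e-3)

    def test_mc_histories_fit_recovers_ground_truth(self, homogeneous_mc):
        """Homogeneous-slab transport fitted with the analytic model and
        matched optics recovers the true flow within 5% at 25 mm."""
        from speckleflow.forward import FlowState, g1_from_histories

        res, optics = homogeneous_mc
        truth = 6e-8
        g1 = g1_from_histories(res.histories, optics,
                               FlowState({"scalp": truth}), TAU, detector_id=2)
        g2 = siegert_g2(g1, 0.5)
        settings = FitSettings(optics=optics["scalp"], wavelength_nm=850.0, beta=0.5)
        fit = fit_bfi_from_g2(g2, settings, 25.0)
        assert fit.bfi == pytest.approx(truth, rel=0.05)

    def test_ensemble_mean_unbiased_at_high_counts(self):
        from speckleflow.noise import (DcsNoiseParams, dcs_noise_sigma,
                                       gaussian_noise_realizations)

        g2 = make_g2(6e-8)
        gamma = estimate_decay_rate(g2)
        params = DcsNoiseParams(1e-6, 0.1, 0.5, gamma, 5.0)  # <n> >> beta
        sigma = dcs_noise_sigma(params, TAU)
        noisy = gaussian_noise_realizations(g2, sigma, 100, seed=8)
        ens = fit_ensemble_g2(TAU, noisy, SETTINGS_850, 25.0)
        assert ens.valid
        assert ens.mean == pytest.approx(6e-8, rel=0.02)


class TestScosInversion:
    def test_noiseless_self_consistency(self):
        model = ScosBfiModel([(1e-3, 0.1)], SETTINGS_850, 25.0)
        kf2 = model.predict(6e-8)[0]
        res = fit_bfi_from_contrast([(1e-3, kf2)], SETTINGS_850, 25.0)
        assert res.converged
        assert res.bfi == pytest.approx(6e-8, rel=1e-3)

    def test_contrast_shift_moves_bfi_oppositely(self):
        model = ScosBfiModel([(1e-3, 0.1)], SETTINGS_850, 25.0)
        kf2 = model.predict(6e-8)[0]
        up = fit_bfi_from_contrast([(1e-3, kf2 * 1.05)], SETTINGS_850, 25.0)
        down = fit_bfi_from_contrast([(1e-3, kf2 * 0.95)], SETTINGS_850, 25.0)
        assert up.bfi < 6e-8 < down.bfi

    def test_forward_map_strictly_decreasing_in_bfi(self):
        model = ScosBfiModel([(1e-3, 0.1)], SETTINGS_850, 25.0)
        bfis = np.logspace(-9, -6, 12)
        kf2 = [model.predict(b)[0] for b in bfis]
        assert np.all(np.diff(kf2) < 0)

    def test_out_of_range_contrast_rejected(self):
        with pytest.raises(ValueError):
            ScosBfiModel([(1e-3, 0.6)], SETTINGS_850, 25.0)  # kf2 >= beta

    def test_ensemble_cov_matches_delta_method(self):
        """CoV of fitted BFi under Gaussian contrast noise agrees with
        first-order error propagation |dBFi/dKf2| sigma / BFi."""
        truth, t_exp, sds = 6e-8, 1e-3, 25.0
        model = ScosBfiModel([(t_exp, 0.1)], SETTINGS_850, sds)
        kf2 = model.predict(truth)[0]
        sigma = 0.01 * kf2
        rng = np.random.default_rng(17)
        ens = fit_ensemble_contrast(t_exp, kf2 + sigma * rng.standard_normal(100),
                                    SETTINGS_850, sds)
        h = 1e-3 * truth
        dk = (model.predict(truth + h)[0] - model.predict(truth - h)[0]) / (2 * h)
        predicted_cov = abs(sigma / dk) / truth
        assert ens.std / ens.mean == pytest.approx(predicted_cov, rel=0.25)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(log_bfi=st.floats(-9, -6), sds=st.floats(5.0, 40.0))
def test_dcs_forward_inverse_identity(log_bfi, sds):
    """fit(forward(BFi)) recovers BFi to 0.1% across flow and separation."""
    bfi = 10.0**log_bfi
    g2 = make_g2(bfi, sds_mm=sds)
    res = fit_bfi_from_g2(g2, SETTINGS_850, sds)
    assert res.bfi == pytest.approx(bfi, rel=1e-3)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(log_bfi=st.floats(-9, -6), log_texp=st.floats(-5, math.log10(2e-2)),
       sds=st.floats(5.0, 40.0))
def test_scos_forward_inverse_identity(log_bfi, log_texp, sds):
    bfi, t_exp = 10.0**log_bfi, 10.0**log_texp
    model = ScosBfiModel([(t_exp, 0.1)], SETTINGS_850, sds)
    kf2 = model.predict(bfi)[0]
    if not 1e-12 < kf2 < 0.5 - 1e-12:
        return  # fully decorrelated: contrast carries no flow information
    res = fit_bfi_from_contrast([(t_exp, kf2)], SETTINGS_850, sds)
    assert res.bfi == pytest.approx(bfi, rel=1e-3)
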