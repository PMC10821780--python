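"""Forward-model unit and property tests: boundary coefficient,
semi-infinite field correlation, Siegert relation, history-based g1 and
fundamental speckle contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speckleflow.forward import (
    CorrelationCurve,
    FlowState,
    OpticalProperties,
    SemiInfiniteGeometry,
    effective_reflection_coefficient,
    g1_from_histories,
    multitau_bin_widths,
    multitau_grid,
    semi_infinite_g1,
    siegert_g2,
    speckle_contrast_from_g1,
)
from speckleflow.montecarlo import parametric_histories

OPT_850 = OpticalProperties(0.15, 8.5, 1.4)


class TestEffectiveReflection:
    @pytest.mark.parametrize("n, expected", [(1.0, 0.0016), (1.4, 0.5295)])
    def test_polynomial_values(self, n, expected):
        assert effective_reflection_coefficient(n) == pytest.approx(expected, abs=5e-5)

    def test_monotone_on_physiological_range(self):
        n = np.linspace(1.0, 1.6, 200)
        r = np.array([effective_reflection_coefficient(x) for x in n])
        assert np.all(np.diff(r) > 0)

    def test_rejects_unphysical_index(self):
        with pytest.raises(ValueError):
            effective_reflection_coefficient(0.9)


class TestSemiInfiniteG1:
    def geometry(self, sds_mm=25.0):
        return SemiInfiniteGeometry.from_measurement(sds_mm, OPT_850, 850.0)

    def test_geometry_invariants(self):
        g = self.geometry()
        assert g.r1 == pytest.approx(np.hypot(g.rho, g.l_star))
        assert g.r_b > g.r1 >= g.rho
        assert 0 < g.r_eff < 1

    def test_unity_at_zero_delay(self):
        tau = np.array([0.0, 1e-6, 1e-3])
        curve = semi_infinite_g1(self.geometry(), OPT_850, 6e-8, tau)
        assert curve.values[0] == 1.0

    def test_decays_to_zero_for_fast_flow(self):
        tau = np.array([1e-3])
        curve = semi_infinite_g1(self.geometry(), OPT_850, 1e-2, tau)
        assert curve.values[0] < 1e-12

    def test_against_independent_high_precision_evaluation(self):
        # frozen 50-digit arbitrary-precision transcription of the
        # semi-infinite solution at rho=2.5 cm, mu_a=0.15, mu_s'=8.5,
        # n=1.4, 850 nm, BFi=6e-8 cm^2/s, tau=1e-5 s
        curve = semi_infinite_g1(self.geometry(), OPT_850, 6e-8, np.array([1e-5]))
        assert curve.values[0] == pytest.approx(0.26455767298902090804, abs=1e-10)

    def test_pointwise_decrease_under_faster_flow(self):
        tau = multitau_grid(tau_max=1e-2)[1:]
        lo = semi_infinite_g1(self.geometry(), OPT_850, 6e-8, tau).values
        hi = semi_infinite_g1(self.geometry(), OPT_850, 7.2e-8, tau).values
        assert np.all(hi < lo)

    def test_rejects_nonfinite_input(self):
        with pytest.raises(ValueError):
            semi_infinite_g1(self.geometry(), OPT_850, np.nan, np.array([1e-5]))


class TestSiegert:
    def test_intercept_and_decayed_limit(self):
        tau = np.array([0.0, 1.0])
        g1 = CorrelationCurve(tau, np.array([1.0, 0.0]))
        g2 = siegert_g2(g1, 0.5)
        assert g2.values[0] == pytest.approx(1.5)
        assert g2.values[1] == pytest.approx(1.0)
        assert g2.beta == 0.5

    def test_single_exponential_maps_to_doubled_decay(self):
        tau = np.linspace(0, 1e-3, 50)
        gamma_f = 4e3
        g1 = CorrelationCurve(tau, np.exp(-gamma_f * tau))
        g2 = siegert_g2(g1, 0.4)
        np.testing.assert_allclose(g2.values - 1.0, 0.4 * np.exp(-2 * gamma_f * tau),
                                   rtol=1e-12)

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.5])
    def test_rejects_invalid_beta(self, beta):
        g1 = CorrelationCurve(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            siegert_g2(g1, beta)


class TestG1FromHistories:
    def test_normalized_at_zero_delay_and_degenerate_closed_form(self):
        # identical Y and L for every photon: single exponential,
        # independent of absorption (the weight cancels)
        table = parametric_histories(
            {"brain": {"L": ("constant", 10.0), "Y": ("constant", 50.0)}},
            n_rows=64, seed=1,
        )
        optics = {"brain": OpticalProperties(0.17, 11.6, 1.4)}
        flow = FlowState({"brain": 6e-8})
        tau = np.array([0.0, 1e-6, 1e-5, 1e-4])
        curve = g1_from_histories(table, optics, flow, tau)
        k = 2 * np.pi * 1.4 / 850e-7
        expected = np.exp(-2.0 * k**2 * 50.0 * 6e-8 * tau)
        assert curve.values[0] == 1.0
        np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

        heavier = {"brain": OpticalProperties(1.7, 11.6, 1.4)}
        curve2 = g1_from_histories(table, heavier, flow, tau)
        np.testing.assert_allclose(curve2.values, curve.values, rtol=1e-12)

    def test_label_mismatch_raises(self):
        table = parametric_histories(
            {"brain": {"L": ("constant", 10.0), "Y": ("constant", 50.0)}},
            n_rows=8, seed=1,
        )
        with pytest.raises(KeyError):
            g1_from_histories(table, {"scalp": OPT_850}, FlowState({"scalp": 1e-8}),
                              np.array([0.0, 1e-5]))

    def test_exponential_pathlengths_match_quadrature_oracle(self):
        # single tissue, L ~ Exp(mean), Y = L mu_s': g1 is the Laplace
        # transform of the weighted pathlength density, computed here by
        # numerical quadrature
        from scipy.integrate import quad

        mean_l, mu_sp, mu_a, bfi = 12.0, 8.5, 0.15, 6e-8
        table = parametric_histories(
            {"t": {"L": ("exponential", mean_l), "Y": ("scaled_L", mu_sp)}},
            n_rows=200_000, seed=3,
        )
        optics = {"t": OpticalProperties(mu_a, mu_sp, 1.4)}
        tau = np.array([0.0, 1e-6, 3e-6, 1e-5, 3e-5])
        curve = g1_from_histories(table, optics, FlowState({"t": bfi}), tau)
        k = 2 * np.pi * 1.4 / 850e-7
        expected = []
        for t in tau:
            a = 2.0 * k**2 * bfi * mu_sp * t
            num = quad(lambda s: np.exp(-s / mean_l - (mu_a + a) * s), 0, np.inf)[0]
            den = quad(lambda s: np.exp(-s / mean_l - mu_a * s), 0, np.inf)[0]
            expected.append(num / den)
        np.testing.assert_allclose(curve.values, expected, atol=0.01)


class TestSpeckleContrast:
    @staticmethod
    def closed_form(beta, x):
        return beta * (np.exp(-2 * x) + 2 * x - 1) / (2 * x**2)

    @pytest.mark.parametrize("x", np.logspace(-3, 3, 13))
    def test_single_exponential_closed_form(self, x):
        gamma_f = 1e3
        t_exp = x / gamma_f
        kf2 = speckle_contrast_from_g1(lambda t: np.exp(-gamma_f * np.asarray(t)),
                                       1.0, t_exp)
        assert kf2 == pytest.approx(self.closed_form(1.0, x), rel=1e-5)

    def test_short_exposure_limit_is_beta(self):
        kf2 = speckle_contrast_from_g1(lambda t: np.exp(-1e3 * np.asarray(t)),
                                       0.4, 1e-9)
        assert kf2 == pytest.approx(0.4, rel=1e-5)

    def test_monotone_nonincreasing_in_exposure(self):
        g1 = lambda t: np.exp(-2e3 * np.asarray(t))
        exposures = np.logspace(-6, -1, 30)
        vals = [speckle_contrast_from_g1(g1, 0.5, t) for t in exposures]
        assert np.all(np.diff(vals) <= 0)

    def test_rejects_nonpositive_exposure(self):
        with pytest.raises(ValueError):
            speckle_contrast_from_g1(lambda t: np.ones_like(t), 0.5, 0.0)


class TestTauGrid:
    def test_grid_is_multitau_structured(self):
        tau = multitau_grid(1e-6, 8, 1e-3)
        assert tau[0] == 0.0
        assert np.all(np.diff(tau) > 0)
        np.testing.assert_allclose(tau[1:17], 1e-6 * np.arange(1, 17))
        assert tau[-1] <= 1e-3

    def test_bin_widths_double_per_octave(self):
        tau = multitau_grid(1e-6, 8, 1e-3)
        w = multitau_bin_widths(tau, 1e-6, 8)
        np.testing.assert_allclose(w[:17], 1e-6)   # zero lag + first 2 octaves
        assert w[-1] > 1e-6
        assert set(np.diff(np.log2(np.unique(w)))) == {1.0}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    bfi=st.floats(1e-9, 1e-6), sds=st.floats(5.0, 40.0),
    beta=st.floats(0.05, 1.0),
)
def test_g2_bounded_by_siegert_band(bfi, sds, beta):
    """Noiseless g2 always lies in [1, 1+beta] on a physical grid."""
    tau = multitau_grid(tau_max=1e-2)
    geo = SemiInfiniteGeometry.from_measurement(sds, OPT_850, 850.0)
    g2 = siegert_g2(semi_infinite_g1(geo, OPT_850, bfi, tau), beta)
    assert np.all(g2.values >= 1.0 - 1e-12)
    assert np.all(g2.values <= 1.0 + beta + 1e-12)
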