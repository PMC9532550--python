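"""Closed-form transport theory against independent numeric oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from dtims import theory
from dtims.exceptions import ParameterError
from dtims.theory import (
    REFERENCE_CONFIG,
    REFERENCE_SPECIES,
    IonSpecies,
    TheoryConstants,
    beam_current,
    counteracted_current,
    counteracted_fwhm_analytic,
    counterbalance_resolution,
    diffusion_limit_resolution,
    drift_time,
    drift_velocity,
    enhancement_ratio_theory,
    inverse_current,
    length_equivalence_factor,
    mobility_from_D,
    nernst_einstein,
    peak_current,
    pulsed_current,
    pulsed_fwhm_analytic,
    tophat_pulsed_current,
)

SP = REFERENCE_SPECIES
CFG = REFERENCE_CONFIG
E, L = CFG.E_d, CFG.L_drift
TD = drift_time(CFG, SP)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestTransportBasics:
    @pytest.mark.parametrize("K, E_d, expected", [
        (1.1173e-4, 5.0e4, 5.5865),
        (2e-4, 1e4, 2.0),
    ])
    def test_drift_velocity(self, K, E_d, expected):
        sp = IonSpecies("x", K=K, D=1e-6)
        assert drift_velocity(sp, E_d) == pytest.approx(expected, rel=1e-4)

    def test_drift_velocity_rejects_nonpositive_field(self):
        with pytest.raises(ParameterError):
            drift_velocity(SP, 0.0)

    @pytest.mark.parametrize("K, expected", [
        (1.1173e-4, 1.790e-3),    # the reference ion arrives at 1.79 ms
        (2.2346e-4, 8.95e-4),     # doubling K halves the drift time
    ])
    def test_drift_time(self, K, expected):
        sp = IonSpecies("x", K=K, D=2.8e-6)
        assert drift_time(CFG, sp) == pytest.approx(expected, rel=1e-3)

    def test_invalid_species_parameters_rejected(self):
        for bad in [dict(K=0.0, D=1e-6), dict(K=1e-4, D=-1e-6),
                    dict(K=math.nan, D=1e-6), dict(K=1e-4, D=1e-6, q=0.0)]:
            with pytest.raises(ParameterError):
                IonSpecies("bad", **bad)


class TestNernstEinstein:
    def test_reference_pair_is_einstein_consistent_near_291K(self):
        # K = 1.1173e-4 and D = 2.8e-6 satisfy D = K·kB·T/q at T ≈ 290.8 K
        D = nernst_einstein(1.1173e-4, TheoryConstants(T=290.7), q=1.602e-19)
        assert D == pytest.approx(2.800e-6, rel=1e-3)
        assert theory.T_REF == pytest.approx(290.8, abs=0.1)

    @settings(derandomize=True, max_examples=50)
    @given(K=positive, T=st.floats(1.0, 1e4), q=st.floats(1e-20, 1e-18))
    def test_round_trip_identity(self, K, T, q):
        constants = TheoryConstants(T=T)
        assert mobility_from_D(nernst_einstein(K, constants, q), constants, q) \
            == pytest.approx(K, rel=1e-12)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ParameterError):
            nernst_einstein(0.0)
        with pytest.raises(ParameterError):
            mobility_from_D(-1e-6)


class TestCurrents:
    def test_pulsed_apex_value(self):
        # apex current v_d/(4πD·t_d)^{1/2} for unit C0·S
        assert pulsed_current(TD, L, SP, E) == pytest.approx(2.2261e4, rel=1e-4)
        assert pulsed_current(TD, L, SP, E) == pytest.approx(
            peak_current(SP, E, L), rel=1e-12)

    def test_pulsed_gaussian_tails_vanish(self):
        assert pulsed_current(TD, L + 0.1, SP, E) < 1e-30
        assert pulsed_current(TD, -0.1, SP, E) < 1e-30

    def test_pulsed_rejects_nonpositive_time(self):
        with pytest.raises(ParameterError):
            pulsed_current(0.0, L, SP, E)
        with pytest.raises(ParameterError):
            pulsed_current(-1e-3, L, SP, E)

    def test_pulsed_time_integral_equals_injected_content(self):
        # delta pulse of unit content: ∫ I1 dt at x = L equals C0·S
        val, _ = quad(lambda t: pulsed_current(t, L, SP, E), TD / 3, 3 * TD,
                      limit=200)
        assert val == pytest.approx(1.0, rel=1e-6)

    def test_inverse_dip_minimum_is_zero_at_apex(self):
        assert inverse_current(TD, L, SP, E, L=L) == pytest.approx(0.0, abs=1e-9)

    def test_inverse_plateau_approaches_peak_current(self):
        i1pk = peak_current(SP, E, L)
        assert inverse_current(TD / 2, L, SP, E, L=L) == pytest.approx(i1pk, rel=1e-6)

    def test_inverse_half_width_early_sits_near_half_peak(self):
        fwhm = pulsed_fwhm_analytic(SP, E, L)
        i1pk = peak_current(SP, E, L)
        val = inverse_current(TD - fwhm / 2, L, SP, E, L=L)
        assert 0 < val == pytest.approx(i1pk / 2, rel=0.02)

    def test_counteracted_apex_equals_pulsed_apex(self):
        i1pk = peak_current(SP, E, L)
        assert counteracted_current(TD, L, SP, E, L=L) == pytest.approx(i1pk, rel=1e-12)

    def test_counteracted_clips_to_zero_outside_half_max_support(self):
        t_far = TD - 3 * pulsed_fwhm_analytic(SP, E, L)
        assert pulsed_current(t_far, L, SP, E) < peak_current(SP, E, L) / 2
        assert counteracted_current(t_far, L, SP, E, L=L) == 0.0

    def test_counteracted_half_max_at_analytic_half_width(self):
        tw3 = counteracted_fwhm_analytic(SP, E, L)
        val = counteracted_current(TD - tw3 / 2, L, SP, E, L=L)
        assert val == pytest.approx(peak_current(SP, E, L) / 2, rel=0.01)

    def test_counteracted_bounded_between_zero_and_peak(self):
        t = np.linspace(TD / 2, 1.5 * TD, 4001)
        y = counteracted_current(t, L, SP, E, L=L)
        assert np.all(y >= 0)
        assert np.all(y <= peak_current(SP, E, L) * (1 + 1e-12))

    def test_beam_superposition_reconstructs_constant_current(self):
        # pulsed + raw inverse (corrected inverse plus its baseline) = I0
        t = np.linspace(TD / 2, 1.5 * TD, 1001)
        i0 = beam_current(SP, E)
        i_base = i0 - peak_current(SP, E, L)
        total = pulsed_current(t, L, SP, E) + inverse_current(t, L, SP, E, L=L) + i_base
        assert np.max(np.abs(total - i0)) < 1e-12 * i0


class TestTophat:
    def test_narrow_slab_limit_recovers_delta_pulse(self):
        t = np.linspace(0.9 * TD, 1.1 * TD, 501)
        L_ion = 0.005 * math.sqrt(4 * SP.D * TD)
        slab = tophat_pulsed_current(t, L, SP, E, L_ion=L_ion) / L_ion
        delta = pulsed_current(t, L, SP, E)
        assert np.max(np.abs(slab - delta)) < 1e-3 * delta.max()

    def test_symmetric_about_packet_centre(self):
        v = drift_velocity(SP, E)
        for dxx in [1e-5, 5e-5, 2e-4]:
            a = tophat_pulsed_current(TD, v * TD + dxx, SP, E, L_ion=1e-4)
            b = tophat_pulsed_current(TD, v * TD - dxx, SP, E, L_ion=1e-4)
            assert a == pytest.approx(b, rel=1e-12)

    def test_detector_time_integral_conserves_slab_content(self):
        L_ion = 1e-4
        val, _ = quad(lambda t: tophat_pulsed_current(t, L, SP, E, L_ion=L_ion),
                      TD / 3, 3 * TD, limit=200)
        assert val == pytest.approx(L_ion, rel=1e-6)


class TestWidthsAndResolution:
    def test_reference_analytic_widths(self):
        assert pulsed_fwhm_analytic(SP, E, L) == pytest.approx(4.220e-5, rel=1e-3)
        assert counteracted_fwhm_analytic(SP, E, L) == pytest.approx(2.719e-5, rel=1e-3)

    def test_widths_agree_with_numeric_half_max_root_find(self):
        i1pk = peak_current(SP, E, L)
        f = lambda t: pulsed_current(t, L, SP, E) - i1pk / 2
        exact = brentq(f, TD, TD + 2e-4) - brentq(f, TD - 2e-4, TD)
        assert pulsed_fwhm_analytic(SP, E, L) == pytest.approx(exact, rel=1e-3)
        g = lambda t: counteracted_current(t, L, SP, E, L=L) - i1pk / 2
        exact3 = brentq(g, TD, TD + 1e-4) - brentq(g, TD - 1e-4, TD)
        assert counteracted_fwhm_analytic(SP, E, L) == pytest.approx(exact3, rel=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(K=st.floats(1e-5, 1e-3), D=st.floats(1e-7, 1e-4))
    def test_width_ratio_is_species_independent(self, K, D):
        sp = IonSpecies("any", K=K, D=D)
        ratio = pulsed_fwhm_analytic(sp, E, L) / counteracted_fwhm_analytic(sp, E, L)
        assert ratio == pytest.approx(enhancement_ratio_theory(), rel=1e-12)

    def test_width_vanishes_with_diffusion(self):
        sp = IonSpecies("cold", K=SP.K, D=1e-15)
        assert pulsed_fwhm_analytic(sp, E, L) < 1e-9

    def test_reference_diffusion_limit_resolutions(self):
        assert diffusion_limit_resolution(E, L, K=SP.K, D=SP.D) \
            == pytest.approx(42.4, abs=0.05)
        assert counterbalance_resolution(E, L, K=SP.K, D=SP.D) \
            == pytest.approx(65.8, abs=0.05)

    def test_field_charge_temperature_form_matches_KD_form(self):
        constants = TheoryConstants(T=321.5)
        q = 1.7e-19
        K = 2.2e-4
        D = nernst_einstein(K, constants, q)  # Einstein-linked pair
        for fn in (diffusion_limit_resolution, counterbalance_resolution):
            assert fn(E, L, K=K, D=D) == pytest.approx(
                fn(E, L, q=q, constants=constants), rel=1e-12)

    def test_quadrupling_length_doubles_resolution(self):
        r1 = diffusion_limit_resolution(E, L, K=SP.K, D=SP.D)
        r4 = diffusion_limit_resolution(E, 4 * L, K=SP.K, D=SP.D)
        assert r4 == pytest.approx(2 * r1, rel=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ParameterError):
            diffusion_limit_resolution(-E, L, K=SP.K, D=SP.D)
        with pytest.raises(ParameterError):
            counterbalance_resolution(E, L, K=SP.K, D=0.0)


class TestEnhancementRatio:
    def test_closed_form_value(self):
        alpha = enhancement_ratio_theory()
        assert alpha == pytest.approx(1.5522, abs=5e-5)
        assert alpha > 1.55
        assert alpha == pytest.approx(math.sqrt(math.log(2) / math.log(4 / 3)),
                                      rel=1e-15)

    def test_length_equivalence_is_alpha_squared(self):
        assert length_equivalence_factor() == pytest.approx(2.4094, abs=5e-4)
        assert length_equivalence_factor() \
            == pytest.approx(enhancement_ratio_theory() ** 2, rel=1e-15)
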