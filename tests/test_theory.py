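"""Closed-form encounter kernels: limits, calculus identities, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mucuswalk as mw
from mucuswalk import units


WT = mw.RelativeMotionParams(v_B=30.0, mean_run_time=0.01, D_alpha=1.03,
                             alpha=0.82)
DHOC = mw.RelativeMotionParams(v_B=30.0, mean_run_time=0.01, D_alpha=2.54,
                               alpha=1.0)
STATIC_DHOC = mw.RelativeMotionParams(v_B=0.0, mean_run_time=1.0, D_alpha=2.54,
                                      alpha=1.0)
STATIC_WT = mw.RelativeMotionParams(v_B=0.0, mean_run_time=1.0, D_alpha=1.03,
                                    alpha=0.82)


class TestBallisticKernel:
    def test_swimming_coli_value(self):
        assert mw.ballistic_kernel(1.1, 30.0) == pytest.approx(4.1e-7, abs=0.05e-7)

    def test_zero_speed(self):
        assert mw.ballistic_kernel(1.1, 0.0) == 0.0

    def test_quadratic_in_radius(self):
        assert mw.ballistic_kernel(2.2, 30.0) == pytest.approx(
            4 * mw.ballistic_kernel(1.1, 30.0), rel=1e-12)


class TestInstantaneousDiffusivity:
    def test_time_independent_at_alpha_one(self):
        assert mw.instantaneous_diffusivity(0.5, DHOC) == pytest.approx(
            5.54e-12, rel=1e-3)
        assert mw.instantaneous_diffusivity(50.0, DHOC) == pytest.approx(
            mw.instantaneous_diffusivity(0.5, DHOC), rel=1e-12)

    def test_static_brownian_reduces_to_d(self):
        assert mw.instantaneous_diffusivity(1.0, STATIC_DHOC) == pytest.approx(
            2.54e-12, rel=1e-12)

    def test_subdiffusive_term_decays_to_zero(self):
        t = np.geomspace(0.01, 1e4, 50)
        d = mw.instantaneous_diffusivity(t, STATIC_WT)
        assert np.all(np.diff(d) < 0)
        # t^(alpha-1) decay: a factor (1e6)^0.18 ~ 12 over this grid
        assert d[-1] < 0.1 * d[0]

    def test_singular_origin_rejected(self):
        with pytest.raises(ValueError):
            mw.instantaneous_diffusivity(0.0, STATIC_WT)


class TestLambdaIntegral:
    def test_zero_at_origin(self):
        assert mw.lambda_integral(0.0, WT) == 0.0

    def test_brownian_limit_is_dt(self):
        assert mw.lambda_integral(2.0, STATIC_DHOC) == pytest.approx(
            2.0 * 2.54e-12, rel=1e-12)

    def test_derivative_matches_diffusivity(self):
        # d lambda / dt == instantaneous diffusivity, checked numerically
        t = np.geomspace(0.05, 100.0, 40)
        h = 1e-6 * t
        num = (mw.lambda_integral(t + h, WT) - mw.lambda_integral(t - h, WT)) / (2 * h)
        assert num == pytest.approx(mw.instantaneous_diffusivity(t, WT), rel=1e-6)


class TestEncounterFlux:
    def test_smoluchowski_limit(self):
        # alpha = 1, v_B = 0, t -> infinity: classical 4 pi R_C D
        classical = units.m3_s_to_ml_h(
            4 * np.pi * (1.1 * units.M_PER_UM) * 2.54e-12)
        ss = mw.steady_state_kernel(STATIC_DHOC)
        assert ss.exists
        assert ss.beta_ml_h == pytest.approx(classical, rel=1e-9)
        _, beta_late = mw.encounter_flux(1e9, STATIC_DHOC)
        assert beta_late == pytest.approx(classical, rel=1e-4)

    def test_transient_exceeds_asymptote(self):
        ss = mw.steady_state_kernel(DHOC)
        _, beta = mw.encounter_flux(0.5, DHOC)
        assert beta > ss.beta_ml_h

    def test_monotonic_decay(self):
        t = np.geomspace(0.01, 1e4, 200)
        for params in (WT, DHOC, STATIC_WT, STATIC_DHOC):
            _, beta = mw.encounter_flux(t, params)
            assert np.all(np.diff(beta) < 0)

    def test_subdiffusive_static_kernel_decays_to_zero(self):
        ss = mw.steady_state_kernel(STATIC_WT)
        assert not ss.exists and ss.beta_ml_h == 0.0
        _, early = mw.encounter_flux(1.0, STATIC_WT)
        _, late = mw.encounter_flux(1e6, STATIC_WT)
        assert late < 0.1 * early

    def test_flux_proportional_to_concentration(self):
        dense = mw.RelativeMotionParams(v_B=30.0, mean_run_time=0.01,
                                        D_alpha=2.54, alpha=1.0, P_inf=2.0)
        f1, b1 = mw.encounter_flux(1.0, DHOC)
        f2, b2 = mw.encounter_flux(1.0, dense)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)
        assert b2 == pytest.approx(b1, rel=1e-12)


class TestSteadyStates:
    def test_frequent_tumbler_with_subdiffusive_phage(self):
        assert mw.steady_state_kernel(WT).beta_ml_h == pytest.approx(
            1.49e-7, abs=0.005e-7)

    def test_frequent_tumbler_with_brownian_phage(self):
        assert mw.steady_state_kernel(DHOC).beta_ml_h == pytest.approx(
            2.77e-7, abs=0.02e-7)

    def test_static_bacterium_brownian_phage(self):
        assert mw.steady_state_kernel(STATIC_DHOC).beta_ml_h == pytest.approx(
            1.26e-7, abs=0.005e-7)


class TestAuxiliaries:
    def test_rms_displacements_over_one_run(self):
        assert mw.rms_displacement(1.03, 0.82, 1.0) == pytest.approx(2.49, abs=0.005)
        assert mw.rms_displacement(2.54, 1.0, 1.0) == pytest.approx(3.90, abs=0.005)
        assert mw.rms_displacement(1.03, 0.82, 0.0) == 0.0

    def test_ballistic_to_static_uptake_ratio(self):
        ratio = mw.kernel_ratio(mw.ballistic_kernel(1.1, 30.0),
                                mw.steady_state_kernel(STATIC_DHOC).beta_ml_h)
        assert ratio == pytest.approx(3.25, abs=0.005)
        # closed form: R_C * v_B / (4 D)
        assert ratio == pytest.approx(1.1 * 30.0 / (4 * 2.54), rel=1e-9)

    def test_ratio_edge_cases(self):
        assert mw.kernel_ratio(1.0, 1.0) == 1.0
        assert mw.kernel_ratio(0.0, 2.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            mw.kernel_ratio(1.0, 0.0)

    @given(value=st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=100, deadline=None)
    def test_unit_conversion_round_trip(self, value):
        assert units.ml_h_to_um3_s(units.um3_s_to_ml_h(value)) == pytest.approx(
            value, rel=1e-12)

    def test_unit_conversion_chain(self):
        # pi (1.1 um)^2 * 30 um/s = 1.140e-16 m^3/s = 4.105e-7 mL/h
        um3_s = np.pi * 1.1 ** 2 * 30.0
        assert um3_s * units.M_PER_UM ** 3 == pytest.approx(1.140e-16, abs=1e-19)
        assert units.um3_s_to_ml_h(um3_s) == pytest.approx(4.105e-7, abs=1e-10)
        assert units.um3_s_to_ml_h(1.0) == pytest.approx(3.6e-9, rel=1e-12)
        assert units.m3_s_to_ml_h(um3_s * units.M_PER_UM ** 3) == pytest.approx(
            units.um3_s_to_ml_h(um3_s), rel=1e-12)
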