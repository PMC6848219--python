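"""Calibration relations: Stokes-Einstein inversion, power-law fits,
CTRW time extraction and their round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mucuswalk as mw
from mucuswalk.calibration import (
    CalibrationDomainError,
    InsufficientDataError,
    normalized_sinc,
)


class TestStokesEinstein:
    @pytest.mark.parametrize("D,expected", [(2.54, 0.99), (3.64, 0.69)])
    def test_viscosity_from_mutant_diffusivity(self, D, expected):
        # 90 nm probe at body temperature reproduces the tabulated viscosities
        assert mw.stokes_einstein_viscosity(D, R_P=90.0, kT=4.28) == pytest.approx(
            expected, abs=0.005)

    def test_viscosity_scales_inversely_with_diffusivity(self):
        assert mw.stokes_einstein_viscosity(2 * 3.64) == pytest.approx(
            mw.stokes_einstein_viscosity(3.64) / 2, rel=1e-12)

    def test_hydrodynamic_radius_of_t4(self):
        r = mw.hydrodynamic_radius(3.64, kT=4.28, eta_water=0.69)
        assert round(r, -1) == 90  # two significant figures

    def test_hydrodynamic_radius_inverse_in_d(self):
        assert mw.hydrodynamic_radius(2 * 3.64) == pytest.approx(
            mw.hydrodynamic_radius(3.64) / 2, rel=1e-12)

    def test_hydrodynamic_radius_room_temperature_probe(self):
        # independent hand evaluation of kT/(6 pi eta D):
        # 4.11 / (6*pi*0.89*3.66) um = 0.06694 um
        assert mw.hydrodynamic_radius(3.66, kT=4.11, eta_water=0.89) == pytest.approx(
            66.94, abs=0.05)

    @pytest.mark.parametrize("bad", [{"D": -1.0}, {"kT": 0.0}, {"R_P": -2.0}])
    def test_nonpositive_inputs_rejected(self, bad):
        kwargs = {"D": 2.54, "R_P": 90.0, "kT": 4.28}
        kwargs.update(bad)
        with pytest.raises(CalibrationDomainError, match=next(iter(bad))):
            mw.stokes_einstein_viscosity(**kwargs)

    def test_viscosity_matches_table2_means(self, table1, table2):
        # inverting every mutant diffusivity reproduces the viscosity table
        means = {e.mucin_concentration: e.viscosity for e in table2}
        for row in table1:
            if row.phage_type != "dhoc":
                continue
            eta = mw.stokes_einstein_viscosity(row.D, R_P=90.0, kT=4.28)
            assert eta == pytest.approx(means[row.mucin_concentration], abs=0.03)


class TestViscosityPowerLaw:
    def test_low_concentration_region(self, table2):
        c = [e.mucin_concentration for e in table2]
        eta = [e.viscosity for e in table2]
        fit = mw.fit_viscosity_powerlaw(c, eta, region=(0.2, 1.0))
        assert fit.exponent == pytest.approx(0.65, abs=0.01)
        assert fit.exponent_stderr == pytest.approx(0.14, abs=0.01)
        assert fit.prefactor_log == pytest.approx(-1.12, abs=0.01)

    def test_high_concentration_region(self, table2):
        c = [e.mucin_concentration for e in table2]
        eta = [e.viscosity for e in table2]
        fit = mw.fit_viscosity_powerlaw(c, eta, region=(1.0, 4.0))
        assert fit.exponent == pytest.approx(1.59, abs=0.01)
        assert fit.exponent_stderr == pytest.approx(0.20, abs=0.01)
        assert fit.prefactor_log == pytest.approx(-1.13, abs=0.01)

    def test_noiseless_power_law_recovered_exactly(self):
        c = np.array([0.2, 0.6, 1.0])
        eta = 2.0 * c ** 0.5 + 0.69
        fit = mw.fit_viscosity_powerlaw(c, eta, eta_water=0.69, region=(0.2, 1.0))
        assert fit.exponent == pytest.approx(0.5, abs=1e-12)
        assert fit.prefactor == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_concentration_always_excluded(self, table2):
        c = [e.mucin_concentration for e in table2]
        eta = [e.viscosity for e in table2]
        full = mw.fit_viscosity_powerlaw(c, eta, region=(0.0, 1.0))
        sub = mw.fit_viscosity_powerlaw(c, eta, region=(0.2, 1.0))
        assert full.exponent == pytest.approx(sub.exponent, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            mw.fit_viscosity_powerlaw([0.5, 1.0], [1.0, 1.2], region=(0.2, 1.0))

    def test_viscosity_below_water_rejected(self):
        with pytest.raises(CalibrationDomainError):
            mw.fit_viscosity_powerlaw([0.2, 0.6, 1.0], [0.5, 0.9, 1.0],
                                      eta_water=0.69, region=(0.2, 1.0))


class TestCTRWTimes:
    def test_one_percent_wildtype(self, wt_1pct_params):
        assert wt_1pct_params.tau_D == pytest.approx(6.6e-3, abs=1e-4)
        assert wt_1pct_params.tau_0 == pytest.approx(9.8e-4, abs=1e-5)
        assert wt_1pct_params.nu == pytest.approx(0.82)

    def test_mean_sticking_time_order_one_millisecond(self, table1):
        rows = [r for r in table1
                if r.phage_type == "wt" and r.mucin_concentration > 0]
        mean = mw.mean_minimum_sticking_time(rows)
        # one significant figure: 0.001 s
        assert 0.0005 <= mean < 0.0015

    def test_alpha_at_one_recovers_regular_diffusion(self):
        # sinc(1) = 0, so the sticking floor vanishes continuously
        assert normalized_sinc(1.0) == pytest.approx(0.0, abs=1e-15)
        row = mw.PhageDiffusivity(mucin_concentration=0.0, alpha=1.02,
                                  D_alpha=3.84, D=3.64)
        with pytest.warns(UserWarning, match="pure diffusion"):
            params = mw.ctrw_times_from_diffusivities(row)
        assert params.nu == 1.0
        assert params.tau_0 == 0.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(CalibrationDomainError):
            mw.PhageDiffusivity(mucin_concentration=1.0, alpha=-0.5,
                                D_alpha=1.0, D=2.0)

    @given(nu=st.floats(min_value=0.05, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_sticking_ratio_in_unit_interval(self, nu):
        ratio = normalized_sinc(nu) ** (1.0 / nu)
        assert 0.0 < ratio < 1.0

    def test_sticking_ratio_decreases_toward_regular_diffusion(self):
        nus = np.linspace(0.05, 0.999, 60)
        ratios = [normalized_sinc(v) ** (1.0 / v) for v in nus]
        assert np.all(np.diff(ratios) < 0)

    @given(nu=st.floats(min_value=0.3, max_value=0.98),
           d=st.floats(min_value=0.1, max_value=5.0),
           d_alpha=st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_recovers_generalized_constant(self, nu, d, d_alpha):
        row = mw.PhageDiffusivity(mucin_concentration=1.0, alpha=nu,
                                  D_alpha=d_alpha, D=d)
        p = mw.ctrw_times_from_diffusivities(row)
        assert mw.generalized_diffusion_constant(p.D, p.tau_D, p.nu) == pytest.approx(
            d_alpha, rel=1e-9)

    def test_round_trip_on_every_subdiffusive_table_row(self, table1):
        for row in table1:
            if row.alpha >= 1.0:
                continue
            p = mw.ctrw_times_from_diffusivities(row)
            back = mw.generalized_diffusion_constant(p.D, p.tau_D, p.nu)
            assert back == pytest.approx(row.D_alpha, rel=1e-9)

    def test_generalized_constant_hand_values(self):
        assert mw.generalized_diffusion_constant(1.0, 0.1, 0.5) == pytest.approx(
            math.sqrt(0.1), rel=1e-12)
        assert mw.generalized_diffusion_constant(2.54, 0.0066, 1.0) == 2.54


class TestRelaxationTime:
    def test_bacterium_and_phage_orders_of_magnitude(self):
        from mucuswalk.units import friction_coefficient
        gamma_b = friction_coefficient(0.69, 1e-6)
        gamma_p = friction_coefficient(0.69, 90e-9)
        assert mw.relaxation_time(1e-15, gamma_b) == pytest.approx(7.7e-8, rel=0.01)
        assert mw.relaxation_time(1e-19, gamma_p) == pytest.approx(8.5e-11, rel=0.01)

    def test_linearity_in_mass(self):
        assert mw.relaxation_time(2e-15, 1e-8) == pytest.approx(
            2 * mw.relaxation_time(1e-15, 1e-8), rel=1e-12)

    def test_overdamped_limit_justified(self, wt_1pct_params):
        from mucuswalk.units import friction_coefficient
        tau_relax = mw.relaxation_time(1e-19, friction_coefficient(0.99, 90e-9))
        assert tau_relax < 1e-4 * wt_1pct_params.tau_D
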