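"""Bioheat temperature-rise estimation."""

import math

import numpy as np
import pytest

from earwave.dielectrics import penetration_depth
from earwave.errors import InvalidInputError
from earwave.thermal import (
    ScenarioDose,
    ThermalState,
    exposure_report,
    init_rate_method1,
    init_rate_method2,
    integrate_bioheat,
)


class TestInitialRates:
    def test_method1_arithmetic(self):
        assert init_rate_method1(3.0, 3000.0) == pytest.approx(1.0e-3)
        assert init_rate_method1(0.0, 3000.0) == 0.0
        assert init_rate_method1(1.78, 3000.0) == pytest.approx(5.9e-4, abs=5e-6)

    def test_method2_surface_and_linearity(self):
        rate0 = init_rate_method2(1.0, 2.7e-4, 0.0, 1151.0, 3000.0)
        assert rate0 == pytest.approx(1.0 / (2.7e-4 * 1151.0 * 3000.0))
        assert init_rate_method2(2.0, 2.7e-4, 0.0, 1151.0, 3000.0) == pytest.approx(2 * rate0)

    def test_method2_fibrous_90ghz_order(self, tissue_table):
        delta = penetration_depth(tissue_table.get("fibrous_tissue", 90e9))
        rate = init_rate_method2(1.38, delta, 3e-5, 1151.0, 3000.0)
        assert rate == pytest.approx(1.2e-3, rel=0.05)


class TestBioheatIntegration:
    def test_equilibrium_is_constant(self, thermal_params):
        fib = thermal_params.get("fibrous_tissue")
        traj = integrate_bioheat(0.0, fib, thermal_params)
        assert np.all(traj.temperatures == traj.temperatures[0])

    def test_exactly_linear_without_perfusion(self, thermal_params):
        sc = thermal_params.get("stratum_corneum")  # BP = 0
        rate = 3.3e-3
        traj = integrate_bioheat(rate, sc, thermal_params, dt=0.1, duration=5.0)
        assert traj.final_rise == pytest.approx(rate * 5.0, rel=1e-14)

    def test_perfusion_decay_matches_closed_form(self, thermal_params):
        """Heating off, 1 degC offset: exponential decay with time constant
        c_t/(rho_b c_b BP), Euler-accurate to 0.5 % at dt = 0.1 s."""
        fib = thermal_params.get("fibrous_tissue")
        lam = (
            thermal_params.blood_density
            * thermal_params.blood_heat_capacity
            * fib.blood_flow
            / fib.heat_capacity
        )
        state0 = ThermalState(tissue_temperature=38.0)
        traj = integrate_bioheat(0.0, fib, thermal_params, state0=state0,
                                 dt=0.1, duration=5.0)
        expected = 37.0 + 1.0 * np.exp(-lam * traj.times)
        assert np.max(np.abs(traj.temperatures - expected)) < 0.005

    def test_method1_equals_single_lossless_step(self, thermal_params):
        sc = thermal_params.get("stratum_corneum")
        rate = init_rate_method1(1.5, sc.heat_capacity)
        traj = integrate_bioheat(rate, sc, thermal_params, dt=0.1, duration=0.1)
        assert traj.final_rise == pytest.approx(rate * 0.1, rel=1e-14)

    def test_headline_occupational_rise(self, thermal_params):
        """The printed occupational 90 GHz orthogonal rate integrates to
        ~0.032 degC over 5 s with a sub-percent perfusion correction."""
        fib = thermal_params.get("fibrous_tissue")
        traj = integrate_bioheat(6.45e-3, fib, thermal_params, dt=0.1, duration=5.0)
        assert traj.final_rise == pytest.approx(0.032, abs=5e-4)
        linear = 6.45e-3 * 5.0
        assert (linear - traj.final_rise) / linear < 0.01

    def test_invalid_steps_rejected(self, thermal_params):
        fib = thermal_params.get("fibrous_tissue")
        with pytest.raises(InvalidInputError):
            integrate_bioheat(1e-3, fib, thermal_params, dt=0.0)
        with pytest.raises(InvalidInputError):
            integrate_bioheat(1e-3, fib, thermal_params, dt=1.0, duration=0.5)
        with pytest.raises(InvalidInputError):
            integrate_bioheat(1e6, fib, thermal_params)  # diverges out of range


class TestExposureReport:
    def _doses(self):
        return [
            ScenarioDose(frequency=90e9, angle="orthogonal", sar_peak=1.78, pd=1.38),
            ScenarioDose(frequency=90e9, angle="anterior_30", sar_peak=0.17, pd=0.13),
            ScenarioDose(frequency=60e9, angle="orthogonal", sar_peak=0.45, pd=0.41),
        ]

    def test_occupational_columns_scale_by_five(self, thermal_params, tissue_table):
        df = exposure_report(self._doses(), thermal_params, tissue_table)
        assert np.allclose(df["sar_occupational_w_kg"], 5 * df["sar_public_w_kg"])
        assert np.allclose(df["rise_5s_occupational_c"], 5 * df["rise_5s_public_c"])

    def test_zero_sar_gives_zero_tables(self, thermal_params, tissue_table):
        doses = [ScenarioDose(90e9, "orthogonal", 0.0, pd=0.0)]
        df = exposure_report(doses, thermal_params, tissue_table)
        assert df["rate1_public_c_per_s"].iloc[0] == 0.0
        assert df["rise_5s_public_c"].iloc[0] == 0.0

    def test_methods_agree_within_band(self, thermal_params, tissue_table):
        """The SAR-based and penetration-depth-based initial rates agree
        within a factor of 2.5 when fed consistent fields."""
        from earwave.dielectrics import intrinsic_impedance
        from earwave.dosimetry import sar as sar_fn

        eps = tissue_table.get("fibrous_tissue", 90e9)
        e_peak = 7.94
        h_peak = e_peak / abs(intrinsic_impedance(eps))
        dose = ScenarioDose(
            frequency=90e9, angle="orthogonal",
            sar_peak=sar_fn(e_peak, tissue_table.conductivity("fibrous_tissue", 90e9), 1151.0),
            pd=e_peak * h_peak,
        )
        df = exposure_report([dose], thermal_params, tissue_table)
        ratio = df["rate1_public_c_per_s"].iloc[0] / df["rate2_public_c_per_s"].iloc[0]
        assert 1 / 2.5 < ratio < 2.5

    def test_rms_convention_doubles_method1(self, thermal_params, tissue_table):
        doses = self._doses()[:1]
        rms = exposure_report(doses, thermal_params, tissue_table, convention="rms")
        peak = exposure_report(doses, thermal_params, tissue_table, convention="peak")
        assert rms["rate1_public_c_per_s"].iloc[0] == pytest.approx(
            2 * peak["rate1_public_c_per_s"].iloc[0], rel=1e-12
        )
        assert rms.attrs["sar_convention"] == "rms"

    def test_published_chain_from_tabulated_sar(self, thermal_params, tissue_table):
        """Peak-convention SAR 1.94 W/kg at the public level feeds the rms
        chain to a 1.29e-3 degC/s method-#1 rate and, at 5x occupational
        scaling, the 6.45e-3 degC/s headline rate."""
        dose = ScenarioDose(frequency=90e9, angle="orthogonal", sar_peak=1.94)
        df = exposure_report([dose], thermal_params, tissue_table)
        assert df["rate1_public_c_per_s"].iloc[0] == pytest.approx(1.29e-3, rel=0.005)
        assert df["rate1_occupational_c_per_s"].iloc[0] == pytest.approx(6.45e-3, rel=0.005)

    def test_missing_metadata_rejected(self, thermal_params, tissue_table):
        with pytest.raises(InvalidInputError):
            exposure_report(
                [ScenarioDose(frequency=90e9, angle="sideways", sar_peak=1.0)],
                thermal_params, tissue_table,
            )
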