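import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mpimfh.catalog import CATALOG, get_particle
from mpimfh.particles import (ParticleSpec, RelaxationParams,
                              SARInputs, heating_power, langevin,
                              langevin_deriv, magnetization, mps_spectrum,
                              relaxation_times, sar_from_curve)

# coth(1) - 1 evaluated with 50-digit arithmetic
LANGEVIN_AT_ONE = 0.31303528549933130363616124693084783406700680881345


class TestLangevin:
    def test_odd_function_zero_at_origin(self):
        assert langevin(0.0) == 0.0

    def test_saturation_limit(self):
        assert langevin(1e9) == pytest.approx(1.0, abs=1e-8)

    def test_high_precision_reference_value(self):
        assert langevin(1.0) == pytest.approx(LANGEVIN_AT_ONE, abs=1e-14)

    @given(st.floats(min_value=-500, max_value=500))
    def test_odd_and_bounded(self, xi):
        assert langevin(xi) == pytest.approx(-langevin(-xi), abs=1e-12)
        assert abs(langevin(xi)) < 1.0

    def test_series_agrees_with_stable_direct_evaluation(self):
        # the direct formula is accurate away from 0; the series must join it
        # smoothly (the direct branch near 1e-4 suffers cancellation, so the
        # comparison is made where both are reliable)
        for xi in (1e-3, 1e-2):
            direct = 1.0 / np.tanh(xi) - 1.0 / xi
            series = xi / 3.0 - xi**3 / 45.0 + 2.0 * xi**5 / 945.0
            assert langevin(xi) == pytest.approx(direct, rel=1e-12)
            assert langevin(xi) == pytest.approx(series, rel=1e-8)
        assert langevin(5e-5) == pytest.approx(5e-5 / 3 - (5e-5) ** 3 / 45, rel=1e-12)

    def test_derivative_initial_slope(self):
        assert langevin_deriv(0.0) == pytest.approx(1.0 / 3.0)


class TestMagnetization:
    def test_zero_field(self):
        p = get_particle("synomag-D-70")
        assert magnetization(0.0, 296.15, p, 5.0) == 0.0

    def test_linear_in_concentration(self):
        p = get_particle("synomag-D-70")
        m1 = magnetization(5.0, 296.15, p, 1.0)
        m2 = magnetization(5.0, 296.15, p, 2.0)
        assert m2 == pytest.approx(2.0 * m1, rel=1e-12)

    def test_odd_in_field(self):
        p = get_particle("synomag-D-70")
        assert magnetization(-5.0, 296.15, p, 1.0) == pytest.approx(
            -magnetization(5.0, 296.15, p, 1.0), rel=1e-12)

    def test_decreasing_in_temperature(self):
        # the thermometry contrast mechanism: warmer tracer magnetizes less
        p = get_particle("synomag-D-70")
        assert magnetization(5.0, 318.15, p, 1.0) < magnetization(5.0, 296.15, p, 1.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            magnetization(5.0, 296.15, get_particle("synomag-D-70"), -1.0)


class TestMPS:
    def test_linear_regime_has_no_fifth_harmonic(self):
        p = get_particle("synomag-D-70")
        res = mps_spectrum(p, 0.1, 25e3)
        assert res.a5_a3 < 1e-2

    def test_step_magnetization_limit(self):
        # a huge drive saturates the response into a square wave whose odd
        # harmonics decay as 1/k: A5/A3 -> 3/5
        p = get_particle("synomag-D-70")
        res = mps_spectrum(p, 1e6, 25e3)
        assert res.a5_a3 == pytest.approx(0.6, rel=1e-2)

    def test_even_harmonics_vanish(self):
        for key in ("synomag-D-70", "perimag-plain"):
            res = mps_spectrum(get_particle(key), 25.0, 25e3)
            assert res.even_residual < 1e-10

    def test_quadrature_oracle_at_double_resolution(self):
        p = get_particle("synomag-S-90")
        a = mps_spectrum(p, 25.0, 25e3, n_samples=4096)
        b = mps_spectrum(p, 25.0, 25e3, n_samples=8192)
        assert np.allclose(a.harmonic_amplitudes, b.harmonic_amplitudes, rtol=1e-8)

    def test_a5_a3_increases_with_core_size_across_catalog(self):
        cores, ratios = [], []
        for p in CATALOG.values():
            cores.append(p.core_diameter)
            ratios.append(mps_spectrum(p, 25.0, 25e3).a5_a3)
        rho = stats.spearmanr(cores, ratios).statistic
        assert rho > 0.9

    def test_ratio_within_langevin_bounds(self):
        res = mps_spectrum(get_particle("synomag-S-90"), 25.0, 25e3)
        assert 0.0 <= res.a5_a3 < 1.0


class TestRelaxation:
    def test_effective_time_below_both(self):
        for key in CATALOG:
            rel = relaxation_times(get_particle(key))
            assert rel.tau_eff <= min(rel.tau_neel, rel.tau_brown) * (1 + 1e-12)

    def test_brownian_hand_value(self):
        # tau_B = 3 eta V_h / (k_B T) for d_h = 70 nm, eta = 1 mPa s, 298 K
        rel = relaxation_times(get_particle("synomag-D-70"), viscosity=1e-3,
                               temperature=298.0)
        assert rel.tau_brown == pytest.approx(1.3096e-4, rel=1e-3)

    def test_neel_increases_with_core_volume(self):
        small = relaxation_times(get_particle("synomag-D-50"))
        large = relaxation_times(get_particle("synomag-D-70"))
        assert large.tau_neel > small.tau_neel

    def test_overflow_capped_and_flagged(self):
        p = ParticleSpec(name="giant", core_diameter=80.0, hydrodynamic_diameter=120.0,
                         anisotropy_constant=5e4)
        rel = relaxation_times(p)
        assert rel.neel_capped
        assert np.isfinite(rel.tau_neel)

    def test_invariant_validated(self):
        with pytest.raises(ValueError):
            RelaxationParams(tau_neel=1e-7, tau_brown=1e-7, tau_eff=2e-7,
                             viscosity=1e-3, anisotropy_constant=1e3, temperature=296.0)


class TestHeatingPower:
    def test_zero_amplitude(self):
        assert heating_power(get_particle("synomag-S-90"), 0.0, 715e3, 10.0) == 0.0

    def test_monotone_in_amplitude_and_concentration(self):
        p = get_particle("synomag-S-90")
        amps = [2.0, 5.0, 8.0, 10.0]
        powers = [heating_power(p, a, 715e3, 5.0) for a in amps]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert heating_power(p, 10.0, 715e3, 10.0) == pytest.approx(
            2.0 * heating_power(p, 10.0, 715e3, 5.0), rel=1e-12)

    def test_dissipation_peaks_at_unit_omega_tau(self):
        p = get_particle("synomag-S-90")
        f = 715e3
        tau_star = 1.0 / (2 * np.pi * f)

        def power_at(tau):
            rel = RelaxationParams(tau_neel=tau, tau_brown=1e6 * tau,
                                   tau_eff=tau / (1 + 1e-6), viscosity=1e-3,
                                   anisotropy_constant=1e3, temperature=296.15)
            return heating_power(p, 10.0, f, 5.0, rel)

        p_star = power_at(tau_star)
        assert p_star > power_at(tau_star / 3)
        assert p_star > power_at(tau_star * 3)

    def test_measured_heating_ranking_of_synomag_family(self):
        # the bench comparison ranks synomag-S-90 >= D-70 >= D-50 at equal iron
        powers = [heating_power(get_particle(k), 10.0, 715e3, 2.4)
                  for k in ("synomag-S-90", "synomag-D-70", "synomag-D-50")]
        assert powers[0] >= powers[1] >= powers[2]
        assert powers[1] > 2 * powers[2]  # the small-core type heats far less


class TestSAR:
    def test_zero_slope(self):
        s = SARInputs(mass_water=0.14, mass_iron=0.0014, initial_slope=0.0)
        assert sar_from_curve(s) == 0.0

    def test_vial_arithmetic(self):
        # 140 uL of water with 1.4 mg iron warming at 0.5 K/s
        s = SARInputs(mass_water=0.14, mass_iron=0.0014, initial_slope=0.5)
        assert sar_from_curve(s) == pytest.approx(208.4)

    @given(st.floats(min_value=1e-4, max_value=10),
           st.floats(min_value=1e-6, max_value=1e-2),
           st.floats(min_value=0.0, max_value=5.0))
    def test_dimensional_scaling(self, m_w, m_fe, slope):
        s = SARInputs(mass_water=m_w, mass_iron=m_fe, initial_slope=slope)
        assert sar_from_curve(s) == pytest.approx(4.168 * m_w / m_fe * slope, rel=1e-12)

    def test_zero_iron_mass_rejected(self):
        with pytest.raises(ValueError):
            SARInputs(mass_water=0.14, mass_iron=0.0, initial_slope=0.5)


class TestActivationResponse:
    def test_fraction_linear_within_window(self):
        p = get_particle("synomag-S-90")
        lo, hi = p.activation_onset, p.activation_onset + p.activation_width
        assert p.active_fraction(lo - 5.0) == 0.0
        assert p.active_fraction(hi + 5.0) == 1.0
        assert p.active_fraction((lo + hi) / 2) == pytest.approx(0.5)
        # affine between the calibration temperatures
        f23, f34, f45 = (p.active_fraction(t) for t in (23.0, 34.0, 45.0))
        assert f34 == pytest.approx(0.5 * (f23 + f45), rel=1e-12)


class TestCatalog:
    def test_all_rows_present_and_valid(self):
        assert len(CATALOG) == 10
        for p in CATALOG.values():
            assert p.core_diameter < p.hydrodynamic_diameter
            assert p.stock_concentration > 0

    def test_lookup_by_product_code(self):
        assert get_particle("104-00-701").name == "synomag-D-70"
        with pytest.raises(KeyError):
            get_particle("unknown-thing")
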