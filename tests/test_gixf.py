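"""Fluorescence forward model, normalisation and derived ion quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gixref.gixf import (
    CA_KALPHA,
    K_KALPHA,
    MOLAR_TO_IONS_PER_A3,
    ConcentrationProfile,
    concentration,
    derive_metrics,
    enrichment,
    fluorescence_forward,
    ions_per_molecule,
    lateral_density,
    normalise_scan,
)
from gixref.optics import R_E, critical_angle
from gixref.synthetic import default_alpha_grid, potassium_profile

profiles = st.builds(
    ConcentrationProfile,
    c0=st.floats(0.0, 2.0),
    c_max=st.floats(0.0, 20.0),
    z_max=st.floats(0.5, 30.0),
    z_hc=st.floats(0.0, 20.0),
)


class TestConcentration:
    def test_anchor_points(self):
        p = ConcentrationProfile(c0=0.1, c_max=4.6, z_max=6.4, z_hc=10.6)
        assert concentration(p, p.z_hc) == pytest.approx(0.1)
        assert concentration(p, p.z_hc + p.z_max) == pytest.approx(0.1 + 4.6)
        assert concentration(p, p.z_hc + 50 * p.z_max) == pytest.approx(0.1)

    def test_hydrocarbon_region_excluded(self):
        p = ConcentrationProfile(c0=0.1, c_max=4.6, z_max=6.4, z_hc=10.6)
        z = np.linspace(0.0, 10.5, 20)
        assert np.all(concentration(p, z) == 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(profiles)
    def test_peak_identity(self, p):
        """argmax c(z) = z_HC + z_max and max = c0 + c_max, analytically."""
        z = np.linspace(p.z_hc, p.z_hc + 8 * p.z_max, 4001)
        c = concentration(p, z)
        assert c.max() <= p.c0 + p.c_max + 1e-9
        if p.c_max > 1e-6:
            assert z[np.argmax(c)] == pytest.approx(p.z_hc + p.z_max, abs=2 * (z[1] - z[0]))
            assert c.max() == pytest.approx(p.c0 + p.c_max, rel=1e-4)


class TestLateralDensity:
    def test_zero_excess(self):
        assert lateral_density(ConcentrationProfile(0.1, 0.0, 5.0, 10.0)) == 0.0

    def test_reported_potassium_value(self):
        """c_max = 4.6 M with a 5.7 Å width integrates to 2.6e14 ions/cm²."""
        p = ConcentrationProfile(c0=0.1, c_max=4.6, z_max=5.7, z_hc=10.6)
        assert lateral_density(p) == pytest.approx(2.6e14, rel=0.02)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(profiles)
    def test_closed_form_equals_quadrature(self, p):
        """c_max·√e·z_max equals the numeric excess integral to 1e-10."""
        closed = p.c_max * math.sqrt(math.e) * p.z_max
        num, _ = quad(
            lambda z: float(concentration(p, z) - p.c0),
            p.z_hc,
            p.z_hc + 40 * p.z_max,
            limit=200,
        )
        assert num == pytest.approx(closed, rel=1e-10, abs=1e-12)
        assert lateral_density(p) == pytest.approx(
            closed * MOLAR_TO_IONS_PER_A3 * 1e16, rel=1e-12
        )


class TestIonBookkeeping:
    def test_potassium_ions_per_molecule(self):
        assert ions_per_molecule(2.6e14, 210.0) == pytest.approx(5.5, abs=0.05)

    def test_bza_condition_ions_per_molecule(self):
        assert ions_per_molecule(2.9e14, 205.0) == pytest.approx(5.9, abs=0.05)

    def test_zero_density(self):
        assert ions_per_molecule(0.0, 210.0) == 0.0

    @pytest.mark.parametrize(
        "c_max,c0,expected", [(4.6, 0.1, 46.0), (0.0, 0.1, 0.0), (0.3, 0.3, 1.0)]
    )
    def test_enrichment(self, c_max, c0, expected):
        assert enrichment(c_max, c0) == pytest.approx(expected)

    def test_enrichment_requires_bulk(self):
        with pytest.raises(ValueError):
            enrichment(4.6, 0.0)

    def test_derive_metrics_consistency(self):
        p = potassium_profile()
        m = derive_metrics(p, area=210.0)
        assert m.n_per_molecule == pytest.approx(m.c_lateral * 210.0 * 1e-16)
        assert m.peak_depth == pytest.approx(17.0)
        assert m.enrichment == pytest.approx(46.0)


class TestForwardModel:
    def test_zero_concentration_gives_zero(self, beam8, lps_stack):
        p = ConcentrationProfile(c0=0.0, c_max=0.0, z_max=5.0, z_hc=lps_stack.z_hc)
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        out = fluorescence_forward(lps_stack, beam8, p, K_KALPHA, default_alpha_grid(ac))
        np.testing.assert_array_equal(out, 0.0)

    def test_uniform_bulk_closed_form_below_critical(self, beam8, water_interface):
        """Bare interface, c ≡ c0, β = 0: I(α) ∝ |T|²/(1/Λ + 1/L)."""
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = np.array([0.3, 0.5, 0.7, 0.9]) * ac
        p = ConcentrationProfile(c0=0.1, c_max=0.0, z_max=1.0, z_hc=0.0)
        out = fluorescence_forward(water_interface, beam8, p, K_KALPHA, alpha)
        kz1 = beam8.k * np.sin(alpha)
        kz2 = np.sqrt(kz1**2 - 4 * np.pi * R_E * 0.334 + 0j)
        t2 = np.abs(2 * kz1 / (kz1 + kz2)) ** 2
        lam = 1.0 / (2.0 * kz2.imag)
        closed = 0.1 * t2 / (1.0 / lam + 1.0 / K_KALPHA.attenuation_length_A)
        np.testing.assert_allclose(out, closed, rtol=1e-4)

    def test_linearity_in_concentration(self, beam8, lps_stack):
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = default_alpha_grid(ac)
        p1 = ConcentrationProfile(c0=0.1, c_max=4.6, z_max=6.4, z_hc=lps_stack.z_hc)
        p2 = ConcentrationProfile(c0=0.2, c_max=9.2, z_max=6.4, z_hc=lps_stack.z_hc)
        i1 = fluorescence_forward(lps_stack, beam8, p1, K_KALPHA, alpha)
        i2 = fluorescence_forward(lps_stack, beam8, p2, K_KALPHA, alpha)
        np.testing.assert_allclose(i2, 2.0 * i1, rtol=1e-9)

    def test_increasing_cmax_increases_intensity(self, beam8, lps_stack):
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = default_alpha_grid(ac)
        lo = ConcentrationProfile(c0=0.1, c_max=2.0, z_max=6.4, z_hc=lps_stack.z_hc)
        hi = ConcentrationProfile(c0=0.1, c_max=4.0, z_max=6.4, z_hc=lps_stack.z_hc)
        i_lo = fluorescence_forward(lps_stack, beam8, lo, K_KALPHA, alpha)
        i_hi = fluorescence_forward(lps_stack, beam8, hi, K_KALPHA, alpha)
        assert np.all(i_hi > i_lo)

    def test_surface_sensitivity_ratio(self, beam8, lps_stack):
        """A near-surface profile raises I(0.8α_c)/I(2α_c) above the
        uniform-bulk value — the qualitative signature of interfacial
        accumulation in the sub-critical counts."""
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = np.array([0.8 * ac, 2.0 * ac])
        surf = ConcentrationProfile(c0=0.1, c_max=4.6, z_max=5.0, z_hc=lps_stack.z_hc)
        bulk = ConcentrationProfile(c0=0.1, c_max=0.0, z_max=5.0, z_hc=lps_stack.z_hc)
        i_surf = fluorescence_forward(lps_stack, beam8, surf, K_KALPHA, alpha)
        i_bulk = fluorescence_forward(lps_stack, beam8, bulk, K_KALPHA, alpha)
        assert i_surf[0] / i_surf[1] > i_bulk[0] / i_bulk[1]


class TestNormalisation:
    def _alpha_and_ac(self):
        ac = critical_angle(0.334, 1.55).alpha_c
        return default_alpha_grid(ac), ac

    def test_scale_invariance(self):
        alpha, ac = self._alpha_and_ac()
        raw = 1.0 + np.linspace(0, 1, alpha.size)
        a = normalise_scan(raw, alpha, ac).intensity
        b = normalise_scan(10.0 * raw, alpha, ac).intensity
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_idempotence(self):
        alpha, ac = self._alpha_and_ac()
        raw = 1.0 + np.linspace(0, 1, alpha.size)
        once = normalise_scan(raw, alpha, ac).intensity
        twice = normalise_scan(once, alpha, ac).intensity
        np.testing.assert_allclose(once, twice, rtol=1e-14)

    def test_high_angle_plateau_is_unity(self):
        alpha, ac = self._alpha_and_ac()
        raw = np.full(alpha.size, 7.3)
        scan = normalise_scan(raw, alpha, ac)
        assert np.mean(scan.intensity[alpha > 1.5 * ac]) == pytest.approx(1.0)

    def test_requires_high_angle_points(self):
        ac = critical_angle(0.334, 1.55).alpha_c
        alpha = np.linspace(0.2, 0.9, 10) * ac
        with pytest.raises(ValueError):
            normalise_scan(np.ones(10), alpha, ac)

    def test_errors_scaled_identically(self):
        alpha, ac = self._alpha_and_ac()
        raw = 2.0 * np.ones(alpha.size)
        scan = normalise_scan(raw, alpha, ac, error=0.1 * raw)
        # plateau mean is 2.0, so errors 0.2 -> 0.1 after normalisation
        np.testing.assert_allclose(scan.error, 0.1, rtol=1e-12)
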