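"""Optical constants, Parratt reflectivity and illumination profiles."""

import math

import numpy as np
import pytest

from gixref.optics import (
    R_E,
    Beam,
    Slab,
    SlabStack,
    _field_amplitudes,
    critical_angle,
    electron_density_profile,
    illumination,
    reflectivity,
    wavelength_from_energy,
)
from gixref.synthetic import table_stacks


@pytest.mark.parametrize(
    "energy,expected,sig",
    [(8.0, 1.55, 3), (10.0, 1.24, 3), (12.39842, 1.0, 6)],
)
def test_wavelength_from_energy(energy, expected, sig):
    lam = wavelength_from_energy(energy)
    assert lam == pytest.approx(expected, rel=10 ** (-sig) * 5)


def test_wavelength_rejects_nonpositive_energy():
    with pytest.raises(ValueError):
        wavelength_from_energy(0.0)
    with pytest.raises(ValueError):
        wavelength_from_energy(-8.0)


def test_beam_requires_exactly_one_of_energy_wavelength():
    with pytest.raises(ValueError):
        Beam()
    with pytest.raises(ValueError):
        Beam(energy=8.0, wavelength=1.55)
    assert Beam(wavelength=1.55).energy == pytest.approx(12.39842 / 1.55)


class TestCriticalAngle:
    def test_aqueous_subphase_at_8kev(self):
        """Water-like subphase (0.334 é/Å) at λ = 1.55 Å."""
        ca = critical_angle(0.334, 1.55)
        assert math.degrees(ca.alpha_c) == pytest.approx(0.154, abs=5e-4)
        assert ca.q_c == pytest.approx(0.022, abs=5e-4)

    def test_no_contrast_no_total_reflection(self):
        assert critical_angle(0.0, 1.55).alpha_c == 0.0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            critical_angle(-0.1, 1.55)


class TestElectronDensityProfile:
    def test_asymptotes(self, lps_stack):
        z = np.array([-200.0, 500.0])
        rho = electron_density_profile(lps_stack, z)
        assert rho[0] == pytest.approx(0.0, abs=1e-12)
        assert rho[1] == pytest.approx(0.334, abs=1e-12)

    def test_midpoint_at_isolated_interface(self):
        stack = SlabStack(
            slabs=(), subphase=Slab(thickness=math.inf, rho=0.334, sigma=2.0)
        )
        rho = electron_density_profile(stack, np.array([0.0]))
        assert rho[0] == pytest.approx(0.334 / 2)


class TestReflectivity:
    def test_no_contrast_gives_zero(self, beam8, q_grid):
        stack = SlabStack(
            slabs=(Slab(thickness=20.0, rho=0.0, sigma=3.0),),
            subphase=Slab(thickness=math.inf, rho=0.0, sigma=3.0),
        )
        assert np.all(reflectivity(stack, beam8, q_grid).R == 0.0)

    def test_fresnel_closed_form_single_interface(self, beam8, water_interface, q_grid):
        """Parratt on one sharp interface equals the Fresnel formula exactly."""
        R = reflectivity(water_interface, beam8, q_grid).R
        kz1 = q_grid / 2.0
        kz2 = np.sqrt(kz1**2 - 4.0 * np.pi * R_E * 0.334 + 0j)
        fresnel = np.abs((kz1 - kz2) / (kz1 + kz2)) ** 2
        np.testing.assert_allclose(R, fresnel, rtol=1e-12)

    def test_total_reflection_below_qc(self, beam8, lps_stack):
        """Absorption-free stacks reflect totally below the subphase q_c."""
        stack = SlabStack(
            slabs=lps_stack.slabs,
            subphase=Slab(thickness=math.inf, rho=0.334, sigma=6.8, beta=0.0),
        )
        qc = critical_angle(0.334, beam8.wavelength).q_c
        q = np.linspace(0.002, 0.95 * qc, 40)
        np.testing.assert_allclose(reflectivity(stack, beam8, q).R, 1.0, atol=1e-9)

    def test_roughness_monotonically_damps_single_interface(self, beam8, q_grid):
        """At fixed q > q_c, increasing sigma never increases the Fresnel
        reflectivity of an interface (Névot–Croce damping is monotone)."""
        q = q_grid[q_grid > 0.03]
        prev = None
        for sigma in (0.0, 2.0, 4.0, 8.0):
            stack = SlabStack(
                slabs=(), subphase=Slab(thickness=math.inf, rho=0.334, sigma=sigma)
            )
            R = reflectivity(stack, beam8, q).R
            if prev is not None:
                assert np.all(R <= prev * (1 + 1e-12))
            prev = R

    def test_roughness_damps_stack_reflectivity_overall(self, beam8, lps_stack, q_grid):
        """For a multilayer, damping one interface's amplitude can raise R
        pointwise at Kiessig minima (interference), but the q-integrated
        reflectivity above q_c still decreases with any added roughness."""
        from dataclasses import replace

        q = q_grid[q_grid > 0.05]
        base = np.trapezoid(reflectivity(lps_stack, beam8, q).R, q)
        for target in range(3):
            if target < 2:
                slabs = list(lps_stack.slabs)
                slabs[target] = replace(slabs[target], sigma=slabs[target].sigma + 2.0)
                bumped = replace(lps_stack, slabs=tuple(slabs))
            else:
                bumped = replace(
                    lps_stack,
                    subphase=replace(lps_stack.subphase, sigma=lps_stack.subphase.sigma + 2.0),
                )
            assert np.trapezoid(reflectivity(bumped, beam8, q).R, q) < base

    def test_energy_wavelength_reciprocity(self, lps_stack, q_grid):
        """E = 8 keV and the equivalent λ give bit-identical curves."""
        lam = wavelength_from_energy(8.0)
        r_e = reflectivity(lps_stack, Beam(energy=8.0), q_grid).R
        r_l = reflectivity(lps_stack, Beam(wavelength=lam), q_grid).R
        assert np.array_equal(r_e, r_l)

    def test_rejects_nonpositive_q(self, beam8, water_interface):
        with pytest.raises(ValueError):
            reflectivity(water_interface, beam8, np.array([-0.1, 0.1]))


def _microslice(stack, dz=0.25, pad=6.0):
    """Slice the erf-smeared density profile into sharp micro-slabs."""
    z_hi = stack.interface_depths[-1] + pad * stack.sigmas.max()
    z_lo = -pad * stack.sigmas[0]
    edges = np.arange(z_lo, z_hi + dz, dz)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho = electron_density_profile(stack, centres)
    slabs = tuple(Slab(thickness=dz, rho=max(r, 0.0), sigma=0.0) for r in rho)
    return SlabStack(
        slabs=slabs,
        subphase=Slab(
            thickness=math.inf, rho=stack.subphase.rho, sigma=0.0, beta=stack.subphase.beta
        ),
    )


class TestProfileCurveConsistency:
    def test_isolated_rough_interface(self, beam8):
        """Micro-sliced erf profile reproduces Névot–Croce where its
        single-interface assumption holds."""
        stack = SlabStack(
            slabs=(), subphase=Slab(thickness=math.inf, rho=0.334, sigma=3.0)
        )
        q = np.linspace(0.03, 0.5, 50)
        r_nc = reflectivity(stack, beam8, q).R
        r_sl = reflectivity(_microslice(stack, dz=0.1), beam8, q).R
        np.testing.assert_allclose(r_sl, r_nc, rtol=0.01)

    @pytest.mark.parametrize("name", ["ca_free", "ca_loaded"])
    def test_monolayer_stacks_envelope(self, beam8, name):
        """On the monolayer models the interfaces' Gaussian tails overlap, so
        NC (independent interfaces) and the exact smeared profile drift apart
        at high q; the deviation stays bounded."""
        stack = table_stacks()[name]
        q = np.linspace(0.03, 0.5, 50)
        r_nc = reflectivity(stack, beam8, q).R
        r_sl = reflectivity(_microslice(stack), beam8, q).R
        np.testing.assert_allclose(r_sl, r_nc, rtol=0.15)


class TestIllumination:
    def test_transmission_peak_at_critical_angle(self, beam8, water_interface):
        """|T|² = 4 exactly at α_c for an absorption-free interface.

        α_c = √(2δ) is the small-angle form; the field solver uses exact
        sin α, so the test evaluates at the exact zero of k_z,sub."""
        ac = math.asin(math.sqrt(4.0 * math.pi * R_E * 0.334) / beam8.k)
        prof = illumination(water_interface, beam8, [ac], [0.0])
        assert prof.intensity[0, 0] == pytest.approx(4.0, abs=1e-6)
        # and the small-angle alpha_c is the same angle to ~1e-6 relative
        assert critical_angle(0.334, beam8.wavelength).alpha_c == pytest.approx(ac, rel=1e-5)

    def test_half_critical_angle_closed_form(self, beam8, water_interface):
        """I(0⁺) = 4α²/α_c² at α = α_c/2 (β = 0)."""
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        prof = illumination(water_interface, beam8, [ac / 2.0], [0.0])
        assert prof.intensity[0, 0] == pytest.approx(1.0, rel=1e-3)

    def test_evanescent_decay_constant(self, beam8, lps_stack):
        """Deep-subphase decay matches Λ = 1/(2 Im k_z,sub) to 1e-6."""
        from dataclasses import replace

        stack = replace(lps_stack, subphase=replace(lps_stack.subphase, beta=0.0))
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = 0.8 * ac
        deep = stack.interface_depths[-1]
        z = np.array([deep + 50.0, deep + 150.0])
        prof = illumination(stack, beam8, [alpha], z)
        lam_measured = (z[1] - z[0]) / np.log(prof.intensity[0, 0] / prof.intensity[1, 0])
        kz0 = beam8.k * math.sin(alpha)
        kz_sub = np.sqrt(complex(kz0**2 - 4.0 * math.pi * R_E * 0.334))
        lam_expected = 1.0 / (2.0 * kz_sub.imag)
        assert lam_measured == pytest.approx(lam_expected, rel=1e-6)

    def test_unit_intensity_well_above_critical_angle(self, beam8, water_interface):
        """For α >> α_c the interface is transparent: I -> 1 at all depths."""
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        prof = illumination(water_interface, beam8, [20 * ac], np.linspace(0, 500, 50))
        np.testing.assert_allclose(prof.intensity[:, 0], 1.0, atol=0.05)

    def test_flux_conservation_single_interface(self, beam8, water_interface):
        """|r|² + Re(kz_t/kz_i)·|t|² = 1 for the absorption-free interface."""
        ac = critical_angle(0.334, beam8.wavelength).alpha_c
        alpha = np.array([1.5 * ac, 3 * ac, 10 * ac])
        kz, A, B = _field_amplitudes(water_interface, beam8, alpha)
        r2 = np.abs(B[0] / A[0]) ** 2
        t2 = np.abs(A[1] / A[0]) ** 2
        flux = r2 + np.real(kz[1] / kz[0]) * t2
        np.testing.assert_allclose(flux, 1.0, atol=1e-10)

    def test_rejects_zero_angle(self, beam8, water_interface):
        with pytest.raises(ValueError):
            illumination(water_interface, beam8, [0.0], [1.0])
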