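"""X-ray optics for stratified liquid interfaces.

Slab (box) models of a monolayer on a semi-infinite subphase, specular
reflectivity by the Parratt recursion with Névot–Croce roughness damping,
and depth-resolved illumination intensity by 2x2 transfer-matrix propagation
of the plane-wave amplitudes.

Conventions
-----------
* z = 0 at the interface between the incident medium (air) and the first
  slab; z increases into the subphase.  Air occupies z < 0.
* All angles are in radians internally; q_z = (4*pi/lambda)*sin(alpha)
  with no small-angle approximation.
* A slab's roughness sigma describes its UPPER interface (toward air).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.special import erf

__all__ = [
    "HC_KEV_ANGSTROM",
    "R_E",
    "Beam",
    "Slab",
    "SlabStack",
    "OpticalConstants",
    "ReflectivityCurve",
    "IlluminationProfile",
    "CriticalAngle",
    "wavelength_from_energy",
    "energy_from_wavelength",
    "critical_angle",
    "optical_constants",
    "electron_density_profile",
    "reflectivity",
    "illumination",
    "q_from_alpha",
    "alpha_from_q",
]

#: hc in keV * Angstrom
HC_KEV_ANGSTROM = 12.39842
#: classical electron radius in Angstrom
R_E = 2.8179403e-5


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in Å from energy in keV (λ = hc/E)."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def energy_from_wavelength(wavelength_A: float) -> float:
    """Photon energy in keV from wavelength in Å."""
    if wavelength_A <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_A}")
    return HC_KEV_ANGSTROM / wavelength_A


@dataclass(frozen=True)
class Beam:
    """Monochromatic X-ray beam.

    Exactly one of ``energy`` (keV) or ``wavelength`` (Å) is supplied; the
    other is derived through λ = hc/E with hc = 12.39842 keV·Å.
    """

    energy: float = None  # keV
    wavelength: float = None  # Å

    def __post_init__(self):
        if (self.energy is None) == (self.wavelength is None):
            raise ValueError("supply exactly one of energy or wavelength")
        if self.energy is None:
            object.__setattr__(self, "energy", energy_from_wavelength(self.wavelength))
        else:
            object.__setattr__(self, "wavelength", wavelength_from_energy(self.energy))

    @property
    def k(self) -> float:
        """Vacuum wavenumber 2π/λ in Å⁻¹."""
        return 2.0 * math.pi / self.wavelength


@dataclass(frozen=True)
class Slab:
    """One homogeneous layer: thickness d (Å), electron density rho (é Å⁻³),
    Gaussian roughness sigma (Å) of its upper interface, and absorption
    index beta (dimensionless, default 0)."""

    thickness: float
    rho: float
    sigma: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        if not self.thickness > 0:
            raise ValueError(f"slab thickness must be positive, got {self.thickness}")
        if self.rho < 0:
            raise ValueError(f"electron density must be >= 0, got {self.rho}")
        if self.sigma < 0:
            raise ValueError(f"roughness must be >= 0, got {self.sigma}")
        if self.beta < 0:
            raise ValueError(f"absorption beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class SlabStack:
    """Ordered layer model: incident medium / finite slabs / semi-infinite subphase.

    ``slabs`` are listed top (air side) to bottom.  The subphase is a Slab
    whose thickness must be infinite; its sigma is the roughness of the
    deepest interface.
    """

    slabs: tuple[Slab, ...]
    subphase: Slab
    rho_incident: float = 0.0
    beta_incident: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "slabs", tuple(self.slabs))
        if not math.isinf(self.subphase.thickness):
            raise ValueError("subphase thickness must be infinite")
        if self.rho_incident < 0:
            raise ValueError("incident-medium density must be >= 0")

    @property
    def interface_depths(self) -> np.ndarray:
        """Depths z_j of the interfaces, z_0 = 0 at air/first slab."""
        d = [s.thickness for s in self.slabs]
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def z_hc(self) -> float:
        """Depth of the first buried interface — for a chains/head-group
        monolayer this is the hydrocarbon/head interface the ion profile
        references."""
        if not self.slabs:
            return 0.0
        return self.slabs[0].thickness

    @property
    def rhos(self) -> np.ndarray:
        """Electron densities from incident medium to subphase."""
        return np.array(
            [self.rho_incident] + [s.rho for s in self.slabs] + [self.subphase.rho]
        )

    @property
    def betas(self) -> np.ndarray:
        return np.array(
            [self.beta_incident] + [s.beta for s in self.slabs] + [self.subphase.beta]
        )

    @property
    def sigmas(self) -> np.ndarray:
        """Roughness of interface j (between layer j and j+1), j = 0..n."""
        return np.array([s.sigma for s in self.slabs] + [self.subphase.sigma])

    def with_subphase_beta(self, beta: float) -> "SlabStack":
        return replace(self, subphase=replace(self.subphase, beta=beta))


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive index decrement n = 1 - delta + i*beta."""

    delta: float
    beta: float


def optical_constants(rho: float, wavelength: float, beta: float = 0.0) -> OpticalConstants:
    """delta = r_e λ² ρ / (2π) for electron density rho (é Å⁻³)."""
    delta = R_E * wavelength**2 * rho / (2.0 * math.pi)
    return OpticalConstants(delta=delta, beta=beta)


class CriticalAngle(NamedTuple):
    alpha_c: float  # rad
    q_c: float  # Å⁻¹


def critical_angle(rho_sub: float, wavelength: float) -> CriticalAngle:
    """Critical angle of total external reflection and critical q.

    alpha_c = sqrt(2*delta) = λ sqrt(r_e ρ / π); q_c = (4π/λ) sin(alpha_c).
    For an aqueous subphase (ρ = 0.334 é Å⁻³) at 8 keV this gives
    alpha_c = 0.154° and q_c = 0.022 Å⁻¹.
    """
    if rho_sub < 0:
        raise ValueError(f"subphase density must be >= 0, got {rho_sub}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    alpha_c = wavelength * math.sqrt(R_E * rho_sub / math.pi)
    q_c = 4.0 * math.pi / wavelength * math.sin(alpha_c)
    return CriticalAngle(alpha_c=alpha_c, q_c=q_c)


def q_from_alpha(alpha, wavelength: float):
    """q_z = (4π/λ) sin α, exact."""
    return 4.0 * math.pi / wavelength * np.sin(alpha)


def alpha_from_q(q, wavelength: float):
    """Inverse of :func:`q_from_alpha`."""
    return np.arcsin(np.asarray(q) * wavelength / (4.0 * math.pi))


@dataclass
class ReflectivityCurve:
    """Specular reflectivity R(q_z) with optional 1-sigma uncertainties."""

    q: np.ndarray
    R: np.ndarray
    dR: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.dR is not None:
            self.dR = np.asarray(self.dR, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("q grid must be positive")
        if np.any(self.R < 0):
            raise ValueError("reflectivity must be non-negative")


def electron_density_profile(stack: SlabStack, z) -> np.ndarray:
    """Laterally averaged electron density ρ(z) of the roughness-smeared stack.

    ρ(z) = ρ_inc + Σ_j Δρ_j · ½[1 + erf((z − z_j)/(√2 σ_j))], summed over
    interfaces j at cumulative depths z_j.
    """
    z = np.asarray(z, dtype=float)
    rhos = stack.rhos
    sigmas = stack.sigmas
    depths = stack.interface_depths
    rho = np.full_like(z, stack.rho_incident, dtype=float)
    for j in range(len(sigmas)):
        drho = rhos[j + 1] - rhos[j]
        s = sigmas[j]
        if s > 0:
            step = 0.5 * (1.0 + erf((z - depths[j]) / (math.sqrt(2.0) * s)))
        else:
            step = np.where(z > depths[j], 1.0, np.where(z < depths[j], 0.0, 0.5))
        rho = rho + drho * step
    return rho


def _kz_layers(stack: SlabStack, beam: Beam, kz0: np.ndarray) -> np.ndarray:
    """Vertical wavevector in every layer, shape (n_layers, n_angles).

    k_z,j = sqrt(k_z0² − 4π r_e (ρ_j − ρ_0) + 2i k² (β_j − β_0)); the branch
    with Im k_z ≥ 0 (decay with depth) is taken.
    """
    k = beam.k
    rhos = stack.rhos
    betas = stack.betas
    kz2 = (
        kz0[None, :] ** 2
        - 4.0 * math.pi * R_E * (rhos[:, None] - rhos[0])
        + 2j * k**2 * (betas[:, None] - betas[0])
    )
    kz = np.sqrt(kz2.astype(complex))
    return np.where(kz.imag < 0, -kz, kz)


def reflectivity(stack: SlabStack, beam: Beam, q) -> ReflectivityCurve:
    """Specular reflectivity by the Parratt recursion.

    Fresnel coefficients at each interface are damped by the Névot–Croce
    factor exp(−2 k_{z,j} k_{z,j+1} σ²) for Gaussian interfacial roughness.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q values must be positive")
    kz0 = q / 2.0
    kz = _kz_layers(stack, beam, kz0)  # (n_layers, n_q)
    sig = stack.sigmas
    d = np.array([s.thickness for s in stack.slabs])
    n_int = kz.shape[0] - 1

    r_eff = np.zeros_like(kz0, dtype=complex)
    for j in range(n_int - 1, -1, -1):
        denom = kz[j] + kz[j + 1]
        # same optical density on both sides -> no interface
        r_f = np.divide(
            kz[j] - kz[j + 1], denom, out=np.zeros_like(r_eff), where=denom != 0
        )
        r_f = r_f * np.exp(-2.0 * kz[j] * kz[j + 1] * sig[j] ** 2)
        if j < n_int - 1:
            phase = np.exp(2j * kz[j + 1] * d[j])
        else:
            phase = 0.0  # nothing below the deepest interface
        num = r_f + r_eff * phase
        den = 1.0 + r_f * r_eff * phase
        r_eff = num / den
    R = np.abs(r_eff) ** 2
    return ReflectivityCurve(q=q, R=R)


@dataclass
class IlluminationProfile:
    """Squared field amplitude I_ill(z, alpha) normalised to unit incidence.

    ``intensity`` has shape (len(z), len(alpha)).
    """

    z: np.ndarray
    alpha: np.ndarray
    intensity: np.ndarray
    #: 1/e penetration depth of the intensity in the subphase per angle (Å)
    penetration_depth: np.ndarray = field(default=None)


def _field_amplitudes(stack: SlabStack, beam: Beam, alpha: np.ndarray):
    """Down/up plane-wave amplitudes (A_j, B_j) at the top of every layer.

    Sharp-interface matching (roughness is a reflectivity-level correction
    and is not applied to the internal field).  The substrate up-going
    amplitude is identically zero by construction.

    Returns (kz, A, B), each shaped (n_layers, n_alpha); layer 0 is the
    incident medium referenced to z = 0.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any(alpha <= 0):
        raise ValueError("incidence angle must be positive")
    k = beam.k
    kz0 = k * np.sin(alpha)
    kz = _kz_layers(stack, beam, kz0)
    d = np.array([s.thickness for s in stack.slabs])
    n_lay = kz.shape[0]

    # Parratt ratios X_j = B_j / A_j at the top of each layer (sharp sigma=0)
    X = [None] * n_lay
    X[-1] = np.zeros_like(kz0, dtype=complex)
    for j in range(n_lay - 2, -1, -1):
        denom = kz[j] + kz[j + 1]
        r_f = np.divide(
            kz[j] - kz[j + 1], denom,
            out=np.zeros(denom.shape, complex), where=denom != 0,
        )
        if j + 1 < n_lay - 1:
            phase = np.exp(2j * kz[j + 1] * d[j])
        else:
            phase = 0.0
        X[j] = (r_f + X[j + 1] * phase) / (1.0 + r_f * X[j + 1] * phase)

    A = np.zeros((n_lay, alpha.size), dtype=complex)
    B = np.zeros_like(A)
    A[0] = 1.0
    B[0] = X[0]
    tiny = 1e-12 * k
    for j in range(n_lay - 1):
        if j == 0:
            a, b = A[0], B[0]  # incident medium referenced at z = 0
        else:
            a = A[j] * np.exp(1j * kz[j] * d[j - 1])
            b = B[j] * np.exp(-1j * kz[j] * d[j - 1])
        kj, kn = kz[j], kz[j + 1]
        degenerate = np.abs(kn) < tiny
        kn_safe = np.where(degenerate, 1.0, kn)
        A_next = ((kn_safe + kj) * a + (kn_safe - kj) * b) / (2.0 * kn_safe)
        B_next = ((kn_safe - kj) * a + (kn_safe + kj) * b) / (2.0 * kn_safe)
        # kz -> 0 (exactly at the critical angle, beta = 0): the field in the
        # next layer is locally constant, E = a + b
        A_next = np.where(degenerate, 0.5 * (a + b), A_next)
        B_next = np.where(degenerate, 0.5 * (a + b), B_next)
        A[j + 1] = A_next
        B[j + 1] = B_next
    B[-1] = 0.0  # semi-infinite subphase carries no up-going wave
    return kz, A, B


def illumination(stack: SlabStack, beam: Beam, alpha, z) -> IlluminationProfile:
    """Depth-resolved illumination intensity I_ill(z, alpha) = |E(z)|².

    Transfer-matrix propagation of the transmitted/reflected plane-wave
    amplitudes through the slab system, normalised to unit incident
    intensity.  Below the critical angle the profile in the deep subphase
    decays as exp(−z/Λ) with Λ = 1/(2 Im k_z,sub).
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    kz, A, B = _field_amplitudes(stack, beam, alpha)
    depths = stack.interface_depths  # tops of layers 1..n at depths[0..n-1]
    n_lay = kz.shape[0]

    intensity = np.empty((z.size, alpha.size), dtype=float)
    # layer index for every z: 0 = incident medium (z < 0), j >= 1 buried
    layer_of = np.searchsorted(depths, z, side="right")  # 0 for z<0, else slab idx+1
    for j in range(n_lay):
        mask = layer_of == j
        if not np.any(mask):
            continue
        zref = 0.0 if j == 0 else depths[j - 1]
        zeta = (z[mask] - zref)[:, None]
        E = A[j][None, :] * np.exp(1j * kz[j][None, :] * zeta) + B[j][None, :] * np.exp(
            -1j * kz[j][None, :] * zeta
        )
        intensity[mask, :] = np.abs(E) ** 2
    with np.errstate(divide="ignore"):
        pen = np.where(kz[-1].imag > 0, 1.0 / (2.0 * kz[-1].imag), np.inf)
    return IlluminationProfile(z=z, alpha=alpha, intensity=intensity, penetration_depth=pen)
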