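"""Synthetic beamline-like data and reference fixtures.

Generates reflectivity curves, fluorescence angle scans and energy-dispersive
spectra with realistic counting statistics, so the whole pipeline can be
exercised and validated without measured data.  Also ships the reference
slab models of an LPS Ra monolayer (alkyl chains / saccharide head group on
an aqueous subphase) under eight buffer/antimicrobial conditions, and the
interfacial K⁺ and Ca²⁺ concentration profiles of the intact monolayers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .gixf import (
    CA_KALPHA,
    K_KALPHA,
    MOLAR_TO_IONS_PER_A3,
    ConcentrationProfile,
    EmissionLine,
    FluorescenceScan,
    fluorescence_forward,
    normalise_scan,
)
from .optics import Beam, ReflectivityCurve, Slab, SlabStack, critical_angle, reflectivity
from .spectra import DEFAULT_SIGMA_E, FluorescenceSpectrum

__all__ = [
    "NoiseModel",
    "table_stacks",
    "potassium_profile",
    "calcium_profile",
    "default_q_grid",
    "default_alpha_grid",
    "simulate_xrr",
    "simulate_gixf_scan",
    "simulate_spectrum",
    "export_fixtures",
]

#: subphase absorption index at 8 keV (water-like)
WATER_BETA_8KEV = 4.6e-8


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise description for simulated observables.

    kind = "poisson-count": ``scale`` is the incident-count level — the
    expected counts where the observable equals 1 (the total-reflection
    plateau for XRR).
    kind = "gaussian-relative": ``scale`` is the relative 1-sigma error.
    """

    kind: str
    scale: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("poisson-count", "gaussian-relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("noise scale must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (noisy values, 1-sigma errors)."""
        y = np.asarray(y, dtype=float)
        rng = self.rng()
        if self.kind == "poisson-count":
            counts = rng.poisson(np.maximum(y * self.scale, 0.0))
            noisy = counts / self.scale
            err = np.sqrt(np.maximum(counts, 1.0)) / self.scale
        else:
            err = self.scale * np.abs(y)
            noisy = np.maximum(y + rng.normal(0.0, 1.0, size=y.shape) * err, 0.0)
        return noisy, err


# (d [Å], rho [é/Å³], sigma [Å]) per row: alkyl chains, head group, subphase
_TABLE_ROWS = {
    # Ca²⁺-free buffer (100 mM KCl)
    "ca_free": ((10.6, 0.326, 3.4), (24.0, 0.483, 3.9), (0.334, 6.8)),
    "ca_free_bza": ((10.8, 0.323, 3.9), (24.3, 0.472, 5.6), (0.334, 6.5)),
    "ca_free_bac": ((11.9, 0.377, 5.0), (21.6, 0.356, 7.3), (0.334, 4.3)),
    "ca_free_bac_bza": ((11.7, 0.356, 4.6), (20.6, 0.360, 4.9), (0.334, 5.7)),
    # Ca²⁺-loaded buffer (50 mM CaCl₂)
    "ca_loaded": ((12.4, 0.319, 3.3), (24.6, 0.525, 3.7), (0.334, 6.7)),
    "ca_loaded_bza": ((12.7, 0.348, 3.7), (23.0, 0.525, 3.7), (0.334, 6.8)),
    "ca_loaded_bac": ((12.1, 0.292, 3.7), (23.7, 0.460, 4.2), (0.334, 7.2)),
    "ca_loaded_bac_bza": ((10.2, 0.313, 4.0), (22.9, 0.437, 6.2), (0.334, 7.9)),
}


def table_stacks(subphase_beta: float = WATER_BETA_8KEV) -> dict[str, SlabStack]:
    """Reference two-slab models of the LPS Ra monolayer, keyed by condition
    (``ca_free``, ``ca_loaded``, with ``_bza``/``_bac``/``_bac_bza`` suffixes
    for 100 mM benzyl alcohol and/or 5 µM benzalkonium chloride)."""
    out = {}
    for name, (chains, head, (rho_sub, sig_sub)) in _TABLE_ROWS.items():
        out[name] = SlabStack(
            slabs=(
                Slab(thickness=chains[0], rho=chains[1], sigma=chains[2]),
                Slab(thickness=head[0], rho=head[1], sigma=head[2]),
            ),
            subphase=Slab(
                thickness=math.inf, rho=rho_sub, sigma=sig_sub, beta=subphase_beta
            ),
        )
    return out


def potassium_profile(reading: str = "peak-includes-chains") -> ConcentrationProfile:
    """Interfacial K⁺ profile of the intact monolayer on 100 mM KCl.

    The peak depth of 17 Å is quoted from the air/chain interface; with the
    fitted alkyl thickness z_HC = 10.6 Å this gives z_max = 6.4 Å
    (``reading="peak-includes-chains"``, default).  The alternative literal
    reading ``"raw"`` takes z_max = 17 Å outright; the source statement is
    ambiguous, so both are available.
    """
    z_hc = _TABLE_ROWS["ca_free"][0][0]
    if reading == "peak-includes-chains":
        z_max = 17.0 - z_hc
    elif reading == "raw":
        z_max = 17.0
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return ConcentrationProfile(c0=0.1, c_max=4.6, z_max=z_max, z_hc=z_hc)


def calcium_profile() -> ConcentrationProfile:
    """Interfacial Ca²⁺ profile of the intact monolayer on 50 mM CaCl₂.

    The peak amplitude is not tabulated anywhere; it is reconstructed from
    the reported lateral density c_L = 2.5e14 ions/cm² through the closed
    form c_L = c_max √e z_max, with the peak depth 19 Å and the fitted alkyl
    thickness z_HC = 12.4 Å.
    """
    z_hc = _TABLE_ROWS["ca_loaded"][0][0]
    z_max = 19.0 - z_hc
    c_l_per_A2 = 2.5e14 / 1e16
    c_max = c_l_per_A2 / (math.sqrt(math.e) * z_max * MOLAR_TO_IONS_PER_A3)
    return ConcentrationProfile(c0=0.05, c_max=c_max, z_max=z_max, z_hc=z_hc)


def default_q_grid(n: int = 200) -> np.ndarray:
    """Default specular scan range, 0.02–0.6 Å⁻¹."""
    return np.linspace(0.02, 0.6, n)


def default_alpha_grid(alpha_c: float, n_sub: int = 31, n_super: int = 10) -> np.ndarray:
    """Default fluorescence angle scan: dense from 0.2·α_c to 1.2·α_c (the
    depth-sensitive evanescent region), sparser up to 3·α_c for the bulk
    plateau — the sampling strategy of an angle scan across total
    reflection."""
    return np.concatenate(
        [
            np.linspace(0.2 * alpha_c, 1.2 * alpha_c, n_sub),
            np.linspace(1.3 * alpha_c, 3.0 * alpha_c, n_super),
        ]
    )


def simulate_xrr(
    stack: SlabStack, beam: Beam, q, noise: NoiseModel | None = None
) -> ReflectivityCurve:
    """Forward reflectivity with counting noise; δR from the noise model."""
    clean = reflectivity(stack, beam, q)
    if noise is None:
        return clean
    noisy, err = noise.apply(clean.R)
    return ReflectivityCurve(q=clean.q, R=noisy, dR=err)


def simulate_gixf_scan(
    stack: SlabStack,
    beam: Beam,
    profile: ConcentrationProfile,
    line: EmissionLine,
    alpha=None,
    noise: NoiseModel | None = None,
) -> FluorescenceScan:
    """Simulated normalised fluorescence angle scan for one emission line."""
    alpha_c = critical_angle(stack.subphase.rho, beam.wavelength).alpha_c
    if alpha is None:
        alpha = default_alpha_grid(alpha_c)
    raw = fluorescence_forward(stack, beam, profile, line, alpha)
    if noise is None:
        err = None
    else:
        raw, err = noise.apply(raw)
    return normalise_scan(raw, alpha, alpha_c, error=err, line=line, beam=beam)


def simulate_spectrum(
    lines: list[EmissionLine],
    areas: list[float],
    energy=None,
    resolution: float = DEFAULT_SIGMA_E,
    background: tuple[float, float] = (0.0, 20.0),
    seed: int | None = 0,
    alpha: float | None = None,
) -> FluorescenceSpectrum:
    """Energy-dispersive spectrum: Gaussian lines on a linear background.

    ``areas`` are integrated counts per line; ``background`` is (slope,
    intercept) in counts/keV and counts.  ``seed=None`` returns the
    noise-free expectation; otherwise counts are Poisson sampled.
    """
    if len(lines) != len(areas):
        raise ValueError("one area per line required")
    if energy is None:
        energy = np.arange(2.5, 4.5, 0.01)
    energy = np.asarray(energy, dtype=float)
    bin_w = float(np.median(np.diff(energy)))
    slope, intercept = background
    model = np.maximum(slope * energy + intercept, 0.0)
    for line, area in zip(lines, areas):
        model = model + (
            area
            * bin_w
            / (resolution * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * ((energy - line.energy) / resolution) ** 2)
        )
    if seed is None:
        counts = model
    else:
        counts = np.random.default_rng(seed).poisson(model).astype(float)
    return FluorescenceSpectrum(energy=energy, counts=counts, alpha=alpha)


def export_fixtures(directory, beam: Beam | None = None, seed: int = 0) -> list[Path]:
    """Write all fixture stacks and profiles, plus one simulated dataset per
    intact condition, in the package's standard text formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if beam is None:
        beam = Beam(energy=8.0)
    written = []
    stacks = table_stacks()
    for name, stack in stacks.items():
        p = directory / f"stack_{name}.toml"
        gio.write_stack_toml(p, stack)
        written.append(p)
    profiles = {"potassium_intact": potassium_profile(), "calcium_intact": calcium_profile()}
    for name, prof in profiles.items():
        p = directory / f"profile_{name}.dat"
        gio.write_profile(p, prof)
        written.append(p)
    conditions = {
        "ca_free": ("potassium_intact", K_KALPHA),
        "ca_loaded": ("calcium_intact", CA_KALPHA),
    }
    for cond, (prof_name, line) in conditions.items():
        stack = stacks[cond]
        curve = simulate_xrr(
            stack, beam, default_q_grid(), NoiseModel("poisson-count", 1e6, seed)
        )
        p = directory / f"xrr_{cond}.dat"
        gio.write_reflectivity(p, curve)
        written.append(p)
        scan = simulate_gixf_scan(
            stack,
            beam,
            profiles[prof_name],
            line,
            noise=NoiseModel("gaussian-relative", 0.03, seed + 1),
        )
        p = directory / f"gixf_{cond}_{line.element}.dat"
        gio.write_scan(p, scan)
        written.append(p)
    return written
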