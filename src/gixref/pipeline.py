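"""End-to-end analysis pipeline: spectra → XRR → illumination → GIXF → metrics.

A run is fully described by a :class:`RunConfig` (serialisable to TOML) and a
seed; re-running the same config and seed reproduces the report verbatim.
Angles in configuration files are degrees; everything internal is radians.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as gio
from .fitting import fit_gixf, fit_reflectivity
from .gixf import (
    CA_KALPHA,
    K_KALPHA,
    EmissionLine,
    ConcentrationProfile,
    derive_metrics,
    normalise_scan,
)
from .optics import Beam, critical_angle
from .spectra import extract_line_intensities

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "LINES"]

LINES = {"K": K_KALPHA, "Ca": CA_KALPHA}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    stack_file: str  # template slab model, TOML
    xrr_file: str  # reflectivity curve, columnar text
    gixf_file: str | None = None  # fluorescence angle scan
    spectra_dir: str | None = None  # alternative: one spectrum per angle
    beam_energy_kev: float = 8.0
    line: str = "K"  # element key into LINES
    c0_molar: float = 0.1  # bulk concentration from buffer composition
    area_A2: float = 210.0  # area per molecule from the isotherm
    seed: int = 0
    outdir: str = "gixref_run"
    xrr_objective: str = "logR"
    xrr_global: bool = True  # run the evolutionary stage before refinement
    xrr_de_maxiter: int = 1000
    gixf_init_cmax: float = 1.0
    gixf_init_zmax: float = 5.0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls(**doc)

    def to_toml(self, path) -> Path:
        scalars = {k: v for k, v in asdict(self).items() if v is not None}
        return gio.dump_toml_tables(path, scalars, {})


def _load_scan_from_spectra(directory: str, line: EmissionLine, beam: Beam):
    """Batch mode: one MCA spectrum per incidence angle -> raw angle scan."""
    paths = sorted(Path(directory).glob("*.dat"))
    if not paths:
        raise PipelineError("spectra", f"no .dat spectra in {directory}")
    alphas, areas, errs = [], [], []
    for p in paths:
        spec = gio.read_spectrum(p)
        if spec.alpha is None:
            raise PipelineError("spectra", f"{p} has no '# alpha_rad:' header")
        fit = extract_line_intensities(spec, [line])
        alphas.append(spec.alpha)
        areas.append(fit.areas[0])
        errs.append(fit.area_errors[0])
    order = np.argsort(alphas)
    return np.asarray(alphas)[order], np.asarray(areas)[order], np.asarray(errs)[order]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a report bundle to ``config.outdir``.

    Returns the report dict.  Raises :class:`PipelineError` on a hard stage
    failure; an unfittable GIXF scan (no resolvable interfacial layer) is a
    reported outcome, not an exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    beam = Beam(energy=config.beam_energy_kev)
    try:
        line = LINES[config.line]
    except KeyError:
        raise PipelineError("config", f"unknown emission line {config.line!r}") from None

    for stage, path in (("load", config.stack_file), ("load", config.xrr_file)):
        if path is not None and not Path(path).exists():
            raise PipelineError(stage, f"input file not found: {path}")
    template = gio.read_stack_toml(config.stack_file)
    curve = gio.read_reflectivity(config.xrr_file)

    xrr_fit = fit_reflectivity(
        curve,
        template,
        beam,
        seed=config.seed,
        objective=config.xrr_objective,
        de_maxiter=config.xrr_de_maxiter,
        skip_global=not config.xrr_global,
    )
    from .fitting import _stack_from_params

    fitted_stack = _stack_from_params(template, xrr_fit.params)
    n_free = len(xrr_fit.errors)
    log.append(
        f"xrr: chi2={xrr_fit.chi2:.6g} free_params={n_free} converged={xrr_fit.success}"
    )
    if not xrr_fit.success:
        raise PipelineError("xrr", f"reflectivity fit did not converge: {xrr_fit.message}")

    alpha_c = critical_angle(fitted_stack.subphase.rho, beam.wavelength).alpha_c
    report: dict = {
        "config": asdict(config),
        "beam": {"energy_kev": beam.energy, "wavelength_A": beam.wavelength},
        "critical_angle_deg": math.degrees(alpha_c),
        "xrr": {
            "params": xrr_fit.params,
            "errors": xrr_fit.errors,
            "chi2": xrr_fit.chi2,
            "redchi": xrr_fit.redchi,
            "success": xrr_fit.success,
        },
    }
    gio.write_fit_report(outdir / "xrr_fit.json", xrr_fit)

    gixf_result = None
    if config.spectra_dir is not None:
        alphas, areas, errs = _load_scan_from_spectra(config.spectra_dir, line, beam)
        scan = normalise_scan(areas, alphas, alpha_c, error=errs, line=line, beam=beam)
        gio.write_scan(outdir / "scan_from_spectra.dat", scan)
    elif config.gixf_file is not None:
        if not Path(config.gixf_file).exists():
            raise PipelineError("load", f"input file not found: {config.gixf_file}")
        scan = gio.read_scan(config.gixf_file)
        if scan.beam is None:
            scan.beam = beam
    else:
        scan = None

    if scan is not None:
        gixf_result = fit_gixf(
            scan,
            fitted_stack,
            line,
            c0=config.c0_molar,
            init=(config.gixf_init_cmax, config.gixf_init_zmax),
            beam=beam,
            seed=config.seed,
        )
        log.append(
            f"gixf: chi2={gixf_result.chi2:.6g} free_params=2 "
            f"converged={gixf_result.success}"
        )
        gio.write_fit_report(outdir / "gixf_fit.json", gixf_result)
        report["gixf"] = {
            "params": gixf_result.params,
            "errors": gixf_result.errors,
            "chi2": gixf_result.chi2,
            "success": gixf_result.success,
            "message": gixf_result.message,
        }
        if gixf_result.metadata.get("no_resolvable_interfacial_layer"):
            report["gixf"]["no_resolvable_interfacial_layer"] = True
        else:
            profile = ConcentrationProfile(
                c0=config.c0_molar,
                c_max=gixf_result.params["c_max"],
                z_max=gixf_result.params["z_max"],
                z_hc=fitted_stack.z_hc,
            )
            metrics = derive_metrics(profile, config.area_A2)
            report["ion_metrics"] = {
                "c_lateral_per_cm2": metrics.c_lateral,
                "n_per_molecule": metrics.n_per_molecule,
                "enrichment": metrics.enrichment,
                "peak_depth_A": metrics.peak_depth,
                "z_max_A": metrics.z_max,
                "area_A2": metrics.area,
            }
            gio.write_profile(outdir / "ion_profile.dat", profile, metrics)
            log.append(
                f"metrics: c_L={metrics.c_lateral:.3g} ions/cm2 "
                f"N={metrics.n_per_molecule:.3g} enrichment={metrics.enrichment:.3g}"
            )

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
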