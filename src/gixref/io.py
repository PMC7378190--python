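"""Text-based readers and writers for the package's observables.

Formats are deliberately plain: '#'-commented whitespace columns for curves,
scans and spectra (np.loadtxt-compatible, ORSO-style .ort headers supported
for reflectivity), TOML for slab stacks and run configuration, JSON for fit
reports and profile sidecars.  Every writer's output round-trips through its
paired reader.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .gixf import (
    ConcentrationProfile,
    DerivedIonMetrics,
    EmissionLine,
    FluorescenceScan,
)
from .optics import Beam, ReflectivityCurve, Slab, SlabStack

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "read_stack_toml",
    "write_stack_toml",
    "read_scan",
    "write_scan",
    "read_spectrum",
    "write_spectrum",
    "write_profile",
    "read_profile",
    "write_fit_report",
]


def write_reflectivity(path, curve: ReflectivityCurve, header: str = "") -> Path:
    """Write q [Å⁻¹], R, δR columns; '.ort' paths get an ORSO-style header."""
    path = Path(path)
    lines = []
    if path.suffix == ".ort":
        lines += [
            "# # ORSO reflectivity data file | 1.0 text dialect",
            "# # columns: [{name: Qz, unit: 1/angstrom}, {name: R}, {name: sR}]",
        ]
    if header:
        lines += [f"# {h}" for h in header.splitlines()]
    lines.append("# q_z[1/A] R dR")
    cols = [curve.q, curve.R]
    if curve.dR is not None:
        cols.append(curve.dR)
    body = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.10e")
    return path


def read_reflectivity(path) -> ReflectivityCurve:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least q and R columns")
    dR = data[:, 2] if data.shape[1] >= 3 else None
    return ReflectivityCurve(q=data[:, 0], R=data[:, 1], dR=dR)


def _toml_value(v) -> str:
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and math.isinf(v):
        return '"inf"'
    return repr(v)


def dump_toml_tables(path, scalars: dict, tables: dict[str, list[dict] | dict]) -> Path:
    """Minimal TOML writer for flat scalar keys plus named (arrays of) tables."""
    path = Path(path)
    out = [f"{k} = {_toml_value(v)}" for k, v in scalars.items()]
    for name, content in tables.items():
        entries = content if isinstance(content, list) else [content]
        header = f"[[{name}]]" if isinstance(content, list) else f"[{name}]"
        for entry in entries:
            out.append("")
            out.append(header)
            out += [f"{k} = {_toml_value(v)}" for k, v in entry.items()]
    path.write_text("\n".join(out) + "\n")
    return path


def write_stack_toml(path, stack: SlabStack) -> Path:
    """Serialise a slab stack; the semi-infinite subphase thickness is the
    string "inf"."""
    layers = [
        {"d": s.thickness, "rho": s.rho, "sigma": s.sigma, "beta": s.beta}
        for s in stack.slabs
    ]
    layers.append(
        {
            "d": "inf",
            "rho": stack.subphase.rho,
            "sigma": stack.subphase.sigma,
            "beta": stack.subphase.beta,
        }
    )
    return dump_toml_tables(
        path,
        {"rho_incident": stack.rho_incident, "beta_incident": stack.beta_incident},
        {"layer": layers},
    )


def read_stack_toml(path) -> SlabStack:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    layers = doc.get("layer", [])
    if not layers:
        raise ValueError(f"{path}: no [[layer]] tables")
    slabs = []
    for entry in layers[:-1]:
        slabs.append(
            Slab(
                thickness=float(entry["d"]),
                rho=float(entry["rho"]),
                sigma=float(entry.get("sigma", 0.0)),
                beta=float(entry.get("beta", 0.0)),
            )
        )
    last = layers[-1]
    if str(last["d"]).lower() not in ("inf", "+inf", "infinity"):
        raise ValueError(f"{path}: last layer must have d = \"inf\" (subphase)")
    subphase = Slab(
        thickness=math.inf,
        rho=float(last["rho"]),
        sigma=float(last.get("sigma", 0.0)),
        beta=float(last.get("beta", 0.0)),
    )
    return SlabStack(
        slabs=tuple(slabs),
        subphase=subphase,
        rho_incident=float(doc.get("rho_incident", 0.0)),
        beta_incident=float(doc.get("beta_incident", 0.0)),
    )


def write_scan(path, scan: FluorescenceScan) -> Path:
    """Fluorescence angle scan: '#' metadata header + (alpha_rad, I, dI)."""
    path = Path(path)
    lines = []
    if scan.line is not None:
        lines.append(f"# element: {scan.line.element} {scan.line.label}")
        lines.append(f"# line_energy_keV: {scan.line.energy}")
        lines.append(f"# attenuation_length_um: {scan.line.attenuation_length_um}")
    if scan.beam is not None:
        lines.append(f"# energy_keV: {scan.beam.energy!r}")
    lines.append("# alpha[rad] intensity error")
    cols = [scan.alpha, scan.intensity]
    if scan.error is not None:
        cols.append(scan.error)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, np.column_stack(cols), fmt="%.10e")
    return path


def read_scan(path) -> FluorescenceScan:
    meta = {}
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#") and ":" in raw:
            key, _, val = raw.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    data = np.loadtxt(path, comments="#", ndmin=2)
    line = None
    if "element" in meta and "line_energy_keV" in meta:
        element, _, label = meta["element"].partition(" ")
        line = EmissionLine(
            element=element,
            label=label or "Kalpha",
            energy=float(meta["line_energy_keV"]),
            attenuation_length_um=float(meta.get("attenuation_length_um", 68.1)),
        )
    beam = Beam(energy=float(meta["energy_keV"])) if "energy_keV" in meta else None
    err = data[:, 2] if data.shape[1] >= 3 else None
    return FluorescenceScan(
        alpha=data[:, 0], intensity=data[:, 1], error=err, line=line, beam=beam
    )


def write_spectrum(path, spectrum) -> Path:
    """MCA-style two-column text (energy keV, counts)."""
    path = Path(path)
    with open(path, "w") as fh:
        if spectrum.alpha is not None:
            fh.write(f"# alpha_rad: {spectrum.alpha!r}\n")
        fh.write("# energy[keV] counts\n")
        np.savetxt(fh, np.column_stack([spectrum.energy, spectrum.counts]), fmt="%.6e")
    return path


def read_spectrum(path):
    from .spectra import FluorescenceSpectrum

    alpha = None
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#") and "alpha_rad:" in raw:
            alpha = float(raw.split("alpha_rad:")[1])
    data = np.loadtxt(path, comments="#", ndmin=2)
    return FluorescenceSpectrum(energy=data[:, 0], counts=data[:, 1], alpha=alpha)


def write_profile(
    path,
    profile: ConcentrationProfile,
    metrics: DerivedIonMetrics | None = None,
    z=None,
) -> Path:
    """Columnar (z, c) plus a JSON sidecar of the profile parameters and any
    derived interfacial-ion metrics."""
    from .gixf import concentration

    path = Path(path)
    if z is None:
        z = np.linspace(0.0, profile.z_hc + 10.0 * profile.z_max, 400)
    c = concentration(profile, z)
    with open(path, "w") as fh:
        fh.write("# z[A] c[M]\n")
        np.savetxt(fh, np.column_stack([z, c]), fmt="%.10e")
    sidecar = {
        "c0": profile.c0,
        "c_max": profile.c_max,
        "z_max": profile.z_max,
        "z_hc": profile.z_hc,
        "peak_depth": profile.peak_depth,
    }
    if metrics is not None:
        sidecar.update(asdict(metrics))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_profile(path) -> ConcentrationProfile:
    sidecar = json.loads(Path(path).with_suffix(".json").read_text())
    return ConcentrationProfile(
        c0=sidecar["c0"],
        c_max=sidecar["c_max"],
        z_max=sidecar["z_max"],
        z_hc=sidecar["z_hc"],
    )


def write_fit_report(path, result, extra: dict | None = None) -> Path:
    """JSON fit report: parameters, uncertainties, χ², seed, metadata."""
    doc = {
        "params": result.params,
        "errors": result.errors,
        "chi2": result.chi2,
        "redchi": result.redchi,
        "nfev": result.nfev,
        "success": result.success,
        "message": result.message,
        "seed": result.seed,
        "metadata": _jsonable(result.metadata),
    }
    if extra:
        doc.update(_jsonable(extra))
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
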