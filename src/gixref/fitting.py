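"""Parameter estimation for slab models and ion profiles.

XRR: a global evolutionary (differential-evolution) search inside parameter
bounds, refined by bounded least squares; the objective is the weighted sum
of squared residuals in log10 R, which balances the many-decade dynamic
range of a reflectivity curve.

GIXF: Levenberg–Marquardt least squares over exactly two parameters,
(c_max, z_max), with the slab stack and bulk concentration held fixed; both
the data and the forward model pass through the same high-angle
normalisation, so the instrument constant cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .gixf import ConcentrationProfile, EmissionLine, FluorescenceScan, GixfForwardModel
from .optics import Beam, ReflectivityCurve, SlabStack, critical_angle, reflectivity

__all__ = ["ParameterSpec", "FitResult", "fit_reflectivity", "fit_gixf", "default_xrr_specs"]

#: below this fitted z_max (Å) a GIXF fit is flagged as having no
#: resolvable interfacial ion layer
Z_MAX_FLOOR = 0.5


@dataclass
class ParameterSpec:
    """One fit parameter: bounds, initial value and whether it varies."""

    name: str
    value: float
    lower: float = -np.inf
    upper: float = np.inf
    vary: bool = True

    def __post_init__(self):
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"{self.name}: initial {self.value} outside [{self.lower}, {self.upper}]"
            )


@dataclass
class FitResult:
    """Best-fit parameters with uncertainties and convergence metadata."""

    params: dict
    errors: dict
    chi2: float
    redchi: float
    nfev: int
    success: bool
    message: str
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def default_xrr_specs(template: SlabStack, span: float = 0.5) -> list[ParameterSpec]:
    """Free every slab's (d, rho, sigma) plus the subphase roughness, with
    bounds at ±``span`` (fractional) around the template values; the
    subphase density is fixed (known buffer)."""
    specs = []
    for i, s in enumerate(template.slabs):
        specs.append(ParameterSpec(f"d{i}", s.thickness, s.thickness * (1 - span), s.thickness * (1 + span)))
        specs.append(ParameterSpec(f"rho{i}", s.rho, s.rho * (1 - span), s.rho * (1 + span)))
        specs.append(ParameterSpec(f"sigma{i}", s.sigma, max(s.sigma * (1 - span), 0.0), s.sigma * (1 + span)))
    sub = template.subphase
    specs.append(ParameterSpec("sigma_sub", sub.sigma, max(sub.sigma * (1 - span), 0.0), sub.sigma * (1 + span)))
    specs.append(ParameterSpec("rho_sub", sub.rho, vary=False))
    return specs


def _stack_from_params(template: SlabStack, values: dict) -> SlabStack:
    slabs = []
    for i, s in enumerate(template.slabs):
        slabs.append(
            replace(
                s,
                thickness=values.get(f"d{i}", s.thickness),
                rho=values.get(f"rho{i}", s.rho),
                sigma=values.get(f"sigma{i}", s.sigma),
            )
        )
    sub = replace(
        template.subphase,
        rho=values.get("rho_sub", template.subphase.rho),
        sigma=values.get("sigma_sub", template.subphase.sigma),
    )
    return replace(template, slabs=tuple(slabs), subphase=sub)


def _cov_errors(jac: np.ndarray, resid: np.ndarray, n_free: int) -> np.ndarray:
    """1-sigma parameter errors from the Jacobian at the optimum."""
    m = resid.size
    dof = max(m - n_free, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        err = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        err = np.full(n_free, np.nan)
    return err


def fit_reflectivity(
    curve: ReflectivityCurve,
    template: SlabStack,
    beam: Beam,
    specs: list[ParameterSpec] | None = None,
    seed: int = 0,
    objective: str = "logR",
    de_maxiter: int = 1000,
    de_popsize: int = 15,
    skip_global: bool = False,
) -> FitResult:
    """Fit a slab model to a reflectivity curve.

    Global differential-evolution search inside the spec bounds followed by
    bounded least-squares refinement.  Residuals are log10(R_model) −
    log10(R_data), weighted by δR/(R ln10) when the curve carries
    uncertainties (``objective="logR"``), or q⁴-scaled linear residuals
    (``objective="rq4"``).  Deterministic for a fixed seed.
    """
    if specs is None:
        specs = default_xrr_specs(template)
    free = [s for s in specs if s.vary]
    fixed = {s.name: s.value for s in specs if not s.vary}
    if curve.q.size < 5 * len(free):
        raise ValueError(
            f"{curve.q.size} data points cannot constrain {len(free)} free "
            "parameters (need >= 5x)"
        )
    names = [s.name for s in free]
    bounds = [(s.lower, s.upper) for s in free]
    x0 = np.array([s.value for s in free])

    pos = curve.R > 0
    q = curve.q[pos]
    r_data = curve.R[pos]
    if objective == "logR":
        y_data = np.log10(r_data)
        if curve.dR is not None:
            w = np.maximum(curve.dR[pos] / (r_data * math.log(10.0)), 1e-12)
        else:
            w = np.ones_like(y_data)
    elif objective == "rq4":
        y_data = r_data * q**4
        w = curve.dR[pos] * q**4 if curve.dR is not None else np.ones_like(y_data)
        w = np.maximum(w, 1e-300)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    def residuals(x: np.ndarray) -> np.ndarray:
        values = dict(zip(names, x))
        values.update(fixed)
        stack = _stack_from_params(template, values)
        r_model = reflectivity(stack, beam, q).R
        if objective == "logR":
            y_model = np.log10(np.maximum(r_model, 1e-300))
        else:
            y_model = r_model * q**4
        return (y_model - y_data) / w

    def cost(x: np.ndarray) -> float:
        r = residuals(x)
        return float(r @ r)

    nfev = 0
    metadata: dict = {"objective": objective, "bounds": dict(zip(names, bounds))}
    if not skip_global:
        de = differential_evolution(
            cost,
            bounds=bounds,
            x0=x0,  # the user's initial guess joins the start population
            seed=seed,
            maxiter=de_maxiter,
            popsize=de_popsize,
            tol=1e-12,
            polish=False,
            init="sobol",
        )
        nfev += de.nfev
        x_start = de.x
        metadata["global_basins"] = _top_basins(de, names)
    else:
        x_start = x0

    lsq = least_squares(
        residuals,
        x_start,
        bounds=([b[0] for b in bounds], [b[1] for b in bounds]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    nfev += lsq.nfev
    errs = _cov_errors(lsq.jac, lsq.fun, len(free))
    chi2 = 2.0 * lsq.cost
    dof = max(q.size - len(free), 1)

    at_bound = [
        n
        for n, v, (lo, hi) in zip(names, lsq.x, bounds)
        if math.isclose(v, lo, rel_tol=0, abs_tol=1e-9 * max(abs(lo), 1))
        or math.isclose(v, hi, rel_tol=0, abs_tol=1e-9 * max(abs(hi), 1))
    ]
    if at_bound:
        metadata["parameters_at_bounds"] = at_bound
    params = dict(zip(names, (float(v) for v in lsq.x)))
    params.update(fixed)
    return FitResult(
        params=params,
        errors={n: float(e) for n, e in zip(names, errs)},
        chi2=float(chi2),
        redchi=float(chi2 / dof),
        nfev=nfev,
        success=bool(lsq.success),
        message=str(lsq.message),
        seed=seed,
        metadata=metadata,
    )


def _top_basins(de_result, names, n_keep: int = 3, min_dist: float = 0.05) -> list[dict]:
    """Best distinct members of the final DE population (multi-minima guard)."""
    pop = np.asarray(de_result.population)
    energies = np.asarray(de_result.population_energies)
    order = np.argsort(energies)
    span = pop.max(axis=0) - pop.min(axis=0)
    span[span == 0] = 1.0
    kept: list[np.ndarray] = []
    out = []
    for idx in order:
        x = pop[idx]
        if any(np.max(np.abs(x - k) / span) < min_dist for k in kept):
            continue
        kept.append(x)
        out.append({"params": dict(zip(names, map(float, x))), "cost": float(energies[idx])})
        if len(out) >= n_keep:
            break
    return out


def fit_gixf(
    scan: FluorescenceScan,
    stack: SlabStack,
    line: EmissionLine,
    c0: float,
    init: tuple[float, float] = (1.0, 5.0),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 50.0), (Z_MAX_FLOOR, 25.0)),
    beam: Beam | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit (c_max, z_max) of the interfacial ion profile to a normalised scan.

    z_HC is fixed at the XRR-fitted alkyl-chain thickness carried by
    ``stack``; c0 comes from the known buffer composition.  Levenberg–
    Marquardt on the residuals between the normalised scan and the
    identically normalised forward model.  A fit driven to the z_max floor
    is flagged ``no_resolvable_interfacial_layer`` — the data carry no
    interfacial excess that the model can resolve.
    """
    if beam is None:
        beam = scan.beam
    if beam is None:
        raise ValueError("supply a Beam (scan carries none)")
    if c0 <= 0:
        raise ValueError("bulk concentration must be positive")
    alpha_c = critical_angle(stack.subphase.rho, beam.wavelength).alpha_c
    hi_mask = scan.alpha > 1.5 * alpha_c
    if np.count_nonzero(hi_mask) < 3:
        raise ValueError("scan needs >= 3 points above 1.5*alpha_c for normalisation")
    (c_lo, c_hi), (z_lo, z_hi) = bounds
    model = GixfForwardModel(stack, beam, line, scan.alpha)
    err = scan.error if scan.error is not None else np.ones_like(scan.intensity)
    err = np.maximum(err, 1e-12)

    def model_norm(c_max: float, z_max: float) -> np.ndarray:
        prof = ConcentrationProfile(c0=c0, c_max=c_max, z_max=z_max, z_hc=stack.z_hc)
        raw = model.intensity(prof)
        return raw / np.mean(raw[hi_mask])

    import lmfit

    params = lmfit.Parameters()
    c0_init = min(max(init[0], c_lo), c_hi)
    z0_init = min(max(init[1], z_lo), z_hi)
    params.add("c_max", value=c0_init, min=c_lo, max=c_hi)
    params.add("z_max", value=z0_init, min=z_lo, max=z_hi)

    def residuals(p) -> np.ndarray:
        return (model_norm(p["c_max"].value, p["z_max"].value) - scan.intensity) / err

    mini = lmfit.minimize(residuals, params, method="leastsq")
    chi2 = float(mini.chisqr)
    dof = max(scan.alpha.size - 2, 1)
    metadata: dict = {"bounds": {"c_max": (c_lo, c_hi), "z_max": (z_lo, z_hi)}}
    c_fit = float(mini.params["c_max"].value)
    z_fit = float(mini.params["z_max"].value)
    flagged = z_fit <= z_lo * (1.0 + 1e-3)
    if flagged:
        metadata["no_resolvable_interfacial_layer"] = True

    def _err(p):
        return float(p.stderr) if p.stderr is not None else float("nan")

    return FitResult(
        params={"c_max": c_fit, "z_max": z_fit},
        errors={"c_max": _err(mini.params["c_max"]), "z_max": _err(mini.params["z_max"])},
        chi2=chi2,
        redchi=float(mini.redchi),
        nfev=int(mini.nfev),
        success=bool(mini.success) and not flagged,
        message="no resolvable interfacial layer (z_max at floor)" if flagged else str(mini.message),
        seed=seed,
        metadata=metadata,
    )
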