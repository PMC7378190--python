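"""Slab-model recovery from a noisy synthetic reflectivity curve.

Simulates a beamline-like measurement (2% relative counting error), then
fits the two-slab model starting from a deliberately
wrong initial guess using the evolutionary + least-squares estimator.
"""

import numpy as np

from gixref import Beam, fit_reflectivity
from gixref.fitting import default_xrr_specs
from gixref.synthetic import NoiseModel, default_q_grid, simulate_xrr, table_stacks

beam = Beam(energy=8.0)
truth = table_stacks()["ca_free"]
curve = simulate_xrr(
    truth, beam, default_q_grid(), NoiseModel("gaussian-relative", 0.02, seed=0)
)

specs = default_xrr_specs(truth)
rng = np.random.default_rng(1)
for s in specs:
    if s.vary:  # start up to 20% away from the truth
        s.value = float(np.clip(s.value * (1 + rng.uniform(-0.2, 0.2)), s.lower, s.upper))

result = fit_reflectivity(curve, truth, beam, specs=specs, seed=1)
print(f"converged: {result.success},  chi2 = {result.chi2:.1f},  evaluations: {result.nfev}")
names = {"d0": 10.6, "d1": 24.0, "rho0": 0.326, "rho1": 0.483, "sigma_sub": 6.8}
for name, true_val in names.items():
    print(
        f"{name:9s} fitted {result.params[name]:7.3f} "
        f"(+- {result.errors[name]:.3f})   truth {true_val}"
    )
print(
    "With counting noise the slab thicknesses come back within a fraction "
    "of an Ångström — the structural resolution the reflectivity fit claims."
)
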