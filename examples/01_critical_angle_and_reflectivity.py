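"""Critical angle and specular reflectivity of an LPS Ra monolayer.

Builds the intact-monolayer slab model (alkyl chains + saccharide head group
on a KCl subphase), computes the critical angle of total external reflection
and the reflectivity curve, and prints a few landmark values.
"""

import math

import numpy as np

from gixref import Beam, critical_angle, reflectivity
from gixref.synthetic import table_stacks

beam = Beam(energy=8.0)
stack = table_stacks()["ca_free"]

ca = critical_angle(stack.subphase.rho, beam.wavelength)
print(f"lambda = {beam.wavelength:.4f} A at {beam.energy} keV")
print(f"alpha_c = {math.degrees(ca.alpha_c):.3f} deg,  q_c = {ca.q_c:.3f} 1/A")

q = np.array([0.5 * ca.q_c, 0.05, 0.1, 0.3])
curve = reflectivity(stack, beam, q)
for qi, ri in zip(curve.q, curve.R):
    print(f"R(q = {qi:.3f}) = {ri:.3e}")
print(
    "Below q_c the monolayer reflects totally (R ~ 1); above it the "
    "reflectivity falls by orders of magnitude, modulated by the slab "
    "thicknesses (Kiessig fringes) and damped by interfacial roughness."
)
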