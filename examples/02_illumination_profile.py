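"""Depth-resolved illumination across the critical angle.

The fluorescence signal is weighted by the X-ray intensity at each depth.
Below the critical angle the field is evanescent — only the first tens of
Ångströms are illuminated; above it the beam penetrates the bulk.
"""

import numpy as np

from gixref import Beam, critical_angle, illumination
from gixref.synthetic import table_stacks

beam = Beam(energy=8.0)
stack = table_stacks()["ca_free"]
ac = critical_angle(stack.subphase.rho, beam.wavelength).alpha_c

z = np.array([0.0, 17.0, 50.0, 200.0])  # depths of interest (A)
alphas = np.array([0.5, 0.9, 1.0, 2.0]) * ac
prof = illumination(stack, beam, alphas, z)

header = "  ".join(f"a={a/ac:4.1f}ac" for a in alphas)
print(f"I_ill(z, alpha):   {header}")
for i, zi in enumerate(z):
    row = "  ".join(f"{prof.intensity[i, j]:8.3f}" for j in range(alphas.size))
    print(f"z = {zi:6.1f} A   {row}")
print(f"penetration depth at 0.5 alpha_c: {prof.penetration_depth[0]:.1f} A")
print(f"penetration depth at 2.0 alpha_c: {prof.penetration_depth[3]:.0f} A")
print(
    "Near alpha_c the surface intensity approaches 4x the incident beam "
    "(standing-wave antinode); the evanescent depth of ~50 A below alpha_c "
    "is what makes the fluorescence surface-sensitive."
)
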