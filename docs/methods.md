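# Methods

## Scope and coordinate conventions

The package analyses a stratified liquid interface: incident medium (air,
ρ = 0) on top, a small number of homogeneous slabs, and a semi-infinite
aqueous subphase. z = 0 sits at the air/first-slab interface and increases
into the liquid; for the two-slab monolayer models (alkyl chains over a
saccharide head group) the depth of the chain/head interface z_HC equals the
fitted alkyl-chain thickness. All angles are radians internally; q_z =
(4π/λ) sin α exactly, with no small-angle approximation, so observables may
be given on either axis. Configuration files and the CLI use degrees.

## Reflectivity

Specular reflectivity uses the Parratt recursion with the Névot–Croce
factor exp(−2 k_{z,j} k_{z,j+1} σ²) applied to each Fresnel coefficient.
Vertical wavevectors are k_{z,j} = √(k_{z,0}² − 4π r_e (ρ_j − ρ_0) +
2ik²(β_j − β_0)) with r_e = 2.8179403×10⁻⁵ Å and the branch Im k_z ≥ 0.
The recursion is exact for sharp slabs; the roughness factor treats each
interface independently. For the monolayer models here the roughnesses
(3–8 Å) are comparable to the 10.6 Å chain layer, so the erf-smeared
continuous profile and the Névot–Croce slab model genuinely differ at high
q (up to ~10% relative on reflectivities of 10⁻⁶–10⁻⁹); the test suite
pins the single-interface agreement at the 1% level and only an envelope on
full stacks. The reconstructed density profile is the analytic erf
superposition, and a micro-slicing helper (0.5 Å steps, chosen well below
the smallest σ of 3.3 Å) provides the profile-based cross-check.

Absorption: β = 0 for the monolayer slabs. The subphase defaults to
β = 4.6×10⁻⁸ (8 keV, water-like, configurable). Reflectivity in the fitted
q-range is insensitive to it, but the illumination profile needs a finite
subphase β to stay regular at the critical angle and to give a finite
penetration depth above it.

## Illumination

The depth-resolved intensity I_ill(z, α) = |E⁺(z) + E⁻(z)|² is obtained by
propagating the down/up plane-wave amplitudes through the layer system with
2×2 interface and phase matrices, matched to the Parratt solution and
normalised to unit incident intensity; the subphase carries no up-going
wave. Roughness is not applied to the internal field: it is a
reflectivity-level correction, and σ ≤ 8 Å is negligible against the
≥ 50 Å illumination length scales. Exactly at a vanishing substrate k_z
(critical angle, β = 0) the degenerate transmission limit E = const is
substituted, reproducing the analytic |T|² = 4 maximum. In the deep
subphase the intensity decays as exp(−z/Λ) with Λ = 1/(2 Im k_z,sub), which
the fluorescence quadrature uses as an analytic tail.

## Fluorescence forward model and inversion

I_i(α) = S ∫ I_ill(z, α) c_i(z) e^(−z/L_i) dz is integrated by composite
Simpson on a segmented grid: the ion profile is identically zero inside the
hydrocarbon region (physical exclusion; it also jumps by c₀ at z_HC, so the
grid starts exactly there), with breakpoints at every slab interface, a
0.25 Å base step, and the analytic bulk tail beyond a cut at
max(z_HC + 12 z_max, deepest interface + 100 Å). `fluorescence_forward`
halves the step until the result is stable to 10⁻⁶ relative; the fitting
path reuses one transfer-matrix solve for all profile evaluations.

Normalisation divides by the mean intensity over α > 1.5 α_c. The
convention is a choice (any smooth monotone alternative only rescales χ²);
applying the identical operation to data and model cancels the instrument
constant S. The published figures imply an effectively bounded bulk
contribution above α_c (finite detector acceptance); this package integrates
the stated model to infinity instead, so normalised sub-critical values are
small — all comparative and inferential results are unaffected because data
and model are treated identically.

The inversion holds the stack (from XRR), c₀ (buffer composition: 0.1 M K⁺
or 0.05 M Ca²⁺) and z_HC fixed and fits exactly (c_max, z_max) by
Levenberg–Marquardt (lmfit/MINPACK, bounds via parameter transformation).
c_max ∈ [0, 50] M; z_max ∈ [0.5, 25] Å, and a fit driven to the 0.5 Å floor
is flagged "no resolvable interfacial layer" rather than reported as a
structure — the outcome expected when the layered membrane is disrupted.
(c_max, z_max) are strongly anti-correlated (their product fixes the
well-determined lateral density), so the depth resolution is set by the
sub-critical sampling; with 31 points between 0.2 α_c and 1.2 α_c at 5%
relative noise the recovered z_max has an RMS deviation of ≈ 2 Å.

## Spectra

Energy-dispersive spectra are decomposed into Σ Gaussians + linear
background with lmfit. Centres start at tabulated line energies (K Kα
3.314 keV, Ca Kα 3.691 keV) constrained to ±0.05 keV; the detector
resolution defaults to σ_E = 0.08 keV (configurable — not a measured
property); weights are Poisson (√counts, floored at 1); the fit window is
the union of line energies ± 5σ_E. Areas are reported in counts (lmfit's
amplitude divided by the bin width).

## Parameter estimation for reflectivity

The objective is Σ[(log₁₀R_model − log₁₀R_data)/w]² with w = δR/(R ln 10)
when uncertainties exist, else 1; a q⁴-weighted linear objective is
available as an option. Points with zero measured reflectivity carry no
log-space information and are excluded. The global stage is differential
evolution (population 15 × free parameters, up to 1000 generations, Sobol
initialisation, the user's initial guess injected into the start
population, fixed seed → bit-reproducible), followed by bounded
least-squares refinement; uncertainties come from the Jacobian at the
optimum. Bounds default to ±50% of the template values with the subphase
density fixed; the best three distinct basins of the final population are
reported in the result metadata as a multiple-minima guard, and parameters
ending on bounds are flagged.

## Synthetic data

The generator emulates: (a) two-slab reflectivity with Poisson counting
noise referenced to 10⁶ incident counts at the total-reflection plateau, or
a relative Gaussian alternative; (b) normalised fluorescence angle scans
(default 3% relative noise) on a grid sampling 0.2–1.2 α_c densely (31
points) plus 10 points to 3 α_c — the sampling strategy of an angle scan
across total reflection, where the evanescent region carries the depth
information; (c) detector spectra as Gaussian lines on a linear background
with Poisson counts. Default scan range for reflectivity is q =
0.02–0.6 Å⁻¹ with 200 points (a choice; the measured range is not part of
the reference data).

Reference fixtures: the eight slab models of the LPS Ra monolayer
(Ca²⁺-free/loaded buffer, ± 100 mM benzyl alcohol, ± 5 µM benzalkonium
chloride) and the intact-monolayer ion profiles. The K⁺ profile uses c₀ =
0.1 M, c_max = 4.6 M and peak depth 17 Å; the statement "17 Å from the
air/chain interface" is ambiguous about whether it includes z_HC, so the
default reading z_max = 17 − 10.6 = 6.4 Å and the literal reading z_max =
17 Å are both shipped, and reports always expose both the raw z_max and the
peak depth z_HC + z_max. The Ca²⁺ profile's amplitude is not tabulated
anywhere; it is reconstructed (≈ 3.8 M) from the reported lateral density
2.5×10¹⁴ ions/cm² via the closed form c_L = c_max √e z_max.

What passing tests do not show: the generator draws independent noise on a
fixed grid and contains no footprint/geometry effects, no energy-dependent
detector efficiency, no background under the emission lines' angle
dependence, and no sample damage or drift; recovery results therefore bound
the statistical, not the systematic, uncertainty of the method on real
beamline data.

## Numerical and degenerate-input policy

Slab thicknesses must be positive and the subphase infinite; q grids
strictly increasing and positive; α = 0 is rejected for illumination.
Stacks with no optical contrast reflect exactly zero. Equal-k_z interfaces
short-circuit to r = 0. The closed-form lateral density is used for derived
metrics (the quadrature agrees to 10⁻¹⁰ and serves as the test oracle).
Unit conversions: 1 M = 6.02214×10⁻⁴ ions/Å³; 1 ion/Å² = 10¹⁶ ions/cm²;
hc = 12.39842 keV·Å.

## Problem sizes used in the shipped studies

The Monte-Carlo studies in the test suite use 20 replicates (reflectivity:
2% noise, local refinement from ±20%-perturbed starts; fluorescence: 5%
noise, full LM fits), and the acceptance checks run one full
evolutionary + refinement reflectivity fit and twenty fluorescence fits;
these sizes are the package's own choice of a compact, reproducible study.

## Known limitations

- Single-element fits only; no self-absorption beyond exp(−z/L_i), no
  secondary fluorescence, no escape/pile-up peaks.
- Névot–Croce roughness assumes independent interfaces (see above).
- No off-specular scattering, diffraction or polarization effects.
- The illumination ignores roughness and detector geometry; absolute
  fluorescence scales are never meaningful, only normalised shapes.
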