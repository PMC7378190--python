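# gixref

Simultaneous analysis of specular X-ray reflectivity (XRR) and
grazing-incidence X-ray fluorescence (GIXF) from monolayers at liquid
interfaces — built around the model system of a lipopolysaccharide (LPS Ra)
monolayer mimicking the outer membrane of Gram-negative bacteria, where the
two techniques together resolve the layered membrane structure *and* the
depth profiles of condensed counterions (K⁺, Ca²⁺) near the charged
saccharide head groups.

It is a library first: the public API plus the short scripts in `examples/`
are the intended interface, with a thin `gixref` command-line wrapper for
running simulations, fits and the full pipeline from a shell.

## The model

**Structure (XRR).** The interface is a stack of slabs, each with thickness
*d*, electron density *ρ* and Gaussian roughness *σ* of its upper interface.
Specular reflectivity is computed by the Parratt recursion with
Névot–Croce damping of each Fresnel coefficient,

    r_j = (k_{z,j} − k_{z,j+1}) / (k_{z,j} + k_{z,j+1}) · exp(−2 k_{z,j} k_{z,j+1} σ²),

with k_{z,j} = √((q/2)² − 4π r_e Δρ_j + 2iβ_j k²). Parameters are estimated
by a global differential-evolution search inside bounds followed by bounded
least squares on log₁₀ R.

**Ion profiles (GIXF).** The angle-resolved fluorescence of element *i* is

    I_i(α) = S ∫₀^∞ I_ill(z, α) · c_i(z) · exp(−z/L_i) dz,

where I_ill(z, α) is the depth-resolved illumination intensity obtained by
transfer-matrix propagation through the fitted slab stack (evanescent below
the critical angle α_c, penetrating above it), L_i the attenuation length of
water at the emission energy (L_K-Kα = 68.1 µm, L_Ca-Kα = 93.7 µm), and S an
instrument constant that cancels when data and model are normalised by their
high-angle plateau. The ion profile is an asymmetric Gaussian anchored at
the hydrocarbon/head-group interface z_HC,

    c(z) = c₀ + c_max · √e (z − z_HC)/z_max · exp(−(z − z_HC)²/(2 z_max²)),

fitted with exactly two free parameters (c_max, z_max) by
Levenberg–Marquardt. Derived quantities: lateral ion density
c_L = c_max √e z_max (converted to ions/cm²), ions per molecule
N = c_L · A · 10⁻¹⁶ with A the area per molecule from the isotherm, and the
enrichment c_max/c₀ over the bulk.

A synthetic-data layer generates reflectivity curves (Poisson counting
statistics), fluorescence angle scans and energy-dispersive spectra with
realistic noise, and ships the reference slab models of the LPS Ra monolayer
under eight buffer/antimicrobial conditions, so every stage is testable
without measured data.

## Worked example

Ion bookkeeping for the intact monolayer on 100 mM KCl
(`python examples/03_ion_profile_metrics.py`):

```
profile: c0 = 0.1 M, c_max = 4.6 M, z_max = 6.4 A, z_HC = 10.6 A
c(z =  10.6 A) = 0.10 M
c(z =  17.0 A) = 4.70 M
c(z =  37.0 A) = 0.11 M
lateral density  c_L = 2.92e+14 ions/cm^2
ions per molecule  N = 6.1
enrichment over bulk = 46x
```

The K⁺ concentration peaks at 17 Å depth (the phosphorylated inner-core
saccharides), 46-fold enriched over the bulk; integrating the excess and
multiplying by the ~210 Å² area per LPS molecule counts ≈ 6 condensed
K⁺ ions per molecule — of the order of the 6 e⁻ net charge per core
saccharide. Inverting a simulated noisy angle scan
(`python examples/05_fit_gixf_scan.py`) recovers the generating profile:

```
c_max = 4.33 +- 0.60 M   (truth 4.6)
z_max = 6.80 +- 1.11 A   (truth 6.4)
```

`examples/04_fit_reflectivity.py` does the same for the structural stage,
recovering the alkyl-chain thickness of 10.6 Å to ±0.03 Å from a 2%-noise
curve started 20% off.

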