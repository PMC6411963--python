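# Methods

## Model overview

The package estimates whether a targeted NIR fluorescent probe accumulating
in inflamed synovial tissue of a hand joint can be detected by planar
epifluorescence imaging at clinical depth. Light transport is modeled with
the steady-state diffusion approximation, valid here because NIR photons in
soft tissue have high albedo and the joint lies several transport scattering
lengths deep:

    div(-D grad u) + mu_a u = f,        D = 1 / (3 (mu_a + mu_s')),

where `u` is the fluence rate, `mu_a` the absorption coefficient, `mu_s'`
the reduced scattering coefficient, and `f` a volumetric source density.
Every tissue/air face carries a Robin (partial-current) condition

    -n . (-D grad u) = u / (2 Cr),

with `Cr` the internal-reflection parameter of the refractive-index mismatch.

Fluorescence imaging is a two-pass chain. Collimated surface illumination is
replaced by an isotropic planar source buried one transport scattering
length (`1/mu_s'`) below the surface — the standard diffusion-theory
treatment of a collimated beam. The excitation solve yields `u_x`; dyed
voxels then emit with source density

    q_em = eta * mu_fx * u_x * C,

(`eta` quantum yield, `mu_fx` per-nM absorption at the excitation
wavelength, `C` local concentration in nM), and a second solve propagates
the emission band. The detected image is the emission fluence in the first
tissue voxel layer under the surface; no lens, camera or noise model is
applied at this stage (noise enters statistically in the detection layer).
Tissue autofluorescence and non-specific uptake are folded into a uniform
background "equivalent dye" concentration, so every tissue voxel emits.
Re-excitation by emitted light (cascade fluorescence) is neglected.

## Geometry

The hand is a rectangular tissue slab, default 80 x 60 x 25 mm. The slab is
wider than the hand around one knuckle because the lateral Robin boundaries
depress the fluence over a range of roughly three diffusion lengths
(~17 mm); the slab must be wide enough that neither ROI (below) sits in
that halo, otherwise a uniform dye distribution would not produce a uniform
image.

The synovial target is a dye-filled *pocket*: a curved sheet of uniform
vertical thickness draped over the joint dome, with an elliptical footprint
(default 20 mm sagittal x 12 mm transverse — an inflamed MCP synovial
cavity extends proximally and distally into its recesses), crown at the
clinical depth of 2.3 mm, dome sagitta 2 mm, and thickness 2.5 mm. The
thickness is the height of the distended synovial compartment (hypertrophic
membrane plus effusion), for which 2-4 mm is typical of active MCP
synovitis on MRI/ultrasound; the pocket volume (~0.48 mL) is likewise in
the range reported for inflamed MCP joints. Joint swelling is modeled by
scaling the thickness by `1 + swelling/100`; pocket volume is exactly
linear in thickness (footprint area x thickness), so 100% swelling doubles
the dye-filled volume while leaving the roof depth unchanged.

All geometry is voxelized on an isotropic grid (0.5 mm default for
production runs, 1 mm in most tests); depth is measured from the top tissue
surface to voxel centers, and the pocket crown snaps to the nearest
voxel-center depth (within spacing/2 of the requested value).

## Numerical scheme

* 7-point finite-volume stencil; harmonic-mean face diffusivity (the
  default optics are uniform across tissue and synovium, so this matters
  only for band-specific or perturbed configurations).
* Robin faces are folded into the diagonal by ghost elimination, giving an
  outward face conductance `2D / (h + 4 Cr D)`; the discrete operator is
  symmetric positive definite and conserves power exactly, so
  absorbed + boundary loss = injected up to the linear-solve residual.
* Conjugate gradients with Jacobi preconditioning, relative residual 1e-5
  (configurable), deterministic.
* Validation oracle: the infinite-medium Green's function
  `P exp(-mu_eff r) / (4 pi D r)`, `mu_eff = sqrt(mu_a / D)`. A centered
  point source in a padded homogeneous cube matches it within ~1-5%
  (grid-dependent) at mid-range radii, with observed convergence order
  above 1 under grid refinement.
* The excitation pass ignores dye-dependent absorption (linear regime:
  nanomolar concentrations add ~1e-5/mm to mu_a, three orders below the
  tissue background); the forward model is therefore exactly linear in the
  concentration map, and concentration-ratio sweeps are computed by
  superposition of two basis emission solves (uniform background +
  synovium-only excess). The equivalence with per-ratio solves is asserted
  in the test suite.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| mu_a (tissue, both bands) | 0.01 | 1/mm | typical NIR soft-tissue absorption |
| mu_s' (tissue, both bands) | 1.0 | 1/mm | typical NIR reduced scattering; also 1% Intralipid |
| Cr | 2.95 | – | internal reflection for n ~ 1.4 tissue/air |
| mu_a (phantom) | 0.005 | 1/mm | 50 ppm India ink at ~780 nm |
| quantum yield | 0.12 | – | IRDye800CW-class fluorophore |
| mu_fx | 5.5e-5 | 1/(mm nM) | epsilon ~ 2.4e5 /M/cm; absolute value cancels in TBR |
| joint depth | 2.3 | mm | clinical MCP joint depth used in simulation (2.5 mm in the phantom) |
| background conc. | 10 | nM | equivalent-dye background |
| background CV | 0.64 | – | conservative late-time variability; presets 0.51 (clinical) and 0.125 also exposed |

Excitation and emission optics default to identical values; band-specific
values are accepted through the config.

## Detection statistics

TBR is the mean signal over the joint ROI divided by the mean over a
background ROI. The target ROI is the synovium's surface projection eroded
by 2 pixels, keeping clear of the diffuse rim of the joint patch; the
background ROI is an annulus 5-12 mm from the projection (adjacent
background, as drawn in practice, so large-scale gradients from the finite
tissue extent cancel), excluding a 5 mm border at the image edge. With
uniform dye this construction yields TBR = 1.018 on the default geometry —
the residual 2% is the footprint of the finite slab.

Background noise is proportional to the background level (fixed CV), so
CNR = (TBR - 1)/CV. Detection is one-sided with the joint location known a
priori: call "inflamed" when CNR exceeds the inverse-normal quantile of the
chosen confidence (1.645 at 95%; no multiple-testing correction by
default). A seeded Monte-Carlo routine verifies the threshold-to-probability
mapping by drawing normal background replicates. Sweeping the
synovium:background concentration ratio gives a CNR curve — TBR - 1 is
proportional to ratio - 1 (Pearson r > 0.999 in the suite) — and
piecewise-linear interpolation at the threshold yields the minimum required
ratio. The sweep must bracket the threshold; on the default geometry that
requires extending the sweep to ratios up to 14.

On the default flat-slab geometry, the required ratio interpolates to ~9.3
(0.5 mm grid; ~10.2 at 1 mm), robust to ±50% changes in tissue absorption
(9.2-10.0). Two geometric simplifications make the slab conservative
relative to an anatomically contoured hand. First, lateral dilution: a
20 x 12 mm target at 2.3-6 mm depth delivers only ~40% of its
laterally-infinite contrast to the surface ROI (the 1D limit of the same
solver puts the operating point near 4-5.5:1). Second, in a real hand the
convex knuckle surface wraps the detector plane closer to the synovial
envelope and background ROIs fall on thinner tissue; both raise contrast.
Mesh-based anatomy is deliberately out of scope. TBR is also only weakly
affected by joint swelling: doubling the pocket thickness at ratio 10
changes TBR by less than halving the concentration ratio does.

## Pharmacokinetics

Non-compartmental analysis with the linear trapezoidal rule over the
observed window only — no log-linear segments, no terminal extrapolation.
Bioavailability is the dose-normalized AUC ratio of an extravascular route
to IV. The synthetic generator produces one-compartment profiles: Bateman
curves `F D/Vd ka/(ka-ke) (e^{-ke t} - e^{-ka t})` for SC/PO (the
degenerate `ka = ke` form is rejected), pure exponentials for IV, with
optional mean-one lognormal noise of stated CV. Default rates
(`ka = 0.03/min`, `ke = 0.005/min`) put Tmax near 1 h, matching
subcutaneous absorption of peptide-scale agents. On the sparse 8-point
blood-draw schedule (5 min - 24 h) the trapezoidal estimate recovers a
generating F = 0.9 within 15% (within 3% on a dense grid); the residual
bias is the area missed before the first sample and the coarse trapezoids
around the peak.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the study inputs — phantom
optics and concentrations, noise levels with stated CV, sampling schedules
— not real-tissue heterogeneity: no spatially varying optics, bones,
vasculature, skin layers, instrument response, or inter-subject variation.
Passing tests therefore demonstrate the internal consistency and numerical
fidelity of the pipeline (solver vs. analytic oracle, statistics vs. their
closed forms, parameter recovery under the stated noise), and the
feasibility conclusions inherit the stated geometric idealizations above.

## Problem sizes

Production feasibility sweeps run on the 0.5 mm grid (~1.0e6 unknowns per
solve, three solves per sweep via superposition); the test suite uses the
1 mm grid (~1.2e5 unknowns) and compact domains, which reproduce the same
statistics to within a few percent.
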