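# Methods

## The model

A charged macromolecule in a low-ionic-strength electrolyte is screened by
its counterion atmosphere; at separations beyond the Debye length
kappa^-1 it interacts as if it carried a reduced, *effective* charge
q_eff, with renormalization factor eta = q_eff/q_str. This package
computes q_eff two ways and connects both to the escape-time observable of
the electrostatic fluidic trap:

1. **Continuum electrostatics.** The nonlinear Poisson-Boltzmann (PB)
   equation for a symmetric 1:1 electrolyte,

       div(eps eps0 grad phi) = 2 c0 N_A e sinh(e phi / kBT),

   is solved around molecular models (uniformly charged rods, bead
   half-helices, atomistic structures with forcefield partial charges) in
   bulk and in the slit geometry. The electrostatic free energy is the
   functional

       F_el = Int_V [ eps eps0/2 |E|^2
                      - 2 c0 N_A kBT (cosh psi - psi sinh psi - 1) ] dV,

   integrated over the solvent region only (psi = e phi/kBT). Two routes to
   the effective charge are implemented:
   - *far-field matching*: least-squares fit of the computed bulk far field,
     sampled on a shell 2-3 Debye lengths from the surface, to a
     superposition of screened-Coulomb kernels on the charge sites with one
     adjustable amplitude;
   - *trap route*: q_calc = (F_slit - F_pocket)/phi_m, with F computed for
     the molecule between the charged plates and in bulk (the pocket gap is
     many Debye lengths, so the pocket state is bulk-like) and phi_m the
     molecule-free midplane potential. Both routes agree to better than 2%
     in the measurement regime (kappa h >= 5, |phi_m| << 1); the far-field
     route is the default because it needs one solve instead of three.

2. **Escape-time statistics.** Residence times in a trap are exponential
   with mean t_esc ~ exp(W/kBT), W = q_eff phi_m + dF_trans. The package
   maps W to t_esc with the exact mean first-passage time (MFPT) of an
   overdamped particle in a radially symmetric well, calibrates the device
   surface potential phi_s from a species of known charge (28.2 e / 45.6 e
   for 30/60 bp dsDNA), and inverts measured t_esc values into q_eff.

3. **Rigid-rod inversion.** |q_calc| versus axial charge spacing b is
   nearly linear over b = 0.35-0.65 nm for 60-base rods; inverting a
   measured |q_eff| through that relation estimates the projected
   inter-phosphate spacing, compared against contour length per base b_c
   from scattering experiments.

## Numerical scheme

All solvers are cell-centred finite-volume discretizations with damped
Newton iteration on the sinh term (relative residual tolerance 1e-8 by
default; backtracking line search guarantees monotone residual decrease).

* **1D / 2D / axisymmetric.** Tridiagonal or sparse-LU linear algebra. The
  slit-pocket cross-section uses axis-aligned walls (no stair-stepping);
  wall charge enters as constant-flux Neumann conditions,
  -eps eps0 grad phi . n = sigma_w. The axisymmetric rod solver places
  grid lines exactly on the rod surface; the side surface carries
  sigma = q_str/(2 pi r l) and the caps are uncharged.
* **3D.** One monolithic nonuniform tensor-product grid: uniform fine
  spacing (default 0.1 nm) across the molecule, geometric stretching
  (ratio 1.18) to a far-field spacing of kappa^-1/3, open boundaries at
  8 Debye lengths (6 in the large acceptance runs) clamped to psi = 0.
  This serves the same purpose as a focusing-grid hierarchy while keeping
  near- and far-field consistent in a single solve. Each Newton step is
  solved by conjugate gradients preconditioned with an exact fast
  diagonalization of the separable constant-coefficient Helmholtz part of
  the Jacobian (per-axis eigendecompositions plus tensor contractions), so
  no 3D sparse factorization is formed; typical solves need 3-5 Newton
  steps of 10-30 CG iterations.
* **Molecules in 3D.** Atomic spheres inflated by the ion-exclusion width
  w (default 0.2 nm) define the ion-free interior with relative
  permittivity eps_mol = 2; face permittivities are harmonic means, which
  enforces the dielectric matching conditions discretely. Partial charges
  are deposited as trilinear point sources at the atom centres (the
  nominal 0.02 nm seed radius is far below the grid scale; the exterior
  field and all reported energy differences are independent of it).
* **Free energy.** The gradient term is accumulated face-by-face with the
  same metric as the solver, so self-energy discretization errors cancel in
  differences between solves on identical grids; the trap route always uses
  one grid for the slit, empty-slit and bulk states.

Validation oracles (in the test suite): screened-Coulomb and Bessel-K0
Debye-Hueckel closed forms in the linear limit (<= 3%), electroneutrality
of the ion atmosphere (<= 2%), a 1D radial nonlinear PB oracle for the
Manning limit of thin rods, grid-refinement stability of q_calc (< 1%),
and cross-route agreement (<= 2%).

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| temperature | 298.15 K | standard biomolecular PB practice |
| solvent eps_r | 78.5 | water at 25 C; gives l_B = 0.714 nm and kappa^-1 = 0.3042/sqrt(c0) nm |
| interior eps_mol | 2 | ion-free molecular interior |
| ion-exclusion width w | 0.2 nm | hydrated-cation layer at the molecular surface |
| charge-seed radius | 0.02 nm | sub-grid; energies reported only as differences |
| wall charge sigma_w | -0.1 e/nm^2 nominal | silica; devices are usually specified by the calibrated phi_s instead |
| half-helix geometry | rise 0.338 nm, twist 36 deg, P radius 0.89 nm | one strand of the canonical B-form duplex |
| dye offset | -0.62 e per two-dye label, -0.31 e single | the only published anchor; each dye also adds -1 e of structural charge |
| rod b grid | 7 points, 0.35-0.65 nm | the computed range of the spacing sweep |
| trap: pocket radius | 300 nm | device nanostructure radius |
| trap: rim width | 15 nm | of the order of the Debye length at 0.6-1.2 mM |
| trap: absorbing radius | 1.5 x pocket radius | midway toward a neighbouring trap of the lattice |
| dF_trans | ln[(2h+d-2 r_H)/(2h-2 r_H)] kBT | confinement entropy of a sphere of hydrodynamic radius r_H; cancels between species of equal r_H |
| lag exclusion | first 2 frame bins | removes transiently trapped weakly charged contaminants |

## Escape-time details

The residence-time fit is the exact maximum-likelihood estimator for
frame-discretized, left-truncated exponential data (a geometric likelihood
in frame counts); by memorylessness the lag exclusion does not bias the
mean. The reported standard error is t_esc/sqrt(N).

The trap landscape is flat at depth -W inside the pocket, rises linearly
across a 15 nm rim, and escapes are scored on an absorbing circle at 1.5
pocket radii. For this family the MFPT quadrature gives
d ln(t_esc)/dW = 0.92 over W = 2-5 kBT, i.e. Kramers scaling holds to
within 10% already at modest depths and improves with depth (the deficit
is the depth-independent in-well diffusion time). Brownian-dynamics
simulation of the identical landscape (Euler-Maruyama, timestep bounded by
0.01 rim^2/D) reproduces the quadrature within sampling error and yields
exponential residence-time distributions. Because calibration and
inference run through the same MFPT map, device calibrations and charge
inferences are exact round trips up to event-sampling noise.

## Synthetic data

The generators emulate the statistical structure of the study's raw
inputs, not their microscopic detail:

* **Escape events** are exponential durations discretized to the camera
  frame interval, optionally mixed with a short-mean contaminant component
  (default mean 2 ms) that reproduces why the shortest lags are excluded.
  They do not model blinking, tracking errors or drift.
* **Chain ensembles** are discrete worm-like chains with fixed bond length
  b_c and thermally distributed bend angles tuned to a persistence length
  l_p (Kuhn convention, so l_p = b_c/2 is the freely jointed limit);
  defaults b_c = 0.56 nm, l_p = 2 nm represent an ssDNA homopolymer at
  ~1 mM salt. They reproduce (R_g, R) landscapes and closed-form <R^2>
  but carry no sequence-specific stacking or hairpin states -- so passing
  ensemble tests demonstrates correct polymer statistics, not forcefield
  realism.
* **Device fixtures** bundle the published geometry/salt/surface-potential
  combinations. One fixture also stores the source's kappa*h bookkeeping
  value verbatim; it is not derivable from the stored h and c0 (the
  conventions disagree in the source) and is never recomputed.

## Design choices where the ground was open

* q_calc route: far-field matching in bulk by default; the slit free-energy
  route is kept as the validation path (identical in linear response,
  three times the cost).
* The dye effective-charge offset is a configuration scalar; nothing in
  the main-text record fixes its chain-length dependence, so the single
  published value (-0.62 e for the two-dye 60-base case) is used for all
  doubly labelled species and half of it for single labels.
* Representative selection from an ensemble: Gaussian KDE in (R_g, R)
  (plug-in bandwidth); the stated-percentile contour is the highest-density
  region holding that mass fraction, and extreme-R members inside it are
  reported. For fewer than 20 conformers a nearest-neighbour density
  replaces the KDE.
* Degenerate inputs: uncharged problems return identically zero fields;
  identical-conformer ensembles return the single conformer three times
  with a warning; calibration refuses devices whose surface potential
  cannot reproduce the calibrator within (-6, 0) kBT/e.

## Problem sizes

Default test and acceptance runs use: 7-point rod sweeps at two radii
(axisymmetric grids of ~2-5 x 10^4 cells), one 2D device solve
(~3 x 10^5 cells), five 3D half-helix solves (~1-2 x 10^6 cells each,
6-Debye-length padding), one 3D route cross-check (three ~5 x 10^5-cell
solves), Brownian-dynamics ladders of a few hundred events per depth and
a 5000-event distribution sample, and 10^4-3 x 10^4 synthetic events per
statistical fit. These sizes hold every validation tolerance quoted above
while keeping a full run on a single CPU within tens of minutes.

## Known limitations

* Mean-field PB: no ion-ion correlations, dielectric saturation or
  specific binding; finite ion size enters only through w.
* The slit trap route assumes the molecule sits at the midplane with its
  principal axis parallel to the walls (the free-energy minimum).
* The computed |q_calc|(b) relation is slightly concave; a straight-line
  summary over 0.35-0.65 nm carries ~1-2% pointwise residuals, and its
  slope depends on the fitted window.
* Absolute escape times depend on the hydrodynamic radius and trap
  geometry; only ratios and calibrated inferences are meaningful, matching
  how the measurement is used.
* eta is meaningful for fully ionized (acidic) molecules with fixed
  structural charge; titratable groups are out of scope.
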