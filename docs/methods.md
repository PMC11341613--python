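# Methods

`atriarom` couples three layers: a desk-scale full-order model (FOM) of
incompressible blood flow in an idealized atrium-with-appendage geometry,
passive-scalar and wall-shear post-processing that yields the standard blood
stasis indices, and a non-intrusive POD-RBF reduced-order model (ROM) of those
indices over the physical parameters.  This note records the governing
equations, the numerical choices, the defaults and why they were chosen, and
what the synthetic setting can and cannot show.

## Full-order flow model

The flow solves the incompressible Navier–Stokes equations

    rho dv/dt + rho div(v ⊗ v) − div(T) = 0,   div(v) = 0,

with blood density rho = 1050 kg/m³ and Cauchy stress T = −p I + 2 mu D(v),
D = (grad v + grad vᵀ)/2.  Two constitutive laws are available:

* **Newtonian**: constant dynamic viscosity mu = 0.0035 Pa·s.
* **Casson** (shear-thinning with a yield stress):

      mu(J2) = [ (eta_bar² J2)^¼ + (tau_y/2)^½ ]² J2^−½,

  where J2 = ½ D:D is the second strain-rate invariant (shear rate
  gamma = 2 sqrt(J2)), eta_bar = eta / (1 − H/100)^2.5 with plasma viscosity
  eta and hematocrit H (stored in percent), and tau_y = (0.290 · H/100)³ Pa.
  This is the standard Casson form: its outer exponent 2 makes the tau_y → 0
  limit exactly Newtonian with mu = eta, which the solver relies on as a
  consistency invariant.  A square-root variant of the law that circulates in
  parts of the literature is retained behind
  `RheologyParams(casson_form="sqrt")` for comparison; it does not recover a
  constant viscosity at zero yield stress and is not used by default.
  The yield-stress singularity at J2 → 0 is regularized by evaluating the law
  at max(J2, J2_min) with J2_min = 1e-12 s⁻² (configurable); the regularized
  viscosity is finite, positive, continuous and monotone non-increasing in J2
  with mu → eta_bar at high shear.

### Discretization

Cell-centred finite volumes on a uniform Cartesian grid restricted to the
active (fluid) cells.  One time step is an incremental pressure-correction
(fractional-step) scheme:

1. **Momentum predictor** — implicit Euler in time; convection implicit
   first-order upwind, raised to second order (linear-upwind) by an explicit
   deferred correction built from Green–Gauss gradients; diffusion implicit
   with the viscosity lagged one Picard iteration (evaluated from the previous
   velocity field, which keeps each step linear); the transpose-stress term
   div(mu (grad v)ᵀ) explicit (it vanishes analytically for constant
   viscosity); the previous pressure gradient on the right-hand side.  The two
   velocity components share one sparse factorization.
2. **Pressure correction** — face fluxes are obtained from the predictor by
   linear interpolation plus a Rhie–Chow substitution of the compact pressure
   gradient for the interpolated one (suppressing the collocated-grid
   checkerboard mode); a pressure-correction Poisson equation with a fixed
   zero reference on the outlet is solved with a prefactorized direct solver;
   fluxes and cell velocities are corrected.  The corrected face-flux
   divergence is zero to linear-solver precision (observed ~1e-19 m²/s per
   cell; the solver aborts above `div_tol`).

Boundary conditions: Dirichlet plug velocity on the inlets (equal flow rate
per inlet, directed inward), no-slip walls, zero-gradient velocity with the
pressure reference at the outlet.  Global mass balance is enforced each step
by an additive correction of the outlet fluxes, which also covers the closed
phase of the cycle when all prescribed rates vanish.

Time steps satisfy both `dt_max` (0.01 s) and a maximum cell Courant number
(0.8); the solver subcycles so that steps land exactly on the uniform
snapshot schedule t_i = i · dt_snap, avoiding interpolation in time.  One
cardiac cycle of period T = 1.07 s at dt_snap = 0.01 s yields 107 snapshots;
runs start from rest (v = 0) and integrate `n_cycles` cycles (default 4),
collecting statistics on the final cycle, whose cycle-to-cycle kinetic-energy
drift falls from ~1e-2 after two cycles to ~4e-6 after four on the toy case.

### Verification oracles

* Developed Poiseuille flow in a straight channel: centreline/mean velocity
  ratio 1.5 (observed within 0.3 % at 25 cells across the channel) and the
  analytic wall shear stress 6 mu U / b (within ~0.5 % with the
  solver-consistent wall gradient, see below).
* Rigid translation and rotation give exactly zero strain invariant; simple
  shear with gamma = 2 s⁻¹ gives J2 = 1 s⁻².
* A Casson run at H = 0 reproduces the Newtonian fields to ~1e-14 relative
  (identical code path, constant effective viscosity).

## Stasis indices

**Age moments.**  The first and second moments of the blood-age distribution
obey advection–diffusion equations with source rho·k·m_{k−1} (m0 ≡ 1),
diffusivity 1e-10 kg/(m·s), Dirichlet 0 on the inlets, zero normal gradient
elsewhere, initial value 0.  m1 is the mean age of blood at a point; large m1
marks stasis.  **Washout** solves the same equation without the source from
initial value 1; its residual after a cycle marks poorly cleared regions.

The scalars are segregated: they consume the velocity snapshots (and the
divergence-free face fluxes) stored by the flow solver, advancing with
implicit Euler on the snapshot schedule.  Convection defaults to first-order
upwind, which guarantees m_k ≥ 0 and washout in [0, 1] by the discrete
maximum principle — at desk resolution boundedness is worth more than formal
order, and a linear-upwind option is available.  Oracles: stagnant fluid ages
linearly (m1 = t exactly under implicit Euler); steady plug flow gives
m1 = x/u and m2 = (x/u)² (first-order upwind bias ~ h/x, verified within 3 %
on a 200-cell channel); the washout front clears the channel after t > L/u.

**Wall shear stress.**  WSS = T_d · n on wall faces; at a no-slip wall the
tangential component mu du_t/dn dominates.  The wall-normal gradient uses the
same one-sided two-point stencil as the solver's wall diffusion and the same
effective viscosity (evaluated at the wall shear rate), so the reported
stress is the one the discrete momentum balance actually exerts — this
estimator reproduces the Poiseuille wall stress to ~0.3 %, whereas formally
higher-order extrapolations of the slightly perturbed near-wall profile do
worse.

**TAWSS and OSI.**  TAWSS = (1/T)∫‖WSS‖dt and
OSI = ½[1 − ‖∫WSS dt‖/∫‖WSS‖dt] per wall face.  The snapshots sample one
period uniformly without a duplicated endpoint, so the trapezoidal rule for a
periodic signal reduces to (sample mean) × T; this periodic closure makes a
constant magnitude give TAWSS = c exactly and a half-period sign flip give
OSI = 0.5 exactly, and for smooth periodic signals it agrees with adaptive
quadrature to below 1e-10 at 256 samples.  Faces with identically zero shear
(0/0 in the OSI ratio) are assigned OSI = 0, consistent with the
unidirectional limit.  Indices integrate over the final cycle.

## Reduced-order model

Snapshots of each variable Phi ∈ {m1, m2, washout, TAWSS, OSI} are collected
into a matrix S (N_h × N_s) with columns ordered parameter-outer /
time-inner; TAWSS and OSI are steady (cycle-integrated) variables with one
column per parameter sample.  A thin SVD of the uncentred S (no mean
subtraction — the expansion uses raw solutions) yields orthonormal modes and
singular values; the retained count L is the smallest integer whose
cumulative squared singular values reach the energy threshold eps (default
0.99; the sweep default is {0.90, 0.95, 0.99, 0.999}).  The thin SVD is the
numerically safer equivalent of the snapshot-correlation eigenproblem; the
Eckart–Young identity (training reconstruction error² = tail singular-value
energy) is asserted in the tests.

Modal coefficients alpha = Bᵀ S are interpolated over x = (t, mu) — or mu
alone for steady variables — by RBF interpolation with a degree-1 polynomial
tail and the moment constraints sum w_j = 0, sum w_j x_j = 0, solved as one
augmented symmetric system per variable (all modal coefficients share the
kernel matrix).  Default kernel: thin-plate spline, the natural partner of a
degree-1 tail and parameter-free; Gaussian and multiquadric kernels with a
shape parameter are selectable.  Inputs are affinely normalized to [0, 1] per
coordinate before kernel evaluation — the raw coordinates mix seconds, Pa·s
and percent and would otherwise be hopelessly ill-conditioned.  Coordinates
that do not vary across the training nodes are excluded from the polynomial
tail (they would duplicate the constant column).  Time enters the RBF jointly
with the parameters (one map F: T × K → R^L), not per-time-instant models.

Parameter designs: equispaced sampling for the one-parameter Newtonian case
(f ∈ [0.5, 1.5], 20 points by default) and seeded Latin hypercube sampling
for the Casson case (f, eta ∈ [1.5e-3, 1.7e-3] Pa·s, H ∈ [35, 50] %, 30
points).  Held-out validation samples are selected by index in the design
configuration.  Accuracy is measured by the relative Frobenius error per time
instant (unsteady) or per field (steady), plus time-averaged summaries.

On a manufactured smooth snapshot family with geometrically decaying modal
content, the held-out error at a new parameter at least halves whenever the
training design is doubled (until the interpolation floor), and the energy
sweep reproduces the expected pattern: mode counts grow with eps while the
held-out error plateaus once the dominant modes are captured.

## Synthetic case and its limits

The case generator replaces the patient anatomy by a 2-D rectangular chamber
(default 40 × 20 mm, h = 1 mm) with a blind rectangular pocket (10 × 6 mm)
attached to the left wall as the appendage surrogate, n equal inlets on the
top wall ("pulmonary veins") and one centred outlet on the bottom wall
("mitral valve").  The outlet waveform is an analytic pulse: zero during the
closed phase, a smooth sin² pulse opening at 0.4·T, scaled exactly linearly
by the cardiac-output factor f and normalized so that its integral over a
cycle is the configured stroke volume (default 3e-4 m² per unit depth, ~37 %
of the chamber area — only the period, the opening time and the scaling-factor
structure are prescribed by the study setting; the pulse shape and stroke
volume are package defaults chosen to give a laminar, clearly pulsatile
chamber flow).  Walls are rigid.

This setting reproduces the *mechanism* under study — the blind pocket
retains old blood (cycle-end washout ≈ 1.0 in the pocket vs ≈ 0.34 in the
chamber on the toy case; mean age correspondingly higher) — and exercises
every operator end-to-end.  It does not reproduce patient-specific anatomy,
3-D secondary flows, moving walls or measured inflow waveforms, so passing
tests validate the numerics and the ROM machinery, not clinical error levels;
quantitative FOM–ROM errors on patient geometries are outside what this
synthetic setting can certify.

## Problem sizes and determinism

Test and acceptance runs use desk-scale meshes (a few hundred to a few
thousand cells), one to four cycles, and manufactured families with
N_h = 300, N_t = 15 and up to 16 design points — sizes chosen so the entire
suite verifies the contracts in minutes on one core.  All randomness
(Latin hypercube designs, manufactured-family draws) is seeded; offline reruns
with the same configuration are bit-identical, which the tests assert.

## Known limitations

* 2-D per-unit-depth formulation; no turbulence model (the study regime is
  laminar) and no fluid–structure interaction.
* First-order upwind scalar transport smears fronts at coarse resolution
  (the washout front check accounts for it); the linear-upwind option trades
  boundedness for sharpness.
* The collocated projection is first-order accurate in time per step
  (incremental form); steady and periodic-state quantities, which the indices
  integrate, are insensitive to this.
* Thin-plate-spline interpolation is global: offline cost grows as the cube
  of the number of training columns, which caps practical designs at a few
  thousand snapshots — the study-scale designs (≤ 3210 columns) fit.
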