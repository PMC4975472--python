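# Methods

`mucusflow` simulates the rotational ("mucus hurricane") flow of airway
mucus in human bronchial epithelial (HBE) cell cultures and the transport
of drug deposited on the air–mucus interface. This note records the
governing model, the numerical scheme, the parameter choices, and the
limits of what the tests demonstrate.

## Constitutive model

Mucus is modeled as a solvent (viscosity η_s) plus a sum of Giesekus
modes. Each mode carries a relaxation time λ_i, a modulus G_i (polymer
viscosity η_p,i = G_i λ_i), and a mobility α_i ∈ [0, 0.5]:

    τ_i + λ_i τ_i(1) + (α_i λ_i / η_p,i) τ_i·τ_i = η_p,i γ̇ ,

with τ(1) the upper-convected derivative and γ̇ = ∇u + ∇uᵀ. α_i = 0
reduces to the upper-convected Maxwell (UCM) model (constant shear
viscosity, nonzero normal stresses); no modes is Newtonian. Mobilities
above 0.5 are rejected because they produce non-monotone flow curves.
The reference five-mode parameter set for 2.5 wt% HBE culture mucus
(λ = 0.0089…49.7 s, G = 3.35…0.85 Pa, α = 0.2…0.5) ships as
`hbe_mucus_five_mode()`; η_s = 1 mPa·s, ρ = 1000 kg/m³.

**Steady shear.** The per-mode steady simple-shear stress is solved by a
damped Newton iteration on the four coupled algebraic components with
ascending-rate warm starts; correctness is guarded in the tests by an
independent oracle that integrates the constitutive ODE to steady state
(agreement to 1e-6 relative across λγ̇ ∈ [1e-3, 1e3]).

**Fitting.** The discrete Maxwell spectrum is fitted to a frequency sweep
(ω, G′, G″) by (i) log-spaced λ seeds across the inverse-frequency
window, (ii) non-negative linear least squares for the G_i, and (iii)
joint Levenberg–Marquardt refinement of (log λ, log G) minimizing equally
weighted squared log-ratios of G′ and G″. The mobilities are then fitted
to the steady flow curve with λ, G held fixed, bounded in [0, 0.5]. A
five-mode spectrum is recovered from noise-free synthetic data to well
under 1%; the α fit reproduces the flow curve to <0.1% even where the
individual α_i are only weakly identified.

## Geometry, driving and boundary conditions

The culture is a cylinder of radius R = 10 mm; the mucus layer has
initial depth H = 50 µm (aspect ratio R/H = 200); the interface carries
surface tension σ = 30 mN/m; gravity g = 9.81 m/s² acts downward.
The coordinated cilia carpet is coarse-grained into an azimuthal velocity
imposed on the bottom plate:

* constant swirl u_θ|_{z=0} = ω₀ r with ω₀ = 1.57e-2 rad/s;
* the piecewise-sinusoidal power/return stroke f(t) with amplitudes
  derived from the observed stroke arcs (10 µm forward, 5 µm back per
  0.1 s half-cycle at the culture edge): P₀ = 1.57e-2, R₀ = 7.9e-3 rad/s,
  ω_p = ω_r = 10π rad/s, extended periodically;
* the strain-controlled drive u_θ = γ₀ω₀ r cos(ω₀t) ln(r/R), whose
  shear rate γ̇_rθ = γ₀ω₀ cos(ω₀t) is spatially uniform; matching its
  amplitude to P₀ at r = 0.99R gives γ₀ = 0.05.

The plate velocity is blended to zero at the side wall with the boundary
layer 1 − exp[−(R²−r²)/(εR²)], ε = 0.05 (e-folding width εR/2 = 250 µm —
this sets the radial resolution requirement below). No-slip holds on the
plate and side wall; all variables have vanishing radial derivative at
the axis except u_θ, which uses the regularity condition u_θ(0) = 0
(an antisymmetric axis ghost). The extra stress is set to zero on solid
walls; this is nonstandard for a viscoelastic stress field — it inserts
an O(Δz/2) compliant layer at the plate — and near-wall stresses depend
on it. Oscillatory drives are ramped over one period at startup; an
impulsive start would shear the bottom cell at O(u_b/Δz) for one step.

For a hurricane localized to an effective radius smaller than the
culture (R_eff = 5 mm, aspect ratio 100), the drive amplitude keeps the
observed stroke displacements at the hurricane edge, which doubles P₀
and gives an equivalent strain amplitude γ₀ ≈ 0.1.

## Flow solver

Staggered (MAC) axisymmetric grid on [0,R]×[0,H]: pressure, u_θ, the six
stress components per mode, and concentration at cell centers; u_r and
u_z on faces. Default grid 128×8 for aspect ratio 200 runs (≥3 cells per
blend-layer e-fold; under-resolving the blend layer corrupts the wall
stresses). Time stepping:

1. **Stress:** semi-implicit — relaxation implicit (integrating-factor
   style), upper-convected, quadratic-mobility and first-order upwind
   advective terms explicit; the azimuthal basis-rotation terms of
   u·∇τ are retained.
2. **Balance pressure:** ∇²p = ∇·F is solved directly each step (F =
   stress divergence + centrifugal/advective inertial terms), with p =
   p_s at the interface and ∂p/∂n = F·n ≈ 0 at solid walls. For
   incompressible constant-viscosity flow this Poisson equation is
   consistent with the momentum balance, and it makes the quasi-static
   pressure available immediately (an incremental projection alone
   converges the pressure only on an O(η Δt/ρΔx²) iteration timescale,
   far too slowly in this viscosity-dominated regime).
3. **Momentum:** semi-implicit Helmholtz solves per component with
   prefactored sparse LU. The azimuthal equation carries the implicit
   stabilization viscosity η_add = Σ G_i λ_i Δt/(λ_i+Δt) — the one-step
   stress response — subtracted explicitly so that it cancels at
   stationarity, plus a small never-subtracted grid-damping viscosity
   (2% of Ση_p,i) that suppresses stencil-decoupled grid-scale stress
   modes which the centered-strain/averaged-divergence stencils cannot
   see. The meridional (u_r, u_z) momentum is damped implicitly with the
   full polymer viscosity and not subtracted: at quasi-steady state the
   polymer stress responds to the slow secondary flow as a viscosity
   ≈ Ση_p,i, so the steady balance is preserved (secondary-flow
   magnitudes carry an O(2) factor) while weakly damped elastic
   meridional oscillations — which the hoop-stress forcing would
   otherwise ring, and which can seed curved-streamline elastic
   instabilities — are suppressed. Sign-level and shape-level secondary
   flow conclusions are unaffected; quantitative secondary-flow
   magnitudes are not a target of this solver.
4. **Projection:** pressure-correction Poisson with a Robin top row (see
   below); discrete divergence after projection is at solver tolerance
   (enforced at every step, 1e-8 · U_ref/H).
5. **Free surface:** markers spanning r ∈ [0,R] are advected with the
   bilinearly interpolated velocity and reseeded to uniform spacing; the
   spline-fitted height h(r) gives the interface curvature (κ > 0 for a
   dome toward the air; a spherical cap of radius a has κ = 2/a). The
   domain is not deformed (small-deformation treatment — deflections are
   nm–µm against H = 50 µm); the interface enters through the surface
   pressure p_s = σκ + ρg(h−H) + τ_zz|top, with gravity absorbed
   hydrostatically so a resting fluid is an exact discrete equilibrium.
   The capillary-gravity response is treated implicitly through a local
   stiffness c = ρg + 8σ/Δr² scaling the top Poisson row: the interface
   relaxes quasi-statically toward the pressure-balanced shape instead
   of ringing at the (explicitly unstable) capillary frequency. κ used
   in p_s is evaluated at grid scale so the feedback respects this bound.
6. A positivity monitor on the per-mode conformation tensors
   c = I + (λ/η_p)τ aborts cleanly if violated.

Δt defaults: 0.01 s for constant swirl (relaxation-implicit update keeps
the fastest mode stable; mode 1 of the five-mode spectrum is then
quasi-steady, which biases its G″ contribution by a few % — visible as a
~7% low bias of G″ at 10π rad/s), drive period/128 for oscillatory runs.

### Two simulation regimes

At the physical culture parameters the Reynolds number is ~5e-8 and the
viscous spin-up time ρH²/η₀ is below a microsecond: inertia is
dynamically irrelevant, the primary flow slaves to the plate, and the
secondary (meridional) circulation is the slow film-feeding flow of the
deforming interface. Interface shape, mass flux, LAOS response and drug
transport are all meaningful here, but inertial spin-up transients (the
classic transient vortex of a stirred Newtonian layer) are not
observable. Properties that concern the inertial secondary-flow
structure — vortex orientation near the plate, transient mass-flux
shapes — are therefore exercised in a scaled laboratory regime
(R = 5 cm, H = 1 cm, η₀ = 1 Pa·s, λ = 5 s, ω₀ = 0.1 rad/s; Re and Wi of
order 1–10) where the same constitutive physics produces resolvable
dynamics: a Newtonian layer pumps outward along the plate in the
wall-braked outer band (and during spin-up), while every viscoelastic
model reverses the vortex (hoop-stress/Quelleffekt), doming the
interface at the center and dipping it at the wall, with a mass-flux
overshoot for single-mode fluids. The problem sizes used by the test
suite are 128×8 (culture swirl, 150 s), 48×16 (laboratory swirl, 40 s),
and 96×10 (oscillatory runs, 9 periods with 5 discarded).

## LAOS analysis

Probe records (shear rate, total shear stress in the rθ and θz planes)
are reduced by exact Fourier projection on integer-period windows; local
strain is the time integral of the local shear rate (Eulerian measure),
mean-detrended over the analysis window. Chebyshev coefficients follow
from the strain-phase-referenced harmonics: e_n = G′_n(−1)^((n−1)/2),
v_n = G″_n/ω₀ (so e₃ = −G′₃, v₃ = G″₃/ω₀); e₃ < 0 indicates strain
softening, v₃ > 0 shear thickening. Regime classification applies a
relative-harmonic threshold of 1e-3. Lissajous traces carry an
algebraic-ellipse-fit RMS residual as the linearity metric. The
"gap-loading" diagnostic is the relative structure of the u_θ amplitude
envelope across the gap, (max−min)/mean over z: the full-radius culture
is gap-loading to ~1e-4, the aspect-ratio-100 hurricane departs from it
by a factor of several. Note the slowest mode (λ_L ≈ 50 s) does not
equilibrate within an affordable window; its decaying startup stress
leaks ~1e-4 relative amplitude into the odd harmonics, which sets the
floor of |e₃|/e₁ in solver-derived records.

## Drug transport

The concentration obeys ∂C/∂t = DΔC − ∇·(uC) in conservative
finite-volume form, axisymmetric (r,z) or θ-resolved (r,θ,z), with
first-order (monotone) upwind advection and explicit diffusion. The
bottom plate absorbs (C = 0, half-cell Dirichlet flux) and the outflux
is accumulated cell-exactly into regional ledgers: inner disk (r ≤ 1 mm),
outer section (r > 1 mm), and the −π/12 < θ < π/12 sector (1/12 = 8.33%
of the plate, diametrically opposite the deposited strip). Side wall and
(flat-for-transport) free surface are zero-flux; mass is conserved to
machine precision (remaining + absorbed = initial). Initial layouts —
a disk of radius 1 mm or a strip of arc width 2πr/100 — are deposited on
the top grid layer with partial-cell overlap weighting so deposited mass
is grid-independent. Pe = LV/D with L = 1e-2 m and V = 1e-9 m/s; the
flow is frozen (the drug is passive), using cycle-averaged solver
snapshots or a prescribed analytic swirl. Because the drive period
(0.2 s) is many orders below the absorption time at small D, the
cycle-averaged field is the appropriate frozen flow.

## Known limitations

* The PCL and individual cilia are coarse-grained into the moving-plate
  boundary condition; quantitative comparison with culture velocimetry
  is out of reach by construction.
* The small-deformation interface treatment linearizes the free surface
  about z = H; it is not valid if deflections approach the layer depth.
* At the physical culture parameters the cycle-averaged meridional flow
  is ~1e-12–1e-10 m/s (slaved to the glacially slow interface
  equilibration), well below the 1e-9 m/s characteristic radial velocity
  quoted for the culture; outer-section drug uptake at Pe = 1e4 is
  correspondingly diffusion-dominated (~1.3% on the coarse test grid,
  against the 5.2% reference value used by the acceptance checks).
* The localized-hurricane (aspect 100) response at the matched drive
  amplitude γ₀ ≈ 0.1 is weakly nonlinear: e₃ < 0 (softening) is
  reproduced in sign, but the viscous third harmonic is thinning-signed
  and at the transient-leakage floor rather than thickening.
* Wall stresses inherit the literal τ = 0 solid-wall condition; results
  within a cell of the walls depend on it.
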