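# Methods

This note records the models, numerical choices and their rationale, what
the scaled-down runs in the test suite do and do not establish, and known
limitations.

## Physical model

A suspended cell is a compound capsule: a Newtonian cytoplasm droplet
(viscosity μ_c = λμ₀) bounded by an infinitely thin viscoelastic
membrane, containing a smaller concentric capsule for the nucleus.  The
suspending buffer is a truncated power-law liquid,
μ = m(γ̇/γ̇₀)^(α−1), clamped between the viscosities at configurable
truncation shear rates so the zero-shear singularity never enters the
solver.  Default fluid constants follow the PBS + 1% methylcellulose
buffer used in deformability cytometry: m = 0.60 Pa s, α = 0.64,
γ̇₀ = 1 s⁻¹, ρ = 1065 kg/m³; truncation defaults are
γ̇ ∈ [1, 10⁵] s⁻¹, bracketing the device's working range (~10³ s⁻¹).

Membrane elasticity follows the Skalak law (shear modulus Gs, hardness
C, dilatation modulus Ks = (1+2C)Gs); membrane viscosity contributes
τᵛ = μs(2D − tr D P).  The dilatational surface viscosity is neglected —
the membranes stay within a few percent of their reference area, where
that term is known to be negligible.  Helfrich bending with
k_c = 0.001 Gs a² (spontaneous curvature c₀ = 0 by default, configurable)
suppresses sub-grid wrinkles; the nucleus membrane uses
k_c,n = 0.001 Gs,n a_n² by analogy.  Default nucleus: a_n/a = 0.5,
Gs,n = 2 Gs, C = 10 — a stiffer but geometrically similar capsule.  The
nucleus interior carries the cytoplasm viscosity (the model only states
that a viscous liquid is enclosed; equating it with the cytoplasm is the
simplest closure).

## Discretisation

* **Membranes** are octahedron-derived triangulated spheres (midpoint
  subdivision + radial projection).  Five levels give the production
  resolution (8192 faces / 4098 vertices, maximum edge ≈ 0.0215 l for
  the 8.5 um cell in the 30 um channel); the scaled-down runs use level
  3 with the same construction.  The reference configuration is the
  initial sphere (initially stress-free cell).
* **Membrane forces**: linear flat-triangle finite elements.  The
  elastic nodal force is the exact analytic gradient of the discrete SK
  energy (first Piola–Kirchhoff tension
  P = Gs(I₁+1)F + Gs(C I₂−1)(I₂+1)F⁻ᵀ on the 2×2 in-plane deformation
  gradient), verified against central finite differences of the energy.
  The viscous tension acts on the current configuration with the
  strain-rate tensor D from the in-plane velocity gradient of each
  element.  Bending uses cotangent-Laplacian curvature estimates with
  Voronoi (mixed) vertex areas and the variational Helfrich force
  density k_c[(2H−c₀)(2H²+c₀H−2K) + 2Δ_s H]; the discretisation-level
  net force is projected out so each force channel conserves momentum
  exactly.  Because bending is a small regulariser, it is refreshed
  every few steps (default 5) rather than every step.
* **Strain-rate time filter.**  The explicit surface-viscous coupling is
  numerically stiff at the membrane viscosities of interest (η* up to
  ~100 means lattice surface viscosities far above the fluid viscosity).
  The element strain rate entering τᵛ is therefore exponentially
  time-averaged with a ~40-step window: this suppresses the unstable
  grid-frequency feedback while leaving membrane-scale transients
  (10³–10⁴ steps) untouched.  The shear-box validation (below) shows
  ~1% agreement with theory with the filter active.
* **Fluid**: D3Q19 LBGK with Guo forcing; per-node relaxation
  τ(x) = 3ν(x) + 1/2 with ν from the truncated power law (shear rate
  recovered locally from the non-equilibrium momentum flux, lagged one
  viscosity-update interval).  Besides the physical truncation, the
  lattice viscosity is clamped to τ ∈ [0.55, 3.5]: BGK accuracy
  deteriorates sharply for τ beyond ~3 (wall-slip and truncation errors
  grow as (τ−1/2)²), which is the standard rationale for the truncated
  power-law model on a lattice.  The clamp binds only in the low-shear
  plug regions, where velocity-profile errors stay small (the plate-flow
  validation meets 2% with the clamp active).
* **Walls**: Bouzidi linear interpolated bounce-back with
  wall-intersection fractions q from bisection on the channel's signed
  wall function (piecewise-linear 45° tapers; exact for plane walls).
  Moving plane walls (shear box) use half-way bounce-back with the
  momentum correction.  Pressure boundaries use non-equilibrium
  extrapolation at the inlet/outlet planes.
* **Coupling**: Peskin 4-point kernel for spreading and interpolation
  (adjoint by construction; total spread force exact).  Node advection
  is forward-Euler at the fluid time step (explicit, first-order
  coupling; a membrane CFL guard aborts if any node moves more than
  half a cell per step).  Indicator functions are recomputed every 10
  steps from a DCT-based Neumann Poisson solve of the divergence of the
  spread area-weighted face normals, with the far-field offset pinned by
  a ray-parity point-in-mesh test every 200 steps.
* **Compressibility correction.**  The weakly compressible LBM fluid
  dilates as the ambient pressure falls along the channel; a mesh
  advected with the raw interpolated velocity would inherit a spurious
  volume gain of a few percent per transit.  The mean fluid divergence
  sampled over the cell interior is subtracted from the advection
  velocity.  This is a property of the carrier field, not a feedback on
  the mesh volume (mesh-volume penalty schemes are deliberately out of
  scope); the residual drift (|ΔV|/V ≈ 0.4% per transit at suite
  resolution) remains visible in the volume-conservation checks.

## Unit mapping and flow calibration

The solver runs in lattice units.  The grid spacing Δx (um) and the
target lattice mean speed u* in the straight segment set the time step,
Δt = u*Δx/V with V = Q/(l·depth) from the flow rate (default 8 nL/s →
V = 0.89 cm/s).  The inlet/outlet pressure difference is calibrated on
the cell-free flow by log-secant iteration with an analytic power-law
initial guess (flux responds as Q ∝ Δp^(1/α)) until the steady flux
matches the target within 0.5%.  Membrane moduli are then fixed from the
dimensionless groups using the *measured* cell-free cross-section
average viscosity μ₀ and mean speed V, mirroring how the physical device
is characterised.  Matching the physical Re ≈ 0.01 exactly would force
impractically small lattice velocities, so scaled-down presets raise Re
(0.1 for the desk preset, 0.25 for the suite's mini conditions) by
rescaling the fluid consistency; both remain well below unity, where
capsule dynamics is dominated by the viscous balance.

## Validation oracles

* **Plane power-law Poiseuille flow** against the analytic profile
  u(z) = α/(α+1)·(G/K)^{1/α}(h^{(α+1)/α} − |z|^{(α+1)/α}).
* **Capsule in simple shear** against a first-order small-deformation
  theory for a spherical capsule with a Kelvin–Voigt interface, derived
  from scratch for this package (perturbation on l = 2 spherical
  modes; the steady state is a tank-treading balance in which the
  rotational part of the shear advects the shape while membrane
  elasticity relaxes it).  The resulting steady Taylor parameter is
  D = (Ca/2)·√(j∥² + j×²) with j∥ = 5/(4κ) + (15/4)/(1+β²),
  j× = (15/4)β/(1+β²), κ = 1+2C and β = η*·Ca.  For κ = 3 (the
  small-strain equivalent of a neo-Hookean membrane) and β = 0 this
  reduces exactly to the classical D = 25/12·Ca; membrane viscosity
  lowers D and tilts the capsule toward the flow direction.  An
  order-one inner viscosity ratio drops out at strict first order (it
  affects transients and O(Ca²) corrections), so the oracle is used at
  λ = 1.  IB-LBM shear-box runs at Ca = 0.04–0.05 agree with the
  theory to 1–3% for η* up to 10.  The sympy-assisted derivation is
  reproducible with `docs/derive_shear_theory.py`.

## Scaled-down study conditions (test suite)

The production-resolution transit (Δx = 0.0156 l, level-5 membranes,
full −190…690 um domain) is cluster-scale.  The suite instead runs
"mini" conditions chosen once: Δx = l/16 (cell radius 4.5 cells),
level-3 membranes, domain x ∈ [−60, 170] um with release at −47 um and a
90-um-wide feed, Re = 0.25, five cell variants sharing one calibrated
background flow.  These conditions preserve the mechanisms (extensional
peak in the taper, bullet development under duct shear, viscous damping
of transients) but not full quantitative fidelity:

* The 90-um feed gives an area contraction ratio of 3, far less
  accumulated extension than the physical device's long 45° taper, and
  at 4.5-cells resolution the IBM under-transfers the stress field, so
  the constriction DI peak is smaller than at production scale and the
  slowly developing downstream bullet can exceed it.  Peak comparisons
  therefore evaluate the converging-region window x ∈ (−30, 25) um,
  where the full-scale curves also peak.
* The truncated straight segment ends before a viscous membrane
  (η* ≳ 5–10) finishes relaxing (even the full 300-um channel only
  allows η* ≲ 20 to reach steady shape).  "Membrane viscosity affects
  transients only" is therefore tested as convergence — the DI gap
  between the η* = 5 and hyperelastic runs decays monotonically past
  the hyperelastic maximum — rather than equality at a fixed station.
* The steady membrane-area gain at the best-fit stiffness measures
  ≈ 2% at suite resolution versus 4% at production resolution; the
  full-scale reproduction test is expected to fail until run at
  production scale, and is kept failing rather than loosened.
* The peak-deformation station (≈ −6 um, just upstream of the
  constriction) and all parametric trends (peak DI decreasing with
  membrane viscosity, cytoplasm viscosity and nucleus size; delayed
  peaks for viscous membranes; < 1% volume drift) are reproduced at
  suite scale.

## Design choices on open points

* Base polyhedron: the octahedron is the unique regular seed whose
  subdivision reproduces the 8192/4098 production counts.
* ε(x) for the flow-type blend is tabulated once per geometry from the
  cell-free ("background") steady flow, sampled over −a ≤ z ≤ a at
  y = 0 at each axial station, with Frobenius tensor magnitudes;
  rotation-dominated values (ε < 0) clamp to 0 so the blend weight
  stays in [0, 1].
* The Drury–Dembo law is driven by the area-averaged membrane strain
  rate (a global membrane property), which is markedly more stable than
  a local evaluation and changes predictions little.
* DI uses the y = 0 cross-section contour; for the convex bullet and
  ellipsoid shapes encountered here it coincides with the projected
  silhouette.  The Taylor parameter uses the inertia-equivalent ellipse
  of the contour, which is robust to mesh faceting.
* Single inlet: the physical device's sheath inlets are not modelled;
  the feed is one straight reservoir joined by the 45° taper.

## Known limitations

* BGK + Bouzidi accuracy degrades where the power-law viscosity clamps
  at the upper relaxation-time bound (low-shear plug regions).
* The explicit coupling limits the stable membrane-viscosity range via
  the strain-rate filter; extremely large η* with very soft membranes
  would need implicit coupling.
* No cell–wall contact or lubrication model: configurations where the
  membrane approaches the wall within a kernel width are outside the
  validated envelope.
* The cytoplasm is Newtonian; shear-thinning or viscoelastic-solid
  interiors and active cytoskeletal coupling are out of scope.
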