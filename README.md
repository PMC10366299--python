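# celltransit

Simulation of suspended cells flowing through a constricted microchannel,
the configuration used in deformability cytometry (DC).  A cell is
modelled as a compound viscoelastic capsule — a Newtonian cytoplasm
droplet enclosed by a thin strain-hardening membrane, with the nucleus as
a smaller, stiffer capsule inside — carried by a shear-thinning
(truncated power-law) buffer through a converging / straight / diverging
channel.  The coupled fluid–structure problem is solved with an immersed-
boundary lattice-Boltzmann method (IB-LBM).  The package is aimed at
people who fit DC experiments (transient cell deformation vs. axial
position) with mechanistic cell models, and at method developers who need
a compact, fully-tested IB-LBM capsule code.

## Model

**Membrane.**  Thin viscoelastic sheet with total in-plane tension
τ = τᵉ + τᵛ.  The elastic part follows the Skalak (SK) law with strain
energy

W = (Gs/4)(I₁² + 2I₁ − 2I₂) + (C·Gs/4)·I₂²,  I₁ = λ₁² + λ₂² − 2, I₂ = (λ₁λ₂)² − 1,

giving principal tensions τᵢᵉ = (Gs λᵢ/λⱼ)(λᵢ² − 1 + C λⱼ² I₂) and the
area-dilatation modulus Ks = (1 + 2C)Gs.  The viscous part is
τᵛ = μs(2**D** − tr **D** **P**) with surface shear viscosity μs (the
dilatational surface viscosity is neglected).  A small Helfrich bending
stiffness k_c = 0.001·Gs·a² regularises the shape.  Three membrane-
viscosity laws are available: constant μs; the Drury–Dembo strain-rate
power law μs = μ₁(1 + γ̄ₘ/γ₀)ⁿ driven by the area-averaged membrane
strain rate γ̄ₘ = √(2 tr **D**²); and a flow-type blend
μs = (1−ε)μₛˢ + ε μₛᵉ, where ε = (|γ̇|−|ω|)/(|γ̇|+|ω|) is the flow-type
parameter of the cell-free background flow (0 in simple shear, 1 in pure
extension).

**Fluid.**  D3Q19 LBGK lattice-Boltzmann solver with Guo forcing; the
buffer viscosity follows the truncated power law μ = m(γ̇/γ̇₀)^(α−1)
through a per-node relaxation time, with the local shear rate recovered
from the non-equilibrium momentum flux.  Channel walls use Bouzidi
second-order bounce-back with exact wall-intersection fractions; the flow
is driven by fixed inlet/outlet pressures (non-equilibrium extrapolation)
calibrated to the target flow rate.

**Coupling.**  Peskin's immersed-boundary method with the 4-point kernel
(adjoint spreading/interpolation); front-tracking indicator (colour)
functions, recovered from a Poisson solve of the spread membrane-normal
field, assign the cytoplasm viscosity μ_c = λ·μ₀ inside the cell.

**Dimensionless groups.**  Ca = μ₀V/Gs, η* = μs/(μ₀a), λ = μ_c/μ₀,
confinement 2a/l, nucleus ratio a_n/a, Re = ρVl/μ₀, with μ₀ and V the
cross-section-averaged viscosity and mean speed in the straight segment.

**Metrics.**  Deformation index DI = 1 − 2√(πA)/P of the y = 0 contour
(A area, P perimeter; 0 for a circle), and the Taylor parameter
D = (L−B)/(L+B) for shear-flow validation, compared against a
first-order small-deformation theory for a capsule with a viscoelastic
interface (see `docs/methods.md`).

## Worked example

Production membrane mesh (five 4-to-1 subdivisions of an octahedron,
radius 8.5 um):

```bash
$ celltransit mesh --radius 8.5 --level 5 --fmt off
{"vertices": 4098, "faces": 8192, "area_um2": 907.1981831378838,
 "volume_um3": 2568.6547446802947, "file": "./sphere_r8.5_l5.off"}
```

8192 flat triangular elements connect 4098 nodes; area and volume are
within 0.15% of the analytic sphere values (908.0 um², 2572.4 um³).

Viscoelastic-membrane validation — a capsule in simple shear at
Ca = 0.05 with membrane viscosity η* = 5 against the small-deformation
theory:

```bash
$ celltransit validate-shear --ca 0.05 --eta-star 5 --steps 9000
{"Ca": 0.05, "eta_star": 5.0, "C": 1.0,
 "D_simulated": 0.09847734360021797, "D_theory": 0.10108808565845682,
 "rel_diff": -0.025826407150093766}
```

The steady Taylor parameter agrees with the theory to 2.6% (well inside
the 10% band expected of IB-LBM at D < 0.1), and decreases when η* is
raised — membrane viscosity restricts tank-treading deformation.

A full channel transit (desk preset, prints the DI/area/speed series and
a JSON summary with the peak DI and its axial station):

```bash
celltransit transit --preset desk --out run_out
celltransit analyze run_out/transit.csv
```

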