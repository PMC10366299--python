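"""Compound-cell construction and dimensionless parameter mapping.

The cell is a liquid droplet (Newtonian cytoplasm) enclosed by a
viscoelastic membrane, with the nucleus represented as a smaller,
concentric, stiffer capsule.  Cell deformation in the channel is governed
by six dimensionless groups:

* capillary number        Ca    = mu0 V / Gs
* membrane viscosity      eta*  = mu_s / (mu0 a)
* cytoplasm/fluid ratio   lam   = mu_c / mu0
* confinement ratio       2a/l
* nucleus size ratio      an/a
* Reynolds number         Re    = rho V l / mu0

where mu0 and V are the cross-section-averaged viscosity and mean speed
of the suspending fluid in the straight channel segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane_mechanics import MembraneMaterial, MembraneState
from .surface_mesh import TriMesh, make_sphere_mesh

__all__ = ["DimensionlessGroups", "PhysicalParameters",
           "dimensionless_groups", "physical_from_groups",
           "CellAssembly", "build_cell"]


@dataclass
class DimensionlessGroups:
    """The six groups governing cell deformation (all > 0)."""

    Ca: float
    eta_star: float
    lam: float
    confinement: float      # 2a/l
    nucleus_ratio: float    # an/a
    Re: float

    def __post_init__(self) -> None:
        for name in ("Ca", "eta_star", "lam", "confinement",
                     "nucleus_ratio", "Re"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhysicalParameters:
    """Dimensional inputs, SI units."""

    mu0: float        # average channel-fluid viscosity, Pa s
    V: float          # mean speed in the straight channel, m/s
    a: float          # cell radius, m
    l: float          # channel width, m
    rho: float        # fluid density, kg/m^3
    Gs: float         # membrane shear modulus, N/m
    mu_s: float       # membrane shear viscosity, N s/m
    mu_c: float       # cytoplasm viscosity, Pa s
    an: float         # nucleus radius, m


def dimensionless_groups(p: PhysicalParameters) -> DimensionlessGroups:
    """Forward mapping physical -> dimensionless."""
    vals = [p.mu0, p.V, p.a, p.l, p.rho, p.Gs]
    if any(v <= 0 for v in vals):
        raise ValueError("mu0, V, a, l, rho, Gs must all be positive")
    return DimensionlessGroups(
        Ca=p.mu0 * p.V / p.Gs,
        eta_star=p.mu_s / (p.mu0 * p.a),
        lam=p.mu_c / p.mu0,
        confinement=2.0 * p.a / p.l,
        nucleus_ratio=p.an / p.a,
        Re=p.rho * p.V * p.l / p.mu0,
    )


def physical_from_groups(groups: DimensionlessGroups, mu0: float, V: float,
                         a: float, l: float) -> PhysicalParameters:
    """Inverse mapping: groups + (mu0, V, a, l) -> dimensional parameters.

    Round-trips with :func:`dimensionless_groups` to round-off.
    """
    if min(mu0, V, a, l) <= 0:
        raise ValueError("mu0, V, a, l must be positive")
    return PhysicalParameters(
        mu0=mu0, V=V, a=a, l=l,
        rho=groups.Re * mu0 / (V * l),
        Gs=mu0 * V / groups.Ca,
        mu_s=groups.eta_star * mu0 * a,
        mu_c=groups.lam * mu0,
        an=groups.nucleus_ratio * a,
    )


@dataclass
class CellAssembly:
    """Cell membrane + nucleus capsule + cytoplasm description.

    Lengths are micrometres; the two meshes are concentric spheres at
    initialisation, offset laterally by ``offset_z`` (in -z, the
    convention of the transit runs) from the channel axis.
    """

    cell: MembraneState
    nucleus: MembraneState | None
    cell_material: MembraneMaterial
    nucleus_material: MembraneMaterial | None
    lam: float                     # cytoplasm / channel-fluid viscosity ratio
    a: float                       # cell radius, um
    an: float                      # nucleus radius, um (0 = no nucleus)
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("viscosity ratio lam must be positive")
        if self.nucleus is not None and not (0.0 < self.an < self.a):
            raise ValueError("need 0 < an < a for a compound cell")

    @property
    def meshes(self) -> list[TriMesh]:
        out = [self.cell.mesh]
        if self.nucleus is not None:
            out.append(self.nucleus.mesh)
        return out


def build_cell(a: float = 8.5, an_ratio: float = 0.5, level: int = 5,
               Gs: float = 1.0, C: float = 10.0,
               Gsn_factor: float = 2.0, Cn: float = 10.0,
               lam: float = 1.0,
               kc_factor: float = 0.001,
               release_x: float = -190.0, offset_z: float = 8.5,
               viscosity_model=None) -> CellAssembly:
    """Build the compound cell at its release station.

    Defaults follow the reference configuration: cell radius a = 8.5 um
    (2a/l = 0.57 in the 30 um channel), nucleus half the cell radius,
    SK hardness C = 10 on both membranes, nucleus membrane twice as stiff
    as the cell membrane, unit cytoplasm viscosity ratio, release at
    x = -190 um with a lateral offset of one radius along -z.  The small
    bending stiffness is ``kc = kc_factor * Gs * a^2`` (and analogously
    for the nucleus).

    ``Gs`` is in solver units (N/m at full physical scale); ``level`` is
    the mesh subdivision level (5 = production resolution).
    """
    if not (0.0 <= an_ratio < 1.0):
        raise ValueError("need 0 <= an/a < 1")
    if 2 * a <= 0:
        raise ValueError("cell radius must be positive")
    center = np.array([release_x, 0.0, -offset_z])
    cell_mesh = make_sphere_mesh(a, level, center)
    cell_mat = MembraneMaterial(Gs=Gs, C=C, kc=kc_factor * Gs * a * a,
                                viscosity_model=viscosity_model)
    nucleus = nucleus_mat = None
    an = an_ratio * a
    if an_ratio > 0.0:
        nucleus_mesh = make_sphere_mesh(an, level, center)
        Gsn = Gsn_factor * Gs
        nucleus_mat = MembraneMaterial(Gs=Gsn, C=Cn,
                                       kc=kc_factor * Gsn * an * an)
        nucleus = MembraneState(nucleus_mesh)
    return CellAssembly(
        cell=MembraneState(cell_mesh), nucleus=nucleus,
        cell_material=cell_mat, nucleus_material=nucleus_mat,
        lam=lam, a=a, an=an, center=center,
    )
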