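"""Membrane stresses and nodal forces on triangulated capsule membranes.

The membrane is a thin viscoelastic sheet: total in-plane tension is the
sum of a strain-hardening Skalak (SK) elastic tension and a surface-viscous
tension proportional to the membrane strain-rate tensor (the dilatational
surface viscosity is neglected).  A small Helfrich bending resistance
regularises the shape.  Forces are assembled with linear (flat) triangular
finite elements: the elastic part is the exact gradient of the discrete SK
strain energy, so it is energy-consistent by construction.

Conventions
-----------
* Each element carries a 2x2 in-plane deformation gradient ``F`` mapping
  the reference triangle (rotated into its own plane) onto the current
  triangle (in the current element frame).
* Principal stretches ``lam1 >= lam2 > 0`` are the singular values of ``F``.
* The surface strain-rate tensor ``D`` is the symmetric part of the
  in-plane velocity gradient of the element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .surface_mesh import TriMesh

__all__ = [
    "MembraneMaterial", "MembraneState", "ElementBasis",
    "element_strain", "sk_tensions", "membrane_viscous_tension",
    "surface_strain_rate", "bending_forces", "assemble_membrane_forces",
    "sk_energy",
]


@dataclass
class MembraneMaterial:
    """Membrane material constants.

    Parameters
    ----------
    Gs : float
        Surface shear elastic modulus (N/m, or any consistent unit system).
    C : float
        SK hardness parameter (dimensionless); the area-dilatation modulus
        is ``Ks = (1 + 2C) * Gs``.
    kc : float
        Helfrich bending modulus (N*m).
    c0 : float
        Spontaneous curvature (1/um).  Default 0.
    viscosity_model : object
        Membrane-viscosity descriptor (see ``rheology_models``); may be None
        for a purely hyperelastic membrane.
    """

    Gs: float
    C: float
    kc: float = 0.0
    c0: float = 0.0
    viscosity_model: object | None = None

    def __post_init__(self) -> None:
        if self.Gs <= 0:
            raise ValueError("Gs must be positive")
        if self.C < 0 or self.kc < 0:
            raise ValueError("C and kc must be non-negative")

    @property
    def Ks(self) -> float:
        return (1.0 + 2.0 * self.C) * self.Gs


# ---------------------------------------------------------------------------
# single-element operations (reference implementations, plain numpy)

def _element_frame(p0, p1, p2):
    """Orthonormal in-plane basis (e1, e2) and edge vectors of a triangle."""
    d1 = np.asarray(p1, dtype=float) - p0
    d2 = np.asarray(p2, dtype=float) - p0
    n = np.cross(d1, d2)
    nn = np.linalg.norm(n)
    if nn <= 0:
        raise ValueError("degenerate (zero-area) triangle")
    e1 = d1 / np.linalg.norm(d1)
    e2 = np.cross(n / nn, e1)
    return e1, e2, d1, d2


def element_strain(ref_triangle, cur_triangle):
    """Principal stretches and directions of a deformed flat triangle.

    Parameters
    ----------
    ref_triangle, cur_triangle : (3, 3) arrays
        Vertex positions of the stress-free and current element.

    Returns
    -------
    lam1, lam2 : float
        Principal extension ratios, ``lam1 >= lam2 > 0``.
    e1, e2 : (3,) arrays
        Unit principal directions in the current element plane.
    F : (2, 2) array
        In-plane deformation gradient (current frame <- reference frame).
    """
    R0, R1, R2 = np.asarray(ref_triangle, dtype=float)
    ref_e1, ref_e2, D1, D2 = _element_frame(R0, R1, R2)
    x0, x1, x2 = np.asarray(cur_triangle, dtype=float)
    cur_e1, cur_e2, d1, d2 = _element_frame(x0, x1, x2)

    X = np.array([[D1 @ ref_e1, D2 @ ref_e1],
                  [D1 @ ref_e2, D2 @ ref_e2]])
    x = np.array([[d1 @ cur_e1, d2 @ cur_e1],
                  [d1 @ cur_e2, d2 @ cur_e2]])
    F = x @ np.linalg.inv(X)
    # principal stretches from right Cauchy-Green tensor
    Cmat = F.T @ F
    evals, evecs = np.linalg.eigh(Cmat)
    lam2, lam1 = np.sqrt(np.maximum(evals, 0.0))
    if lam2 <= 0:
        raise ValueError("singular element: non-positive principal stretch")
    # principal directions in the current plane: v_i = F u_i / lam_i
    u1, u2 = evecs[:, 1], evecs[:, 0]
    v1 = F @ u1 / lam1
    v2 = F @ u2 / lam2
    dir1 = v1[0] * cur_e1 + v1[1] * cur_e2
    dir2 = v2[0] * cur_e1 + v2[1] * cur_e2
    return float(lam1), float(lam2), dir1, dir2, F


def sk_tensions(lam1: float, lam2: float, Gs: float, C: float):
    """Principal elastic tensions of the SK law.

    ``tau1 = Gs*lam1/lam2 * (lam1^2 - 1 + C*lam2^2*I2)`` and symmetrically
    for ``tau2``, with ``I2 = (lam1*lam2)^2 - 1``.  Both vanish iff the
    element is unstretched.
    """
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("principal stretches must be positive")
    I2 = (lam1 * lam2) ** 2 - 1.0
    tau1 = Gs * lam1 / lam2 * (lam1 ** 2 - 1.0 + C * lam2 ** 2 * I2)
    tau2 = Gs * lam2 / lam1 * (lam2 ** 2 - 1.0 + C * lam1 ** 2 * I2)
    return tau1, tau2


def sk_energy(lam1, lam2, Gs, C):
    """SK strain energy density per unit reference area."""
    I1 = lam1 ** 2 + lam2 ** 2 - 2.0
    I2 = (lam1 * lam2) ** 2 - 1.0
    return 0.25 * Gs * (I1 ** 2 + 2.0 * I1 - 2.0 * I2) + 0.25 * C * Gs * I2 ** 2


def membrane_viscous_tension(D: np.ndarray, mu_s: float) -> np.ndarray:
    """Surface-viscous tension ``mu_s * (2 D - tr(D) P)``.

    ``D`` is the in-plane (2x2 or 3x3 tangential) strain-rate tensor; the
    dilatational viscous term is omitted, so pure area dilatation produces
    no viscous tension.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-12 * (1 + np.abs(D).max())):
        raise ValueError("D must be symmetric")
    P = np.eye(D.shape[0])
    return mu_s * (2.0 * D - np.trace(D) * P)


# ---------------------------------------------------------------------------
# mesh-level finite-element machinery

@dataclass
class ElementBasis:
    """Static per-element reference data for a membrane mesh."""

    tris: np.ndarray       # (F, 3) int64
    invX: np.ndarray       # (F, 2, 2) inverse reference edge matrix
    area_ref: np.ndarray   # (F,)

    @classmethod
    def from_mesh(cls, mesh: TriMesh) -> "ElementBasis":
        t = mesh.triangles
        R = mesh.ref_vertices
        F = t.shape[0]
        invX = np.empty((F, 2, 2))
        area = np.empty(F)
        for k in range(F):
            p0, p1, p2 = R[t[k]]
            e1, e2, D1, D2 = _element_frame(p0, p1, p2)
            X = np.array([[D1 @ e1, D2 @ e1],
                          [D1 @ e2, D2 @ e2]])
            invX[k] = np.linalg.inv(X)
            area[k] = 0.5 * abs(np.linalg.det(X))
        return cls(np.ascontiguousarray(t), invX, area)


@dataclass
class MembraneState:
    """Current kinematic state of one membrane."""

    mesh: TriMesh
    basis: ElementBasis = field(default=None)  # type: ignore[assignment]
    nodal_velocities: np.ndarray = field(default=None)  # type: ignore
    D_ema: np.ndarray = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.basis is None:
            self.basis = ElementBasis.from_mesh(self.mesh)
        if self.nodal_velocities is None:
            self.nodal_velocities = np.zeros_like(self.mesh.vertices)


@njit(cache=True)
def _element_kinematics(verts, vels, tris, invX):
    """Per-element F (2x2), D (2x2), stretches and current area.

    Returns (F2, D2, lam1, lam2, area_cur).  The current element frame has
    e1 along edge 1 and e2 perpendicular in-plane.
    """
    nf = tris.shape[0]
    F2 = np.empty((nf, 2, 2))
    D2 = np.empty((nf, 2, 2))
    lam1 = np.empty(nf)
    lam2 = np.empty(nf)
    area = np.empty(nf)
    for k in range(nf):
        i0, i1, i2 = tris[k, 0], tris[k, 1], tris[k, 2]
        d1x = verts[i1, 0] - verts[i0, 0]
        d1y = verts[i1, 1] - verts[i0, 1]
        d1z = verts[i1, 2] - verts[i0, 2]
        d2x = verts[i2, 0] - verts[i0, 0]
        d2y = verts[i2, 1] - verts[i0, 1]
        d2z = verts[i2, 2] - verts[i0, 2]
        nx = d1y * d2z - d1z * d2y
        ny = d1z * d2x - d1x * d2z
        nz = d1x * d2y - d1y * d2x
        nn = (nx * nx + ny * ny + nz * nz) ** 0.5
        l1 = (d1x * d1x + d1y * d1y + d1z * d1z) ** 0.5
        e1x, e1y, e1z = d1x / l1, d1y / l1, d1z / l1
        ux, uy, uz = nx / nn, ny / nn, nz / nn
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        area[k] = 0.5 * nn
        # current edge matrix in local frame
        a11 = d1x * e1x + d1y * e1y + d1z * e1z
        a12 = d2x * e1x + d2y * e1y + d2z * e1z
        a21 = 0.0
        a22 = d2x * e2x + d2y * e2y + d2z * e2z
        # F = x @ invX
        b = invX[k]
        f11 = a11 * b[0, 0] + a12 * b[1, 0]
        f12 = a11 * b[0, 1] + a12 * b[1, 1]
        f21 = a21 * b[0, 0] + a22 * b[1, 0]
        f22 = a21 * b[0, 1] + a22 * b[1, 1]
        F2[k, 0, 0], F2[k, 0, 1], F2[k, 1, 0], F2[k, 1, 1] = f11, f12, f21, f22
        # principal stretches from C = F^T F
        c11 = f11 * f11 + f21 * f21
        c12 = f11 * f12 + f21 * f22
        c22 = f12 * f12 + f22 * f22
        tr = c11 + c22
        det = c11 * c22 - c12 * c12
        disc = max(0.25 * tr * tr - det, 0.0) ** 0.5
        lam1[k] = max(0.5 * tr + disc, 0.0) ** 0.5
        lam2[k] = max(0.5 * tr - disc, 0.0) ** 0.5
        # in-plane velocity gradient L = [v][x]^-1 then D = sym(L)
        v1x = vels[i1, 0] - vels[i0, 0]
        v1y = vels[i1, 1] - vels[i0, 1]
        v1z = vels[i1, 2] - vels[i0, 2]
        v2x = vels[i2, 0] - vels[i0, 0]
        v2y = vels[i2, 1] - vels[i0, 1]
        v2z = vels[i2, 2] - vels[i0, 2]
        w11 = v1x * e1x + v1y * e1y + v1z * e1z
        w12 = v2x * e1x + v2y * e1y + v2z * e1z
        w21 = v1x * e2x + v1y * e2y + v1z * e2z
        w22 = v2x * e2x + v2y * e2y + v2z * e2z
        deti = a11 * a22 - a12 * a21
        i11, i12 = a22 / deti, -a12 / deti
        i21, i22 = -a21 / deti, a11 / deti
        L11 = w11 * i11 + w12 * i21
        L12 = w11 * i12 + w12 * i22
        L21 = w21 * i11 + w22 * i21
        L22 = w21 * i12 + w22 * i22
        D2[k, 0, 0] = L11
        D2[k, 1, 1] = L22
        D2[k, 0, 1] = 0.5 * (L12 + L21)
        D2[k, 1, 0] = D2[k, 0, 1]
    return F2, D2, lam1, lam2, area


@njit(cache=True)
def _membrane_forces_kernel(verts, vels, tris, invX, area_ref,
                            Gs, C, mu_s, ema_alpha, D_ema, forces):
    """Elastic (SK, exact energy gradient) + viscous nodal forces.

    The elastic first Piola-Kirchhoff tension is
    ``P = Gs (I1 + 1) F + Gs (C I2 - 1) (I2 + 1) F^{-T}``; nodal forces are
    ``f_a = -A_ref * P grad_X(N_a)`` mapped back to 3D through the current
    element frame.  The viscous Cauchy tension ``mu_s (2D - tr(D) I)`` is
    applied on the current configuration using the exponentially
    time-averaged element strain rate ``D_ema`` (per-element components
    Dxx, Dyy, Dxy in the element frame; ``ema_alpha = 1`` reproduces the
    instantaneous strain rate).  Time filtering removes the grid-frequency
    feedback of the stiff explicit surface-viscous coupling while leaving
    the membrane-scale transients (hundreds to thousands of steps)
    untouched.
    Returns (gamma_bar from D_ema, total current area).
    """
    nf = tris.shape[0]
    gnum = 0.0
    atot = 0.0
    for k in range(nf):
        i0, i1, i2 = tris[k, 0], tris[k, 1], tris[k, 2]
        d1x = verts[i1, 0] - verts[i0, 0]
        d1y = verts[i1, 1] - verts[i0, 1]
        d1z = verts[i1, 2] - verts[i0, 2]
        d2x = verts[i2, 0] - verts[i0, 0]
        d2y = verts[i2, 1] - verts[i0, 1]
        d2z = verts[i2, 2] - verts[i0, 2]
        nx = d1y * d2z - d1z * d2y
        ny = d1z * d2x - d1x * d2z
        nz = d1x * d2y - d1y * d2x
        nn = (nx * nx + ny * ny + nz * nz) ** 0.5
        l1 = (d1x * d1x + d1y * d1y + d1z * d1z) ** 0.5
        e1x, e1y, e1z = d1x / l1, d1y / l1, d1z / l1
        ux, uy, uz = nx / nn, ny / nn, nz / nn
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        area_cur = 0.5 * nn
        atot += area_cur
        a11 = d1x * e1x + d1y * e1y + d1z * e1z
        a12 = d2x * e1x + d2y * e1y + d2z * e1z
        a22 = d2x * e2x + d2y * e2y + d2z * e2z
        b = invX[k]
        f11 = a11 * b[0, 0] + a12 * b[1, 0]
        f12 = a11 * b[0, 1] + a12 * b[1, 1]
        f21 = a22 * b[1, 0]
        f22 = a22 * b[1, 1]
        detF = f11 * f22 - f12 * f21
        I1 = f11 * f11 + f12 * f12 + f21 * f21 + f22 * f22 - 2.0
        I2 = detF * detF - 1.0
        # P = c1 * F + c2 * F^{-T}
        c1 = Gs * (I1 + 1.0)
        c2 = Gs * (C * I2 - 1.0) * (I2 + 1.0)
        g11 = c1 * f11 + c2 * f22 / detF
        g12 = c1 * f12 - c2 * f21 / detF
        g21 = c1 * f21 - c2 * f12 / detF
        g22 = c1 * f22 + c2 * f11 / detF
        # shape-function gradients in reference coords:
        # N0 = 1 - xi - eta, N1 = xi, N2 = eta with [xi, eta] = invX @ X_local
        # grad_X N1 = invX row 1 (as column), grad_X N2 = invX row 2
        h1x = b[0, 0]
        h1y = b[0, 1]
        h2x = b[1, 0]
        h2y = b[1, 1]
        ar = area_ref[k]
        # 2D elastic nodal forces f_a = -A_ref * P @ gradN_a
        fe1x = -ar * (g11 * h1x + g12 * h1y)
        fe1y = -ar * (g21 * h1x + g22 * h1y)
        fe2x = -ar * (g11 * h2x + g12 * h2y)
        fe2y = -ar * (g21 * h2x + g22 * h2y)

        # surface strain rate in the element frame (and its time filter)
        v1x = vels[i1, 0] - vels[i0, 0]
        v1y = vels[i1, 1] - vels[i0, 1]
        v1z = vels[i1, 2] - vels[i0, 2]
        v2x = vels[i2, 0] - vels[i0, 0]
        v2y = vels[i2, 1] - vels[i0, 1]
        v2z = vels[i2, 2] - vels[i0, 2]
        w11 = v1x * e1x + v1y * e1y + v1z * e1z
        w12 = v2x * e1x + v2y * e1y + v2z * e1z
        w21 = v1x * e2x + v1y * e2y + v1z * e2z
        w22 = v2x * e2x + v2y * e2y + v2z * e2z
        # inverse of current edge matrix [[a11, a12], [0, a22]]
        i11, i12 = 1.0 / a11, -a12 / (a11 * a22)
        i22 = 1.0 / a22
        L11 = w11 * i11
        L12 = w11 * i12 + w12 * i22
        L21 = w21 * i11
        L22 = w21 * i12 + w22 * i22
        Dxx = (1.0 - ema_alpha) * D_ema[k, 0] + ema_alpha * L11
        Dyy = (1.0 - ema_alpha) * D_ema[k, 1] + ema_alpha * L22
        Dxy = (1.0 - ema_alpha) * D_ema[k, 2] \
            + ema_alpha * 0.5 * (L12 + L21)
        D_ema[k, 0] = Dxx
        D_ema[k, 1] = Dyy
        D_ema[k, 2] = Dxy
        gnum += area_cur * (2.0 * (Dxx * Dxx + Dyy * Dyy
                                   + 2.0 * Dxy * Dxy)) ** 0.5
        if mu_s > 0.0:
            trD = Dxx + Dyy
            # tau_v = mu_s (2D - trD I) on the current configuration
            txx = mu_s * (2.0 * Dxx - trD)
            tyy = mu_s * (2.0 * Dyy - trD)
            txy = mu_s * 2.0 * Dxy
            # current shape-function gradients: rows of inv(x)
            fe1x += -area_cur * (txx * i11 + txy * i12)
            fe1y += -area_cur * (txy * i11 + tyy * i12)
            fe2x += -area_cur * txy * i22
            fe2y += -area_cur * tyy * i22

        # map 2D nodal forces to 3D: f3 = fx * e1 + fy * e2
        forces[i1, 0] += fe1x * e1x + fe1y * e2x
        forces[i1, 1] += fe1x * e1y + fe1y * e2y
        forces[i1, 2] += fe1x * e1z + fe1y * e2z
        forces[i2, 0] += fe2x * e1x + fe2y * e2x
        forces[i2, 1] += fe2x * e1y + fe2y * e2y
        forces[i2, 2] += fe2x * e1z + fe2y * e2z
        forces[i0, 0] -= (fe1x + fe2x) * e1x + (fe1y + fe2y) * e2x
        forces[i0, 1] -= (fe1x + fe2x) * e1y + (fe1y + fe2y) * e2y
        forces[i0, 2] -= (fe1x + fe2x) * e1z + (fe1y + fe2y) * e2z
    return gnum / max(atot, 1e-300), atot


def surface_strain_rate(state: MembraneState, dt: float | None = None):
    """Per-element strain-rate tensors and area-averaged magnitude.

    Uses the current nodal velocities (equivalently, the deformation
    gradient increment over one step divided by ``dt``).  Returns
    ``(D, gamma_bar)`` where ``D`` is (F, 2, 2) in element frames and
    ``gamma_bar = <sqrt(2 tr D^2)>`` area-averaged over the membrane.
    """
    if dt is not None and dt <= 0:
        raise ValueError("dt must be positive")
    b = state.basis
    _, D2, _, _, area = _element_kinematics(
        state.mesh.vertices, state.nodal_velocities, b.tris, b.invX)
    mag = np.sqrt(2.0 * np.einsum("kij,kji->k", D2, D2))
    gamma_bar = float((mag * area).sum() / area.sum())
    return D2, gamma_bar


# ---------------------------------------------------------------------------
# bending

@njit(cache=True)
def _curvature_kernel(verts, tris):
    """Cotangent mean-curvature vectors, Voronoi mixed areas, angle-defect K.

    Returns (Hn, area_v, K, normal) where ``Hn[i]`` is the integrated
    mean-curvature normal, ``area_v`` the mixed (Voronoi, clamped for
    obtuse triangles) vertex area, ``K`` the Gaussian curvature and
    ``normal`` the area-weighted vertex normal.
    """
    nv = verts.shape[0]
    nf = tris.shape[0]
    Hn = np.zeros((nv, 3))
    area_v = np.zeros(nv)
    angsum = np.zeros(nv)
    normal = np.zeros((nv, 3))
    idx = np.empty(3, dtype=np.int64)
    cots = np.empty(3)
    angs = np.empty(3)
    sq = np.empty(3)  # squared edge length opposite to corner c
    for k in range(nf):
        idx[0], idx[1], idx[2] = tris[k, 0], tris[k, 1], tris[k, 2]
        for c in range(3):
            l = idx[c]
            i = idx[(c + 1) % 3]
            j = idx[(c + 2) % 3]
            # angle at corner l between (i - l) and (j - l)
            ux = verts[i, 0] - verts[l, 0]
            uy = verts[i, 1] - verts[l, 1]
            uz = verts[i, 2] - verts[l, 2]
            vx = verts[j, 0] - verts[l, 0]
            vy = verts[j, 1] - verts[l, 1]
            vz = verts[j, 2] - verts[l, 2]
            dot = ux * vx + uy * vy + uz * vz
            cx = uy * vz - uz * vy
            cy = uz * vx - ux * vz
            cz = ux * vy - uy * vx
            cn = (cx * cx + cy * cy + cz * cz) ** 0.5
            cots[c] = dot / cn
            angs[c] = np.arctan2(cn, dot)
            ex = verts[i, 0] - verts[j, 0]
            ey = verts[i, 1] - verts[j, 1]
            ez = verts[i, 2] - verts[j, 2]
            sq[c] = ex * ex + ey * ey + ez * ez
            # cot(angle at l) weights opposite edge (i, j)
            Hn[i, 0] += 0.5 * cots[c] * ex
            Hn[i, 1] += 0.5 * cots[c] * ey
            Hn[i, 2] += 0.5 * cots[c] * ez
            Hn[j, 0] -= 0.5 * cots[c] * ex
            Hn[j, 1] -= 0.5 * cots[c] * ey
            Hn[j, 2] -= 0.5 * cots[c] * ez
            angsum[l] += angs[c]
        ia, ib, ic = idx[0], idx[1], idx[2]
        d1x = verts[ib, 0] - verts[ia, 0]
        d1y = verts[ib, 1] - verts[ia, 1]
        d1z = verts[ib, 2] - verts[ia, 2]
        d2x = verts[ic, 0] - verts[ia, 0]
        d2y = verts[ic, 1] - verts[ia, 1]
        d2z = verts[ic, 2] - verts[ia, 2]
        nx = d1y * d2z - d1z * d2y
        ny = d1z * d2x - d1x * d2z
        nz = d1x * d2y - d1y * d2x
        atri = (nx * nx + ny * ny + nz * nz) ** 0.5 / 2.0
        obtuse = -1
        for c in range(3):
            if angs[c] > np.pi / 2.0:
                obtuse = c
        for c in range(3):
            if obtuse >= 0:
                area_v[idx[c]] += atri / 2.0 if c == obtuse else atri / 4.0
            else:
                # Voronoi area at corner c from its two adjacent edges
                area_v[idx[c]] += (sq[(c + 2) % 3] * cots[(c + 2) % 3]
                                   + sq[(c + 1) % 3] * cots[(c + 1) % 3]) / 8.0
        for c in range(3):
            i = idx[c]
            normal[i, 0] += nx
            normal[i, 1] += ny
            normal[i, 2] += nz
    K = np.empty(nv)
    for i in range(nv):
        K[i] = (2.0 * np.pi - angsum[i]) / area_v[i]
        ln = (normal[i, 0] ** 2 + normal[i, 1] ** 2 + normal[i, 2] ** 2) ** 0.5
        if ln > 0:
            normal[i, 0] /= ln
            normal[i, 1] /= ln
            normal[i, 2] /= ln
    return Hn, area_v, K, normal


@njit(cache=True)
def _cotan_laplacian(verts, tris, f, area_v):
    nv = verts.shape[0]
    nf = tris.shape[0]
    out = np.zeros(nv)
    for k in range(nf):
        ia, ib, ic = tris[k, 0], tris[k, 1], tris[k, 2]
        for c in range(3):
            if c == 0:
                i, j, l = ia, ib, ic
            elif c == 1:
                i, j, l = ib, ic, ia
            else:
                i, j, l = ic, ia, ib
            ux = verts[i, 0] - verts[l, 0]
            uy = verts[i, 1] - verts[l, 1]
            uz = verts[i, 2] - verts[l, 2]
            vx = verts[j, 0] - verts[l, 0]
            vy = verts[j, 1] - verts[l, 1]
            vz = verts[j, 2] - verts[l, 2]
            dot = ux * vx + uy * vy + uz * vz
            cx = uy * vz - uz * vy
            cy = uz * vx - ux * vz
            cz = ux * vy - uy * vx
            cn = (cx * cx + cy * cy + cz * cz) ** 0.5
            cot = dot / cn
            df = f[j] - f[i]
            out[i] += 0.5 * cot * df
            out[j] -= 0.5 * cot * df
    for i in range(nv):
        out[i] /= area_v[i]
    return out


def mean_curvature(mesh: TriMesh):
    """Per-vertex mean curvature H (sphere of radius r gives H = 1/r),
    barycentric vertex areas, Gaussian curvature and outward normals."""
    Hn, area_v, K, normal = _curvature_kernel(mesh.vertices, mesh.triangles)
    # Hn = 2 H n * A_i (integrated mean-curvature normal, outward for sphere)
    H = 0.5 * np.einsum("ij,ij->i", Hn, normal) / area_v
    return H, area_v, K, normal


def bending_energy(mesh: TriMesh, kc: float, c0: float = 0.0) -> float:
    """Discrete Helfrich energy ``(kc/2) sum (2H - c0)^2 A_v``."""
    H, area_v, _, _ = mean_curvature(mesh)
    return float(0.5 * kc * ((2.0 * H - c0) ** 2 * area_v).sum())


def bending_forces(mesh: TriMesh, kc: float, c0: float = 0.0) -> np.ndarray:
    """Nodal Helfrich bending forces.

    Evaluates the variational (shape-equation) force density
    ``f_n = kc [(2H - c0)(2H^2 + c0 H - 2K) + 2 lap_s H]`` on the vertex
    normals with cotangent-Laplacian curvature estimates, then removes the
    (discretisation-level) net force so that momentum is conserved exactly.
    A sphere with ``c0 = 2/r`` is an energy minimum and yields zero force.
    """
    if kc == 0.0:
        return np.zeros_like(mesh.vertices)
    H, area_v, K, normal = mean_curvature(mesh)
    lapH = _cotan_laplacian(mesh.vertices, mesh.triangles, H, area_v)
    fn = kc * ((2.0 * H - c0) * (2.0 * H ** 2 + c0 * H - 2.0 * K)
               + 2.0 * lapH)
    forces = (fn * area_v)[:, None] * normal
    # momentum guard: remove area-weighted mean force density
    forces -= area_v[:, None] * (forces.sum(axis=0) / area_v.sum())
    return forces


# ---------------------------------------------------------------------------
# assembly

def assemble_membrane_forces(state: MembraneState, material: MembraneMaterial,
                             mu_s_current: float = 0.0,
                             ema_alpha: float = 1.0):
    """Total nodal membrane forces (elastic + viscous + bending).

    Parameters
    ----------
    state : MembraneState
    material : MembraneMaterial
    mu_s_current : float
        Instantaneous membrane shear viscosity supplied by the active
        membrane-viscosity model (0 for a hyperelastic membrane).
    ema_alpha : float
        Weight of the exponential time average of the element strain rate
        used by the viscous tension (1 = instantaneous).

    Returns
    -------
    forces : (V, 3) array
    gamma_bar : float
        Area-averaged membrane strain-rate magnitude.
    area : float
        Current total membrane area.
    """
    b = state.basis
    if getattr(state, "D_ema", None) is None or \
            state.D_ema.shape[0] != b.tris.shape[0]:
        state.D_ema = np.zeros((b.tris.shape[0], 3))
    forces = np.zeros_like(state.mesh.vertices)
    gamma_bar, area = _membrane_forces_kernel(
        state.mesh.vertices, state.nodal_velocities, b.tris, b.invX,
        b.area_ref, material.Gs, material.C, mu_s_current,
        ema_alpha, state.D_ema, forces)
    if material.kc > 0.0:
        forces += bending_forces(state.mesh, material.kc, material.c0)
    return forces, float(gamma_bar), float(area)
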