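"""Shape metrics, membrane diagnostics and the small-deformation oracle.

Two deformation measures are used throughout:

* the deformation index ``DI = 1 - 2 sqrt(pi A) / P`` of the cell contour
  in the channel symmetry plane y = 0 (A = contour area, P = perimeter);
  DI = 0 for a circle and grows with non-circularity;
* the Taylor parameter ``D = (L - B) / (L + B)`` of the inertia-equivalent
  ellipse of the contour in the plane of shear, the standard measure for
  capsules in simple shear flow.

The module also carries the first-order (small-deformation) theory for a
spherical capsule with a viscoelastic interface in simple shear, used as
the independent oracle for the shear-box validation runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .surface_mesh import TriMesh, mesh_geometry

__all__ = ["ShapeContour", "TaylorShape", "extract_contour",
           "deformation_index", "taylor_parameter",
           "small_deformation_oracle", "membrane_diagnostics"]


@dataclass
class ShapeContour:
    """Closed planar polygon (slice of the membrane mesh), coordinates um.

    ``points`` is an (n, 2) array of ordered in-plane coordinates; for the
    y = 0 symmetry plane these are (x, z).
    """

    points: np.ndarray
    area: float
    perimeter: float


@dataclass
class TaylorShape:
    """Semi-axes of the inertia-equivalent in-plane ellipse."""

    L: float
    B: float

    @property
    def D(self) -> float:
        return (self.L - self.B) / (self.L + self.B)


def _polygon_area_perimeter(pts: np.ndarray) -> tuple[float, float]:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * np.sum(x * yn - xn * y)
    perim = np.sum(np.hypot(xn - x, yn - y))
    return float(area), float(perim)


def extract_contour(mesh: TriMesh, plane_axis: int = 1,
                    plane_value: float = 0.0) -> ShapeContour:
    """Ordered intersection polygon of the mesh with an axis-aligned plane.

    Default is the channel symmetry plane y = 0.  Raises ``ValueError``
    when the plane misses the mesh.
    """
    normal = np.zeros(3)
    normal[plane_axis] = 1.0
    origin = plane_value * normal
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    sec = tm.section(plane_origin=origin, plane_normal=normal)
    if sec is None or len(sec.discrete) == 0:
        raise ValueError("plane does not intersect the mesh")
    # keep the largest loop (a single closed loop for a capsule slice)
    loops = sorted(sec.discrete, key=len, reverse=True)
    pts3 = loops[0]
    if np.allclose(pts3[0], pts3[-1]):
        pts3 = pts3[:-1]
    keep = [ax for ax in range(3) if ax != plane_axis]
    pts = np.asarray(pts3)[:, keep]
    area, perim = _polygon_area_perimeter(pts)
    if area < 0:
        pts = pts[::-1]
        area = -area
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate contour")
    return ShapeContour(points=pts, area=area, perimeter=perim)


def deformation_index(contour: ShapeContour) -> float:
    """Non-circularity ``DI = 1 - 2 sqrt(pi A) / P`` of a closed contour.

    Zero for a circle; positive for any other simple closed contour by
    the isoperimetric inequality.
    """
    if contour.perimeter <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    return 1.0 - 2.0 * np.sqrt(np.pi * contour.area) / contour.perimeter


def _polygon_second_moments(pts: np.ndarray):
    """Area, centroid and central second moments of a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * cross.sum()
    cx = np.sum((x + xn) * cross) / (6.0 * A)
    cy = np.sum((y + yn) * cross) / (6.0 * A)
    Ixx = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    Iyy = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    Ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    # shift to centroid
    Ixx -= A * cy * cy
    Iyy -= A * cx * cx
    Ixy -= A * cx * cy
    return A, (cx, cy), Ixx, Iyy, Ixy


def taylor_parameter(mesh: TriMesh, plane_axis: int = 1,
                     plane_value: float = 0.0) -> TaylorShape:
    """Taylor parameter from the inertia-equivalent ellipse of the slice.

    The contour's central second moments define an ellipse with identical
    moments; its semi-axes L >= B give ``D = (L - B)/(L + B)``.  Using the
    moment ellipse (rather than a bounding box) makes D insensitive to
    mesh faceting and invariant under in-plane rigid rotation.
    """
    contour = extract_contour(mesh, plane_axis, plane_value)
    A, _, Ixx, Iyy, Ixy = _polygon_second_moments(contour.points)
    cov = np.array([[Iyy, Ixy], [Ixy, Ixx]]) / A
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate contour")
    B, L = 2.0 * np.sqrt(evals)
    return TaylorShape(L=float(L), B=float(B))


# ---------------------------------------------------------------------------
# small-deformation theory (first order in Ca) for a capsule in shear


def small_deformation_oracle(Ca: float, eta_star: float, lam: float = 1.0,
                             C: float = 1.0) -> float:
    """Steady Taylor parameter of a capsule in simple shear, first order.

    First-order perturbation solution for an initially spherical capsule
    with a Kelvin-Voigt interface (linearised SK elasticity with shear
    modulus Gs and area modulus Ks = (1 + 2C) Gs, plus surface shear
    viscosity) suspended in unbounded simple shear at vanishing Reynolds
    number.  ``Ca = mu0 gdot a / Gs``, ``eta_star = mu_s / (mu0 a)``,
    ``lam`` the inner/outer viscosity ratio.

    The steady state is a tank-treading balance: the shear forcing drives
    the l = 2 shape mode while membrane elasticity relaxes it and the
    rotational part of the shear advects it; interface and inner-fluid
    viscosities slow the relaxation, which both lowers the steady
    deformation and tilts the capsule toward the flow direction.  At
    ``Ca -> 0`` the deformation is linear in ``Ca``; the prediction is
    only meaningful while D stays small (flagged above 0.15 by callers).

    Returns the steady ``D`` in the shear plane.
    """
    if Ca < 0 or eta_star < 0 or lam < 0:
        raise ValueError("Ca, eta_star and lam must be non-negative")
    if Ca == 0.0:
        return 0.0
    from ._capsule_theory import steady_taylor_parameter
    return steady_taylor_parameter(Ca=Ca, eta_star=eta_star, lam=lam, C=C)


# ---------------------------------------------------------------------------
# transit diagnostics


def membrane_diagnostics(record) -> dict:
    """Summary diagnostics of a transit record.

    Returns the relative membrane area change (%) at the end of the
    record, the axial station of maximum DI, the peak and final DI, and
    the peak membrane strain rate with its station.
    ``record`` is a ``TransitRecord`` (see ``transit_driver``).
    """
    x = np.asarray(record.x)
    di = np.asarray(record.DI)
    area = np.asarray(record.area)
    gbar = np.asarray(record.gamma_bar)
    i_peak = int(np.argmax(di))
    out = {
        "area_change_pct": 100.0 * (area[-1] / record.area_ref - 1.0),
        "peak_DI": float(di[i_peak]),
        "peak_DI_x": float(x[i_peak]),
        "final_DI": float(di[-1]),
    }
    if gbar.size:
        j = int(np.argmax(gbar))
        out["peak_gamma_bar"] = float(gbar[j])
        out["peak_gamma_bar_x"] = float(x[j])
    return out


def area_change_pct(mesh: TriMesh) -> float:
    """Relative total-area change (%) vs the stress-free reference mesh."""
    cur = mesh_geometry(mesh).total_area
    ref = mesh_geometry(TriMesh(mesh.ref_vertices, mesh.triangles)).total_area
    return 100.0 * (cur / ref - 1.0)
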