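"""Constricted microchannel geometry and background-flow probes.

The device is a converging -- straight -- diverging channel: a wide
reservoir feeds a 45-degree converging taper into a straight segment of
square cross section (width l = 30 um, depth 30 um, length 300 um),
followed by the mirrored diverging taper.  The taper acts on the channel
width (z) only; the depth (y) is constant.  The axial datum x = 0 sits at
the converging-to-straight junction; y = z = 0 on the channel axis.

``build_channel`` rasterises the geometry onto the lattice (node
classification, Bouzidi wall-link fractions from exact wall intersections
of the piecewise-linear walls) and ``background_flow_probe`` extracts the
centreline velocity, the flow-type parameter profile eps(x), the mean
straight-segment speed V and the cross-section-averaged viscosity mu0
from a converged cell-free solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lbm_fluid import D3Q19, FluidLattice
from .rheology_models import flow_type_parameter

__all__ = ["ChannelGeometry", "build_channel", "background_flow_probe",
           "BackgroundFlow"]


@dataclass
class ChannelGeometry:
    """Channel dimensions in micrometres; angles in degrees."""

    l: float = 30.0                 # straight-segment width (z)
    depth: float = 30.0             # constant depth (y)
    straight_length: float = 300.0
    taper_angle_deg: float = 45.0
    reservoir_width: float = 90.0   # wide-section width (z), both ends
    x_min: float = -190.0           # domain start (inlet plane)
    x_max: float = 390.0            # domain end (outlet plane)

    def width(self, x: float) -> float:
        """Channel width in z at axial position x (45-degree tapers)."""
        t = np.tan(np.radians(self.taper_angle_deg))
        if x < 0.0:
            w = self.l + 2.0 * t * (-x)
        elif x <= self.straight_length:
            w = self.l
        else:
            w = self.l + 2.0 * t * (x - self.straight_length)
        return min(w, self.reservoir_width)

    def sdf(self, x: float, y: float, z: float) -> float:
        """Signed distance-like wall function (>= 0 in the wall)."""
        return max(abs(y) - 0.5 * self.depth,
                   abs(z) - 0.5 * self.width(x))

    def contains(self, x: float, y: float, z: float) -> bool:
        return self.sdf(x, y, z) < 0.0


@dataclass
class ChannelLattice:
    """Rasterised channel: lattice + coordinate mapping (um <-> cells)."""

    lattice: FluidLattice
    geometry: ChannelGeometry
    dx: float                     # um per cell
    origin: np.ndarray            # physical coords (um) of node (0,0,0)

    def to_lattice(self, xyz_um):
        return (np.asarray(xyz_um, dtype=float) - self.origin) / self.dx

    def to_physical(self, xyz_lat):
        return np.asarray(xyz_lat, dtype=float) * self.dx + self.origin

    def x_of_index(self, ix):
        return self.origin[0] + np.asarray(ix, dtype=float) * self.dx


def build_channel(geometry: ChannelGeometry, dx: float) -> ChannelLattice:
    """Classify lattice nodes and attach Bouzidi link fractions.

    ``dx`` is the lattice spacing in um; it must resolve the straight
    width with at least 8 cells.  Nodes are cell centres; the first and
    last x-planes are the pressure inlet/outlet.
    """
    if geometry.l / dx < 8.0:
        raise ValueError("grid too coarse: need >= 8 cells across "
                         "the straight width")
    g = geometry
    nx = int(round((g.x_max - g.x_min) / dx))
    ny = int(round(g.depth / dx)) + 2
    nzmax = int(round(g.reservoir_width / dx)) + 2
    # origin: physical position of node index 0 along each axis
    origin = np.array([g.x_min + 0.5 * dx,
                       -(ny / 2.0 - 0.5) * dx,
                       -(nzmax / 2.0 - 0.5) * dx])

    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dx * np.arange(ny)
    zs = origin[2] + dx * np.arange(nzmax)
    wmask = np.zeros((nx, ny, nzmax), dtype=np.int8)
    widths = np.array([g.width(x) for x in xs])
    inside_y = np.abs(ys) < 0.5 * g.depth
    for ix in range(nx):
        inside_z = np.abs(zs) < 0.5 * widths[ix]
        wmask[ix] = np.where(inside_y[:, None] & inside_z[None, :],
                             D3Q19.FLUID, D3Q19.WALL)
    wmask[0][wmask[0] == D3Q19.FLUID] = D3Q19.INLET
    wmask[-1][wmask[-1] == D3Q19.FLUID] = D3Q19.OUTLET

    lat = FluidLattice.create(wmask)

    def sdf_lat(i, j, k):
        return g.sdf(origin[0] + i * dx, origin[1] + j * dx,
                     origin[2] + k * dx)

    lat.find_links(sdf=sdf_lat)
    return ChannelLattice(lattice=lat, geometry=g, dx=dx, origin=origin)


@dataclass
class BackgroundFlow:
    """Cell-free steady-flow diagnostics (physical units unless noted)."""

    x_um: np.ndarray           # axial stations (um)
    u_centerline: np.ndarray   # centreline axial velocity, lattice units
    eps: np.ndarray            # flow-type parameter profile eps(x)
    V_lat: float               # mean speed in the straight segment
    nu0_lat: float             # cross-section average kinematic viscosity
    flux_lat: float            # volumetric flux (lattice units)

    def eps_at(self, x_um: float) -> float:
        return float(np.interp(x_um, self.x_um, self.eps))


def velocity_gradients(u: np.ndarray, points) -> np.ndarray:
    """Velocity-gradient tensors at grid points from central differences.

    ``u`` is the (nx, ny, nz, 3) lattice velocity field; ``points`` an
    (n, 3) integer index array.  Returns (n, 3, 3) with G[a, b] = du_a/dx_b.
    """
    grads = np.empty((3, 3) + u.shape[:3])
    for a in range(3):
        for b in range(3):
            grads[a, b] = np.gradient(u[..., a], axis=b, edge_order=1)
    pts = np.asarray(points, dtype=int)
    return np.transpose(grads[:, :, pts[:, 0], pts[:, 1], pts[:, 2]],
                        (2, 0, 1))


def background_flow_probe(chan: ChannelLattice, a_um: float = 8.5,
                          x_probe_um: float | None = None) -> BackgroundFlow:
    """Diagnostics of the converged cell-free flow currently in ``chan``.

    The flow-type parameter eps(x) is the average over the vertical
    sampling segment -a <= z <= a at y = 0 for every axial station (the
    same convention used by the shear/extension membrane-viscosity
    blend).  ``x_probe_um`` sets the cross-section used for V and mu0
    (default: middle of the straight segment).
    """
    lat = chan.lattice
    g = chan.geometry
    u = lat.u
    nx, ny, nz = lat.shape
    if not np.any(np.abs(u) > 0):
        raise RuntimeError("background flow has not been computed")
    iy0 = int(round((0.0 - chan.origin[1]) / chan.dx))
    iz0 = int(round((0.0 - chan.origin[2]) / chan.dx))
    na = max(1, int(round(a_um / chan.dx)))

    xs = chan.x_of_index(np.arange(nx))
    eps = np.zeros(nx)
    ucl = np.zeros(nx)
    for ix in range(1, nx - 1):
        zr = [iz for iz in range(max(1, iz0 - na), min(nz - 1, iz0 + na + 1))
              if lat.mask[ix, iy0, iz] == D3Q19.FLUID]
        if not zr:
            continue
        pts = [(ix, iy0, iz) for iz in zr]
        G = velocity_gradients(u, pts)
        eps[ix] = flow_type_parameter(G)
        ucl[ix] = u[ix, iy0, iz0, 0]
    eps[0], eps[-1] = eps[1], eps[-2]
    ucl[0], ucl[-1] = ucl[1], ucl[-2]

    if x_probe_um is None:
        x_probe_um = 0.5 * g.straight_length
    ixp = int(round((x_probe_um - chan.origin[0]) / chan.dx))
    ixp = min(max(ixp, 1), nx - 2)
    fluid = lat.mask[ixp] == D3Q19.FLUID
    flux = float(u[ixp, :, :, 0][fluid].sum())          # cells^3 / step
    area = float(fluid.sum())
    V_lat = flux / area
    nu_field = (lat.tau[ixp] - 0.5) / 3.0
    nu0_lat = float(nu_field[fluid].mean())
    return BackgroundFlow(x_um=xs, u_centerline=ucl, eps=eps,
                          V_lat=V_lat, nu0_lat=nu0_lat, flux_lat=flux)
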