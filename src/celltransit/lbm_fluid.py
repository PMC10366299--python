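"""D3Q19 lattice-Boltzmann fluid solver.

Single-relaxation-time (LBGK) collision with Guo second-order forcing,
per-node relaxation time driven by a truncated power-law viscosity,
Bouzidi second-order interpolated bounce-back at (possibly curved) static
walls, half-way bounce-back at moving plane walls (shear box), and the
non-equilibrium extrapolation pressure condition at inlet/outlet planes.

All quantities in this module are in lattice units (dx = dt = rho0 = 1);
the driver performs the physical mapping.  The local shear rate is
recovered locally from the non-equilibrium momentum flux (no finite
differences), which feeds the power-law viscosity and hence the local
relaxation time of the next step.  Distributions are stored node-major,
``f[ix, iy, iz, i]``, which is markedly faster for the collision loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["FluidLattice", "D3Q19", "collide_stream", "equilibrium",
           "macroscopic", "ViscosityLaw", "local_shear_rate"]


class D3Q19:
    """Lattice constants."""

    c = np.array([[0, 0, 0],
                  [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, 1], [0, 0, -1],
                  [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
                  [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
                  [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1]],
                 dtype=np.int64)
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    opp = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9,
                    12, 11, 14, 13, 16, 15, 18, 17], dtype=np.int64)

    FLUID, WALL, INLET, OUTLET = 0, 1, 2, 3


_C = np.ascontiguousarray(D3Q19.c)
_W = np.ascontiguousarray(D3Q19.w)
_OPP = np.ascontiguousarray(D3Q19.opp)


@dataclass
class FluidLattice:
    """Distribution field plus macroscopic state and boundary metadata.

    ``mask`` classifies nodes (0 fluid, 1 wall, 2 inlet, 3 outlet).
    ``links`` holds boundary links as an (n, 5) int array
    (ix, iy, iz, direction, moving-wall id) and ``link_q`` the wall
    intersection fractions in (0, 1].  ``uwall`` maps moving-wall ids to
    velocities (id 0 = static, Bouzidi interpolation; ids > 0 use the
    half-way momentum-corrected bounce-back).
    """

    f: np.ndarray             # (nx, ny, nz, 19) node-major
    mask: np.ndarray          # (nx, ny, nz) int8
    tau: np.ndarray           # (nx, ny, nz)
    force: np.ndarray         # (nx, ny, nz, 3) body-force density
    rho: np.ndarray
    u: np.ndarray             # (nx, ny, nz, 3)
    shear_rate: np.ndarray    # (nx, ny, nz) local gamma-dot
    links: np.ndarray = field(default_factory=lambda: np.zeros((0, 5), np.int64))
    link_q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    uwall: np.ndarray = field(default_factory=lambda: np.zeros((1, 3)))
    periodic: tuple[bool, bool, bool] = (False, False, False)
    rho_in: float = 1.0
    rho_out: float = 1.0

    @classmethod
    def create(cls, mask: np.ndarray, tau0: float = 1.0,
               periodic=(False, False, False)) -> "FluidLattice":
        nx, ny, nz = mask.shape
        rho = np.ones((nx, ny, nz))
        u = np.zeros((nx, ny, nz, 3))
        f = equilibrium(rho, u)
        lat = cls(f=f, mask=np.ascontiguousarray(mask, dtype=np.int8),
                  tau=np.full((nx, ny, nz), tau0),
                  force=np.zeros((nx, ny, nz, 3)), rho=rho, u=u,
                  shear_rate=np.zeros((nx, ny, nz)),
                  periodic=tuple(periodic))
        lat._scratch = np.empty_like(f)
        return lat

    @property
    def shape(self):
        return self.mask.shape

    def total_mass(self) -> float:
        fluid = self.mask == D3Q19.FLUID
        return float(self.f[fluid].sum())

    def find_links(self, sdf=None):
        """Detect fluid->wall links; q from bisection on ``sdf`` when
        given, else half-way (q = 1/2)."""
        self.links, self.link_q = _find_links(self.mask, self.periodic, sdf)
        bad = (self.link_q <= 0) | (self.link_q > 1.0)
        if np.any(bad):
            raise ValueError("wall-intersection fraction outside (0, 1]")

    def checkpoint(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            for name in ("f", "mask", "tau", "force", "rho", "u"):
                h5.create_dataset(name, data=getattr(self, name))

    def restore(self, path: str) -> None:
        import h5py
        with h5py.File(path, "r") as h5:
            for name in ("f", "tau", "force", "rho", "u"):
                getattr(self, name)[...] = h5[name][...]


def _find_links(mask, periodic, sdf=None):
    nx, ny, nz = mask.shape
    links = []
    qs = []
    fluid_idx = np.argwhere(mask != D3Q19.WALL)
    for ix, iy, iz in fluid_idx:
        for i in range(1, 19):
            jx, jy, jz = ix + _C[i, 0], iy + _C[i, 1], iz + _C[i, 2]
            if periodic[0]:
                jx %= nx
            if periodic[1]:
                jy %= ny
            if periodic[2]:
                jz %= nz
            if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
                continue
            if mask[jx, jy, jz] == D3Q19.WALL:
                q = 0.5 if sdf is None else _bisect_q(sdf, (ix, iy, iz), i)
                links.append((ix, iy, iz, i, 0))
                qs.append(q)
    return (np.array(links, dtype=np.int64).reshape(-1, 5),
            np.array(qs, dtype=np.float64))


def _bisect_q(sdf, node, i):
    """Wall-intersection fraction along lattice link ``i`` from ``node``."""
    x0 = np.asarray(node, dtype=float)
    ci = _C[i].astype(float)
    if sdf(*x0) >= 0:
        return 1e-6  # node itself grazes the wall
    a, bq = 0.0, 1.0
    for _ in range(50):
        m = 0.5 * (a + bq)
        if sdf(*(x0 + m * ci)) >= 0:
            bq = m
        else:
            a = m
    return min(max(0.5 * (a + bq), 1e-6), 1.0)


# ---------------------------------------------------------------------------
# kernels

@njit(cache=True)
def _equilibrium_kernel(rho, u, f):
    nx, ny, nz = rho.shape
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                r = rho[ix, iy, iz]
                ux = u[ix, iy, iz, 0]
                uy = u[ix, iy, iz, 1]
                uz = u[ix, iy, iz, 2]
                usq = ux * ux + uy * uy + uz * uz
                for i in range(19):
                    cu = (_C[i, 0] * ux + _C[i, 1] * uy + _C[i, 2] * uz)
                    f[ix, iy, iz, i] = _W[i] * r * (
                        1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


def equilibrium(rho, u):
    f = np.empty(rho.shape + (19,))
    _equilibrium_kernel(rho, np.ascontiguousarray(u), f)
    return f


def macroscopic(lat: FluidLattice):
    """Density and (force-corrected) velocity of the current state."""
    rho = lat.f.sum(axis=-1)
    mom = np.einsum("xyzi,id->xyzd", lat.f, _C.astype(float))
    u = (mom + 0.5 * lat.force) / rho[..., None]
    fluid = lat.mask == D3Q19.FLUID
    u[~fluid] = 0.0
    rho[~fluid] = 1.0
    return rho, u


@njit(cache=True)
def _collide_kernel(f, fpost, mask, tau, force, rho_a, u_a, shear,
                    phi, nu_c, K_pl, alpha, nu_lo, nu_hi, update_visc,
                    need_shear):
    """LBGK collision with Guo forcing; updates macroscopic fields,
    recovers the local shear rate from the non-equilibrium momentum flux
    and (if requested) sets the relaxation time of the next step from the
    truncated-power-law / indicator-blended viscosity."""
    nx, ny, nz = mask.shape
    fl = np.empty(19)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if mask[ix, iy, iz] == 1:   # wall
                    continue
                r = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(19):
                    fi = f[ix, iy, iz, i]
                    fl[i] = fi
                    r += fi
                    mx += fi * _C[i, 0]
                    my += fi * _C[i, 1]
                    mz += fi * _C[i, 2]
                Fx = force[ix, iy, iz, 0]
                Fy = force[ix, iy, iz, 1]
                Fz = force[ix, iy, iz, 2]
                ux = (mx + 0.5 * Fx) / r
                uy = (my + 0.5 * Fy) / r
                uz = (mz + 0.5 * Fz) / r
                rho_a[ix, iy, iz] = r
                u_a[ix, iy, iz, 0] = ux
                u_a[ix, iy, iz, 1] = uy
                u_a[ix, iy, iz, 2] = uz
                t = tau[ix, iy, iz]
                om = 1.0 / t
                gf = 1.0 - 0.5 * om
                usq = ux * ux + uy * uy + uz * uz
                if need_shear:
                    pxx = 0.0
                    pyy = 0.0
                    pzz = 0.0
                    pxy = 0.0
                    pxz = 0.0
                    pyz = 0.0
                    for i in range(19):
                        cx = _C[i, 0]
                        cy = _C[i, 1]
                        cz = _C[i, 2]
                        cu = cx * ux + cy * uy + cz * uz
                        feq = _W[i] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu
                                           - 1.5 * usq)
                        src = _W[i] * (3.0 * ((cx - ux) * Fx + (cy - uy) * Fy
                                              + (cz - uz) * Fz)
                                       + 9.0 * cu * (cx * Fx + cy * Fy
                                                     + cz * Fz))
                        fneq = fl[i] - feq
                        fpost[ix, iy, iz, i] = fl[i] - om * fneq + gf * src
                        pxx += fneq * cx * cx
                        pyy += fneq * cy * cy
                        pzz += fneq * cz * cz
                        pxy += fneq * cx * cy
                        pxz += fneq * cx * cz
                        pyz += fneq * cy * cz
                    # strain rate S = -3/(2 tau rho)[Pi_neq + (u F + F u)/2]
                    cfac = -1.5 / (t * r)
                    sxx = cfac * (pxx + ux * Fx)
                    syy = cfac * (pyy + uy * Fy)
                    szz = cfac * (pzz + uz * Fz)
                    sxy = cfac * (pxy + 0.5 * (ux * Fy + uy * Fx))
                    sxz = cfac * (pxz + 0.5 * (ux * Fz + uz * Fx))
                    syz = cfac * (pyz + 0.5 * (uy * Fz + uz * Fy))
                    gd = (2.0 * (sxx * sxx + syy * syy + szz * szz
                                 + 2.0 * (sxy * sxy + sxz * sxz
                                          + syz * syz))) ** 0.5
                    shear[ix, iy, iz] = gd
                else:
                    gd = shear[ix, iy, iz]
                    for i in range(19):
                        cx = _C[i, 0]
                        cy = _C[i, 1]
                        cz = _C[i, 2]
                        cu = cx * ux + cy * uy + cz * uz
                        feq = _W[i] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu
                                           - 1.5 * usq)
                        src = _W[i] * (3.0 * ((cx - ux) * Fx + (cy - uy) * Fy
                                              + (cz - uz) * Fz)
                                       + 9.0 * cu * (cx * Fx + cy * Fy
                                                     + cz * Fz))
                        fpost[ix, iy, iz, i] = (fl[i] - om * (fl[i] - feq)
                                                + gf * src)
                if update_visc:
                    if alpha == 1.0:
                        nu = K_pl
                    else:
                        nu = K_pl * gd ** (alpha - 1.0) if gd > 0 else nu_hi
                    if nu < nu_lo:
                        nu = nu_lo
                    elif nu > nu_hi:
                        nu = nu_hi
                    p = phi[ix, iy, iz]
                    if p > 0.0:
                        if p > 1.0:
                            p = 1.0
                        nu = (1.0 - p) * nu + p * nu_c
                    tau[ix, iy, iz] = 3.0 * nu + 0.5


@njit(cache=True)
def _stream_kernel(fpost, fnew, mask, px, py, pz):
    nx, ny, nz = mask.shape
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if mask[ix, iy, iz] == 1:
                    continue
                for i in range(19):
                    jx = ix + _C[i, 0]
                    jy = iy + _C[i, 1]
                    jz = iz + _C[i, 2]
                    if jx < 0:
                        if not px:
                            continue
                        jx += nx
                    elif jx >= nx:
                        if not px:
                            continue
                        jx -= nx
                    if jy < 0:
                        if not py:
                            continue
                        jy += ny
                    elif jy >= ny:
                        if not py:
                            continue
                        jy -= ny
                    if jz < 0:
                        if not pz:
                            continue
                        jz += nz
                    elif jz >= nz:
                        if not pz:
                            continue
                        jz -= nz
                    if mask[jx, jy, jz] != 1:
                        fnew[jx, jy, jz, i] = fpost[ix, iy, iz, i]


@njit(cache=True)
def _bounce_back_kernel(fpost, fnew, mask, links, link_q, uwall, rho_a,
                        px, py, pz):
    """Bouzidi linear interpolated bounce-back on all wall links.

    q = 1/2 reduces to half-way bounce-back; moving walls (wall id > 0)
    use the half-way momentum-corrected form and assume q = 1/2 geometry.
    """
    nx, ny, nz = mask.shape
    n = links.shape[0]
    for k in range(n):
        ix, iy, iz, i, wid = (links[k, 0], links[k, 1], links[k, 2],
                              links[k, 3], links[k, 4])
        q = link_q[k]
        io = _OPP[i]
        fi = fpost[ix, iy, iz, i]
        if wid > 0:
            cu = (_C[i, 0] * uwall[wid, 0] + _C[i, 1] * uwall[wid, 1]
                  + _C[i, 2] * uwall[wid, 2])
            fnew[ix, iy, iz, io] = fi - 6.0 * _W[i] * rho_a[ix, iy, iz] * cu
            continue
        if q >= 0.5:
            fnew[ix, iy, iz, io] = (fi / (2.0 * q)
                                    + (2.0 * q - 1.0) / (2.0 * q)
                                    * fpost[ix, iy, iz, io])
        else:
            jx = ix - _C[i, 0]
            jy = iy - _C[i, 1]
            jz = iz - _C[i, 2]
            if px:
                jx = jx % nx
            if py:
                jy = jy % ny
            if pz:
                jz = jz % nz
            ok = (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz)
            if ok and mask[jx, jy, jz] != 1:
                fnew[ix, iy, iz, io] = (2.0 * q * fi
                                        + (1.0 - 2.0 * q)
                                        * fpost[jx, jy, jz, i])
            else:
                fnew[ix, iy, iz, io] = fi


@njit(cache=True)
def _pressure_bc_kernel(f, mask, rho_in, rho_out):
    """Guo non-equilibrium extrapolation at inlet (x=0) / outlet (x=nx-1).

    Boundary-node distributions are rebuilt as the equilibrium at the
    imposed density with the neighbour velocity, plus the neighbour's
    non-equilibrium part."""
    nx, ny, nz = mask.shape
    for iy in range(ny):
        for iz in range(nz):
            for side in range(2):
                ix = 0 if side == 0 else nx - 1
                m = mask[ix, iy, iz]
                if m != 2 and m != 3:
                    continue
                jx = 1 if side == 0 else nx - 2
                if mask[jx, iy, iz] == 1:
                    continue
                rb = rho_in if m == 2 else rho_out
                r = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(19):
                    fi = f[jx, iy, iz, i]
                    r += fi
                    mx += fi * _C[i, 0]
                    my += fi * _C[i, 1]
                    mz += fi * _C[i, 2]
                ux, uy, uz = mx / r, my / r, mz / r
                usq = ux * ux + uy * uy + uz * uz
                for i in range(19):
                    cu = (_C[i, 0] * ux + _C[i, 1] * uy + _C[i, 2] * uz)
                    com = 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
                    f[ix, iy, iz, i] = (_W[i] * rb * com
                                        + (f[jx, iy, iz, i] - _W[i] * r * com))


@dataclass
class ViscosityLaw:
    """Lattice-unit viscosity closure for the collision kernel.

    ``nu(gdot) = K_pl * gdot^(alpha - 1)`` clamped to ``[nu_lo, nu_hi]``
    outside the cell, blended by the indicator ``phi`` toward the
    Newtonian cytoplasm viscosity ``nu_c`` inside.  ``alpha = 1`` makes
    ``K_pl`` the constant kinematic viscosity (clamps inactive).
    """

    K_pl: float
    alpha: float = 1.0
    nu_lo: float = 0.0
    nu_hi: float = 1.0e30
    nu_c: float = 0.0


_ZERO_PHI: dict = {}


def collide_stream(lat: FluidLattice, law: ViscosityLaw | None = None,
                   phi: np.ndarray | None = None,
                   update_visc: bool = False,
                   need_shear: bool | None = None) -> None:
    """One LBGK collision + streaming + boundary step, in place.

    ``need_shear`` controls whether the local shear rate is recomputed
    this step (defaults to ``update_visc``); skipping it when the
    viscosity map is not being refreshed saves a substantial fraction of
    the collision cost."""
    if np.any(lat.tau <= 0.5):
        raise RuntimeError("relaxation time <= 1/2: unstable viscosity map")
    if law is None:
        law = ViscosityLaw(K_pl=(float(lat.tau.flat[0]) - 0.5) / 3.0)
    if phi is None:
        phi = _ZERO_PHI.setdefault(lat.shape, np.zeros(lat.shape))
    fpost = getattr(lat, "_scratch", None)
    if fpost is None or fpost.shape != lat.f.shape:
        fpost = lat._scratch = np.empty_like(lat.f)
    px, py, pz = lat.periodic
    if need_shear is None:
        need_shear = update_visc
    _collide_kernel(lat.f, fpost, lat.mask, lat.tau, lat.force,
                    lat.rho, lat.u, lat.shear_rate, phi, law.nu_c,
                    law.K_pl, law.alpha, law.nu_lo, law.nu_hi, update_visc,
                    need_shear)
    _stream_kernel(fpost, lat.f, lat.mask, px, py, pz)
    if lat.links.shape[0]:
        _bounce_back_kernel(fpost, lat.f, lat.mask, lat.links, lat.link_q,
                            lat.uwall, lat.rho, px, py, pz)
    if lat.mask[0].max() >= 2 or lat.mask[-1].max() >= 2:
        _pressure_bc_kernel(lat.f, lat.mask, lat.rho_in, lat.rho_out)


def local_shear_rate(lat: FluidLattice) -> np.ndarray:
    """Shear-rate field gdot = sqrt(2 tr S^2) recovered by the last
    collision from the non-equilibrium momentum flux (lattice units)."""
    return lat.shear_rate
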