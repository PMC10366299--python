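"""Coupled time integration, flow calibration, configuration and outputs.

The driver binds the pieces together: channel lattice + truncated
power-law LBGK fluid, compound capsule membranes (SK elasticity, surface
viscosity, Helfrich bending), Peskin immersed-boundary transfer and the
front-tracking indicator for the cytoplasm viscosity contrast.

Unit system
-----------
The solver runs in lattice units.  The physical mapping is set by the
grid spacing ``dx`` (um) and by pinning the mean speed of the straight
channel segment to the lattice velocity ``u_target``:  ``dt =
u_target dx / V`` with ``V = Q / (l depth)`` from the target flow rate.
Dimensionless groups (Ca, eta*, lambda, ...) are imposed exactly by
converting membrane properties with the *measured* cell-free
cross-section-average viscosity ``mu0`` and mean speed ``V`` (both in
lattice units), mirroring how the physical device is characterised.

To keep the explicit solver inside its accurate relaxation-time window,
scaled-down presets run at a Reynolds number above the physical ~0.01
(still well below unity, where capsule dynamics is insensitive to
inertia); the fluid consistency is rescaled accordingly.

One coupled step: (1) membrane strain/strain-rate update, (2) membrane
viscosity from the active rheology law, (3) nodal force assembly,
(4) force spreading, (5) LBGK collide-stream with local power-law
relaxation and wall/pressure boundaries, (6) velocity interpolation,
(7) node advection, (8) periodic indicator refresh.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cell_assembly import CellAssembly, build_cell
from .channel_geometry import (BackgroundFlow, ChannelGeometry,
                               ChannelLattice, background_flow_probe,
                               build_channel)
from .ibm_coupling import (IndicatorField, interpolate_velocity,
                           spread_forces)
from .lbm_fluid import D3Q19, FluidLattice, ViscosityLaw, collide_stream
from .membrane_mechanics import (MembraneState, assemble_membrane_forces)
from .rheology_models import MembraneViscosityModel, membrane_viscosity
from .surface_mesh import TriMesh, make_sphere_mesh, mesh_geometry
from .analysis_metrics import deformation_index, extract_contour

log = logging.getLogger("celltransit")

__all__ = ["SimConfig", "TransitRecord", "TransitSimulation",
           "calibrate_flow", "run_transit", "run_shear_box", "load_config",
           "PRESETS"]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class FluidConfig:
    """Physical fluid parameters (SI)."""

    m: float = 0.60               # consistency, Pa s
    alpha: float = 0.64
    gamma_dot0: float = 1.0       # 1/s
    rho: float = 1065.0           # kg/m^3
    gamma_dot_min: float = 1.0    # truncation, 1/s
    gamma_dot_max: float = 1.0e5
    flux_nL_s: float = 8.0        # target flow rate


@dataclass
class CellConfig:
    """Cell parameters; moduli via dimensionless groups."""

    a_um: float = 8.5
    an_ratio: float = 0.5
    Ca: float = 0.75
    C: float = 10.0
    Gsn_factor: float = 2.0
    Cn: float = 10.0
    lam: float = 1.0
    kc_factor: float = 0.001
    release_x_um: float = -190.0
    offset_z_ratio: float = 1.0       # initial offset along -z, units of a
    visc_kind: str = "none"           # none|constant|strain_rate_power|flow_type_blend
    eta_star: float = 0.0             # constant model
    mu1_star: float = 400.0           # Drury-Dembo mu1/(mu0 a)
    gamma0_star: float = 0.0075       # Drury-Dembo gamma0/(V/l)
    n_exp: float = -0.8
    eta_s_shear: float = 20.0         # blend model mu_s^s/(mu0 a)
    eta_s_ext: float = 100.0          # blend model mu_s^e/(mu0 a)


@dataclass
class NumericsConfig:
    dx_um: float = 30.0 / 16.0
    u_target: float = 4.0e-3      # lattice mean speed, straight segment
    Re_target: float = 0.1        # raised from the physical ~0.01
    tau_min: float = 0.55
    tau_max: float = 3.5
    mesh_level: int = 3
    ind_update_every: int = 10
    reinit_every: int = 200
    record_every: int = 50
    max_steps: int = 400_000
    ema_steps: float = 40.0       # strain-rate time-filter (steps)
    bending_every: int = 5        # bending-force refresh cadence


@dataclass
class SimConfig:
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    cell: CellConfig = field(default_factory=CellConfig)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    mode: str = "transit"         # transit | shear_box | poiseuille | calibrate


PRESETS = {
    # desk: full channel at dx = l/16, production membrane level 3
    "desk": SimConfig(
        geometry=ChannelGeometry(x_min=-75.0, x_max=290.0,
                                 reservoir_width=90.0),
        cell=CellConfig(release_x_um=-60.0),
        numerics=NumericsConfig(dx_um=30.0 / 16.0),
    ),
    # mini: truncated domain and coarser grid for desk-scale suites
    "mini": SimConfig(
        geometry=ChannelGeometry(x_min=-62.0, x_max=175.0,
                                 straight_length=300.0,
                                 reservoir_width=60.0),
        cell=CellConfig(release_x_um=-48.0),
        numerics=NumericsConfig(dx_um=30.0 / 12.0, Re_target=0.25,
                                record_every=25),
    ),
    # production scales (cluster-sized; not for desk runs)
    "production": SimConfig(
        geometry=ChannelGeometry(x_min=-220.0, x_max=420.0),
        numerics=NumericsConfig(dx_um=0.0156 * 30.0, mesh_level=5,
                                Re_target=0.01, u_target=1.0e-3),
    ),
}


def load_config(path: str) -> SimConfig:
    """Read a TOML run configuration; unknown keys are rejected."""
    import tomllib
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PRESETS.get(raw.pop("preset", "desk"))
    cfg = replace(cfg)
    out = SimConfig(geometry=replace(cfg.geometry), fluid=replace(cfg.fluid),
                    cell=replace(cfg.cell), numerics=replace(cfg.numerics),
                    mode=raw.pop("mode", cfg.mode))
    for section, obj in (("geometry", out.geometry), ("fluid", out.fluid),
                         ("cell", out.cell), ("numerics", out.numerics)):
        for key, val in raw.pop(section, {}).items():
            if not hasattr(obj, key):
                raise KeyError(f"unknown config key {section}.{key}")
            setattr(obj, key, val)
    if raw:
        raise KeyError(f"unknown config sections: {sorted(raw)}")
    return out


# ---------------------------------------------------------------------------
# records

@dataclass
class TransitRecord:
    """Scalar time series of one transit run (physical units)."""

    t: list = field(default_factory=list)            # s
    x: list = field(default_factory=list)            # centroid x, um
    speed: list = field(default_factory=list)        # um/s
    DI: list = field(default_factory=list)
    area: list = field(default_factory=list)         # um^2
    gamma_bar: list = field(default_factory=list)    # 1/s
    eps: list = field(default_factory=list)
    volume: list = field(default_factory=list)       # um^3
    area_ref: float = 0.0
    volume_ref: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "t": self.t, "x_c": self.x, "speed": self.speed, "DI": self.DI,
            "area": self.area, "gamma_bar": self.gamma_bar, "eps": self.eps,
            "volume": self.volume,
        })

    def save_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        from .analysis_metrics import membrane_diagnostics
        out = membrane_diagnostics(self)
        out["volume_drift_pct"] = 100.0 * (self.volume[-1] / self.volume_ref
                                           - 1.0)
        out.update(self.meta)
        return out


# ---------------------------------------------------------------------------
# flow calibration

def run_to_steady(chan: ChannelLattice, law: ViscosityLaw,
                  check_every: int = 400, rtol: float = 2e-3,
                  max_steps: int = 60_000) -> float:
    """Advance the cell-free flow to a statistically steady flux.

    Returns the steady flux (lattice units) through the straight section.
    """
    lat = chan.lattice
    ix = int(round((0.5 * chan.geometry.straight_length
                    - chan.origin[0]) / chan.dx))
    ix = min(max(ix, 1), lat.shape[0] - 2)
    prev = None
    for step in range(max_steps):
        collide_stream(lat, law, update_visc=True)
        if (step + 1) % check_every == 0:
            umax = float(np.abs(lat.u).max())
            if umax > 0.0577:   # lattice Mach > ~0.1
                raise RuntimeError(
                    f"pressure difference drives Mach > 0.1 "
                    f"(|u|max = {umax:.3g} lattice units)")
            fluid = lat.mask[ix] == D3Q19.FLUID
            flux = float(lat.u[ix, :, :, 0][fluid].sum())
            if prev is not None and abs(flux - prev) <= rtol * abs(flux):
                return flux
            prev = flux
    raise RuntimeError("cell-free flow did not converge")


def _drho_initial_guess(chan: ChannelLattice, law: ViscosityLaw,
                        target_flux: float) -> float:
    """Analytic starting point for the pressure-difference calibration.

    Uses the plane power-law Poiseuille relation for the straight segment
    (mean speed ubar = (G/K)^(1/alpha) h^((alpha+1)/alpha) alpha/(2alpha+1)
    for pressure gradient G) with an empirical duct shape factor, and
    assigns the whole pressure drop to an effective channel length.
    """
    g = chan.geometry
    l_lat = g.l / chan.dx
    area = l_lat * (g.depth / chan.dx)
    ubar = target_flux / area / 0.85        # square-duct shape factor
    h = 0.5 * l_lat
    alpha = law.alpha
    if alpha == 1.0:
        G = 3.0 * law.K_pl * ubar / h ** 2
    else:
        G = law.K_pl * (ubar * (2.0 * alpha + 1.0)
                        / (alpha * h ** (1.0 / alpha + 1.0))) ** alpha
    L_eff = (g.straight_length + 0.35 * (g.x_max - g.x_min
                                         - g.straight_length)) / chan.dx
    L_eff = min(L_eff, (g.x_max - g.x_min) / chan.dx)
    return 3.0 * G * L_eff


def calibrate_flow(chan: ChannelLattice, law: ViscosityLaw,
                   target_flux: float, tol: float = 0.005,
                   max_iter: int = 30) -> float:
    """Tune the inlet/outlet density difference until the steady flux
    matches ``target_flux`` (lattice units) within ``tol``.

    Starts from an analytic power-law estimate, applies log-space secant
    iterations (the flux responds as ``Q ~ dp^(1/alpha)``), and falls
    back to bisection on the bracket the iterations build.  Returns the
    calibrated density difference ``drho`` (lattice pressure difference
    ``dp = drho / 3``); the lattice is left in the converged steady state.
    """
    if target_flux == 0.0:
        chan.lattice.rho_in = chan.lattice.rho_out = 1.0
        return 0.0
    lat = chan.lattice

    def flux_of(drho: float) -> float:
        lat.rho_in = 1.0 + 0.5 * drho
        lat.rho_out = 1.0 - 0.5 * drho
        return run_to_steady(chan, law)

    lo, hi = 0.0, np.inf          # bracket
    d1 = _drho_initial_guess(chan, law, target_flux)
    f1 = flux_of(d1)
    for it in range(max_iter):
        if abs(f1 - target_flux) <= tol * target_flux:
            return d1
        if f1 < target_flux:
            lo = max(lo, d1)
        else:
            hi = min(hi, d1)
        # log-secant step assuming Q ~ dp^(1/alpha_eff)
        d2 = d1 * (target_flux / f1) ** law.alpha
        if not (lo < d2 < hi):
            d2 = 0.5 * (lo + hi) if np.isfinite(hi) else 2.0 * d1
        d1, f1 = d2, flux_of(d2)
    raise RuntimeError("flow calibration did not converge")


# ---------------------------------------------------------------------------
# the coupled simulation

class TransitSimulation:
    """Compound capsule transiting the constricted channel."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        g, fl, nc = config.geometry, config.fluid, config.numerics
        self.chan = build_channel(g, nc.dx_um)
        self.lat = self.chan.lattice

        # physical mapping
        V_phys = (fl.flux_nL_s * 1e-12) / (g.l * 1e-6 * g.depth * 1e-6)
        self.dx_m = nc.dx_um * 1e-6
        self.dt_s = nc.u_target * self.dx_m / V_phys
        self.V_phys = V_phys

        # viscosity rescaling to the target Reynolds number
        mu0_phys_est = 0.0325   # only used for the Re rescale factor
        Re_phys = fl.rho * V_phys * g.l * 1e-6 / mu0_phys_est
        self.visc_scale = max(Re_phys / nc.Re_target, 1e-30) \
            if nc.Re_target > 0 else 1.0
        m_eff = fl.m * self.visc_scale

        # lattice power-law: nu = K gdot^(alpha-1), clamped.
        # nu_lat(gd_lat) = (m/rho) (gd_lat/(dt gd0))^(alpha-1) dt/dx^2
        Kl = (m_eff / fl.rho) * (self.dt_s ** (2.0 - fl.alpha)) \
            * ((1.0 / fl.gamma_dot0) ** (fl.alpha - 1.0)) / self.dx_m ** 2
        nu_of = lambda gd_lat: Kl * gd_lat ** (fl.alpha - 1.0) \
            if fl.alpha != 1.0 else Kl
        g_lo = fl.gamma_dot_min * self.dt_s
        g_hi = fl.gamma_dot_max * self.dt_s
        nu_lo = max(nu_of(g_hi), (nc.tau_min - 0.5) / 3.0)
        nu_hi = min(nu_of(g_lo), (nc.tau_max - 0.5) / 3.0)
        self.law = ViscosityLaw(K_pl=Kl, alpha=fl.alpha, nu_lo=nu_lo,
                                nu_hi=nu_hi)
        self.lat.tau[...] = 3.0 * min(max(nu_of(nc.u_target / 8.0), nu_lo),
                                      nu_hi) + 0.5
        self.background: BackgroundFlow | None = None
        self.cell: CellAssembly | None = None
        self.phi_cell: IndicatorField | None = None
        self.phi_nuc: IndicatorField | None = None
        self.step_count = 0
        self.drho = 0.0
        self._f0 = None

    # -- background / calibration ------------------------------------

    def prepare_background(self, tol: float = 0.005, cache: dict | None = None):
        """Calibrate the pressure difference to the target flow rate and
        tabulate the cell-free diagnostics (V, mu0, eps(x)).

        ``cache`` (as returned by :meth:`background_cache`) restores a
        previously calibrated state for the same geometry/fluid, skipping
        the calibration run.
        """
        nc, g = self.cfg.numerics, self.cfg.geometry
        if cache is not None:
            self.drho = cache["drho"]
            self.lat.rho_in = 1.0 + 0.5 * self.drho
            self.lat.rho_out = 1.0 - 0.5 * self.drho
            self.lat.f[...] = cache["f"]
            self.lat.tau[...] = cache["tau"]
            collide_stream(self.lat, self.law, update_visc=True)
            self.background = cache["background"]
            return self.background
        area_lat = (g.l / nc.dx_um) * (g.depth / nc.dx_um)
        target = nc.u_target * area_lat
        self.drho = calibrate_flow(self.chan, self.law, target, tol=tol)
        self.background = background_flow_probe(
            self.chan, a_um=self.cfg.cell.a_um,
            x_probe_um=min(150.0, 0.5 * g.straight_length))
        log.info("calibrated drho=%.3e V=%.3e mu0=%.3e", self.drho,
                 self.background.V_lat, self.background.nu0_lat)
        return self.background

    def background_cache(self) -> dict:
        return {"drho": self.drho, "f": self.lat.f.copy(),
                "tau": self.lat.tau.copy(), "background": self.background}

    # -- cell setup ----------------------------------------------------

    def insert_cell(self):
        bg = self.background
        if bg is None:
            raise RuntimeError("run prepare_background first")
        cc, nc = self.cfg.cell, self.cfg.numerics
        dx = self.cfg.numerics.dx_um
        mu0 = bg.nu0_lat                  # rho_lat = 1
        a_lat = cc.a_um / dx
        V_lat = bg.V_lat
        l_lat = self.cfg.geometry.l / dx
        Gs = mu0 * V_lat / cc.Ca
        cell = build_cell(
            a=a_lat, an_ratio=cc.an_ratio, level=nc.mesh_level,
            Gs=Gs, C=cc.C, Gsn_factor=cc.Gsn_factor, Cn=cc.Cn, lam=cc.lam,
            kc_factor=cc.kc_factor, release_x=0.0, offset_z=0.0)
        # position in lattice coordinates
        center = self.chan.to_lattice([cc.release_x_um, 0.0,
                                       -cc.offset_z_ratio * cc.a_um])
        for st in (cell.cell, cell.nucleus):
            if st is None:
                continue
            st.mesh.vertices += center
            st.mesh.ref_vertices += center
        cell.center = center
        self.cell = cell

        # membrane-viscosity model in lattice units
        kind = cc.visc_kind
        if kind in ("none", None):
            self.visc_model = None
        elif kind == "constant":
            self.visc_model = MembraneViscosityModel(
                kind="constant", mu_s=cc.eta_star * mu0 * a_lat)
        elif kind == "strain_rate_power":
            self.visc_model = MembraneViscosityModel(
                kind="strain_rate_power", mu1=cc.mu1_star * mu0 * a_lat,
                gamma0=cc.gamma0_star * V_lat / l_lat, n=cc.n_exp)
        elif kind == "flow_type_blend":
            self.visc_model = MembraneViscosityModel(
                kind="flow_type_blend",
                mu_s_shear=cc.eta_s_shear * mu0 * a_lat,
                mu_s_ext=cc.eta_s_ext * mu0 * a_lat)
        else:
            raise ValueError(f"unknown membrane viscosity kind {kind!r}")

        self.phi_cell = IndicatorField(self.lat.shape, self.lat.periodic)
        self.phi_nuc = (IndicatorField(self.lat.shape, self.lat.periodic)
                        if cell.nucleus is not None else None)
        self._refresh_indicator(reinit=True)
        self._gamma_bar = 0.0
        self._mu_s = 0.0
        self._bend_cache = {}
        geo = mesh_geometry(cell.cell.mesh)
        self.area_ref = geo.total_area
        self.volume_ref = geo.volume
        return cell

    def _refresh_indicator(self, reinit: bool = False):
        self.phi_cell.update(self.cell.cell.mesh, reinit=reinit)
        if self.phi_nuc is not None:
            self.phi_nuc.update(self.cell.nucleus.mesh, reinit=reinit)
        lam_nu = self.cfg.cell.lam * self.background.nu0_lat
        self.law.nu_c = lam_nu
        self._phi = np.clip(self.phi_cell.phi, 0.0, 1.0)

    # -- stepping ------------------------------------------------------

    def centroid_x_um(self) -> float:
        cx = self.cell.cell.mesh.vertices[:, 0].mean()
        return float(self.chan.to_physical([cx, 0, 0])[0])

    def step(self):
        """One coupled explicit step (see module docstring for ordering)."""
        cell = self.cell
        nc = self.cfg.numerics
        ema_alpha = 1.0 / max(nc.ema_steps, 1.0)

        # (1-2) membrane viscosity from the active law
        eps_here = 0.0
        if self.visc_model is not None:
            if self.visc_model.kind == "flow_type_blend":
                eps_here = self.background.eps_at(self.centroid_x_um())
            self._mu_s = membrane_viscosity(self.visc_model,
                                            max(self._gamma_bar, 0.0),
                                            eps_here)
        self._eps_here = eps_here

        # (3) force assembly (bending refreshed at a lower cadence)
        refresh_bend = (self.step_count % nc.bending_every) == 0
        self.lat.force[...] = 0.0
        gb_area = 0.0
        gb_num = 0.0
        from .membrane_mechanics import bending_forces
        for tag, st, mat in (("cell", cell.cell, cell.cell_material),
                             ("nuc", cell.nucleus, cell.nucleus_material)):
            if st is None:
                continue
            mu_s = self._mu_s if tag == "cell" else 0.0
            forces, gbar, area = assemble_membrane_forces(
                st, replace(mat, kc=0.0), mu_s_current=mu_s,
                ema_alpha=ema_alpha)
            if mat.kc > 0.0:
                if refresh_bend or tag not in self._bend_cache:
                    self._bend_cache[tag] = bending_forces(st.mesh, mat.kc,
                                                           mat.c0)
                forces += self._bend_cache[tag]
            if tag == "cell":
                gb_num = gbar
                self._area_cur = area
            # (4) spread
            spread_forces(st.mesh.vertices, forces, self.lat.force,
                          self.lat.periodic)
        self._gamma_bar = gb_num

        # (5) fluid step with local power-law relaxation
        update_visc = (self.step_count % nc.ind_update_every) == 0
        collide_stream(self.lat, self.law, phi=self._phi,
                       update_visc=update_visc)

        # (6-7) interpolate and advect.  The weakly compressible LBM
        # fluid dilates as the ambient pressure drops along the channel;
        # an incompressible cytoplasm must not inherit that dilation, so
        # the mean fluid divergence sampled over the cell interior is
        # removed from the advection velocity (a property of the carrier
        # field, not a feedback on the mesh volume).
        if update_visc or not hasattr(self, "_div_cell"):
            self._div_cell = self._mean_divergence()
        ctr = cell.cell.mesh.vertices.mean(axis=0)
        vmax = 0.0
        for st in (cell.cell, cell.nucleus):
            if st is None:
                continue
            vel = interpolate_velocity(self.lat.u, st.mesh.vertices,
                                       self.lat.periodic)
            vel = vel - (self._div_cell / 3.0) * (st.mesh.vertices - ctr)
            st.nodal_velocities = vel
            st.mesh.vertices += vel      # dt = 1 in lattice units
            vmax = max(vmax, float(np.abs(vel).max()))
        if vmax > 0.5:
            raise RuntimeError(
                f"membrane CFL violation at step {self.step_count}: "
                f"max nodal displacement {vmax:.3f} cells/step")

        # (8) indicator refresh
        if (self.step_count + 1) % nc.ind_update_every == 0:
            reinit = (self.step_count + 1) % nc.reinit_every == 0
            self._refresh_indicator(reinit=reinit)
        self.step_count += 1

    def _mean_divergence(self) -> float:
        """Mean fluid velocity divergence over the cell interior."""
        v = self.cell.cell.mesh.vertices
        lo = np.maximum(np.floor(v.min(axis=0)).astype(int) - 2, 1)
        hi = np.minimum(np.ceil(v.max(axis=0)).astype(int) + 3,
                        np.array(self.lat.shape) - 1)
        sub = self.lat.u[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        w = self._phi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        wsum = w.sum()
        if wsum <= 0:
            return 0.0
        div = sum(np.gradient(sub[..., d], axis=d, edge_order=1)
                  for d in range(3))
        return float((div * w).sum() / wsum)

    # -- full run ------------------------------------------------------

    def run_transit(self, x_stop_um: float | None = None,
                    progress: bool = False) -> TransitRecord:
        nc = self.cfg.numerics
        if self.cell is None:
            self.insert_cell()
        g = self.cfg.geometry
        x_safe = g.x_max - 1.6 * self.cfg.cell.a_um - 4.0 * nc.dx_um
        x_stop_um = x_safe if x_stop_um is None else min(x_stop_um, x_safe)
        rec = TransitRecord(area_ref=self.area_ref * nc.dx_um ** 2,
                            volume_ref=self.volume_ref * nc.dx_um ** 3)
        rec.meta = {"Ca": self.cfg.cell.Ca, "C": self.cfg.cell.C,
                    "lam": self.cfg.cell.lam,
                    "visc_kind": self.cfg.cell.visc_kind}
        x_prev = self.centroid_x_um()
        t_prev = 0.0
        while self.step_count < nc.max_steps:
            self.step()
            if self.step_count % nc.record_every == 0:
                x_um = self.centroid_x_um()
                t_s = self.step_count * self.dt_s
                mesh_um = self._mesh_um()
                geo = mesh_geometry(mesh_um)
                try:
                    di = deformation_index(extract_contour(mesh_um))
                except ValueError:
                    di = np.nan
                rec.t.append(t_s)
                rec.x.append(x_um)
                rec.speed.append((x_um - x_prev) / max(t_s - t_prev, 1e-30))
                rec.DI.append(di)
                rec.area.append(geo.total_area)
                rec.volume.append(geo.volume)
                rec.gamma_bar.append(self._gamma_bar / self.dt_s)
                rec.eps.append(self._eps_here)
                x_prev, t_prev = x_um, t_s
                if progress:
                    log.info("step %d x=%.1f um DI=%.3f", self.step_count,
                             x_um, di)
                if x_um >= x_stop_um:
                    break
        return rec

    def _mesh_um(self) -> TriMesh:
        m = self.cell.cell.mesh
        v = self.chan.to_physical(m.vertices)
        r = self.chan.to_physical(m.ref_vertices)
        return TriMesh(v, m.triangles, r)


def run_transit(config: SimConfig, **kw) -> TransitRecord:
    sim = TransitSimulation(config)
    sim.prepare_background()
    sim.insert_cell()
    return sim.run_transit(**kw)


# ---------------------------------------------------------------------------
# shear-box validation mode

def run_shear_box(Ca: float, eta_star: float = 0.0, C: float = 1.0,
                  a: float = 5.0, box=(32, 32, 40), gamma_dot: float = 1e-3,
                  nu: float = 0.25, mesh_level: int = 3,
                  steps: int | None = None, ema_steps: float = 40.0,
                  record_every: int = 200) -> dict:
    """Spherical capsule in simple shear between moving plates.

    Periodic in x and y; plates at the z extremes move at +-U so the
    nominal shear rate is ``gamma_dot = 2U/H``.  The membrane follows the
    SK law with hardness ``C`` plus a constant surface viscosity
    ``eta_star * mu0 * a``.  Returns the Taylor-parameter time series and
    its steady value.
    """
    from .analysis_metrics import taylor_parameter
    nx, ny, nzf = box
    nz = nzf + 2
    mask = np.zeros((nx, ny, nz), np.int8)
    mask[:, :, 0] = D3Q19.WALL
    mask[:, :, -1] = D3Q19.WALL
    lat = FluidLattice.create(mask, tau0=3.0 * nu + 0.5,
                              periodic=(True, True, False))
    lat.find_links()
    H = nzf
    U = 0.5 * gamma_dot * H
    lat.uwall = np.array([[0.0, 0.0, 0.0], [-U, 0.0, 0.0], [U, 0.0, 0.0]])
    zmid = 0.5 * (nz - 1)
    for k in range(lat.links.shape[0]):
        lat.links[k, 4] = 1 if lat.links[k, 2] < zmid else 2
    law = ViscosityLaw(K_pl=nu)

    Gs = nu * gamma_dot * a / Ca
    mu_s = eta_star * nu * a
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, zmid)
    mesh = make_sphere_mesh(a, mesh_level, center)
    state = MembraneState(mesh)
    from .membrane_mechanics import MembraneMaterial
    mat = MembraneMaterial(Gs=Gs, C=C, kc=0.001 * Gs * a * a)

    if steps is None:
        steps = int((6.0 + 1.2 * eta_star * Ca * 10.0) / gamma_dot)
    ema_alpha = 1.0 / max(ema_steps, 1.0)
    ts, Ds = [], []
    for n in range(steps):
        lat.force[...] = 0.0
        forces, gbar, area = assemble_membrane_forces(
            state, mat, mu_s_current=mu_s, ema_alpha=ema_alpha)
        spread_forces(mesh.vertices, forces, lat.force, lat.periodic)
        collide_stream(lat, law)
        vel = interpolate_velocity(lat.u, mesh.vertices, lat.periodic)
        state.nodal_velocities = vel
        mesh.vertices += vel
        if (n + 1) % record_every == 0:
            D = taylor_parameter(mesh, plane_axis=1,
                                 plane_value=center[1]).D
            ts.append((n + 1) * gamma_dot)
            Ds.append(D)
    return {"t_gamma": np.array(ts), "D": np.array(Ds),
            "D_steady": float(np.mean(Ds[-3:])),
            "mesh": mesh, "Ca": Ca, "eta_star": eta_star}
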