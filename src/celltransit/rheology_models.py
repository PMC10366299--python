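"""Suspending-fluid and membrane rheology models.

The channel fluid (PBS + 1% methylcellulose in the target device) is a
truncated power-law liquid:  mu = m (gamma_dot / gamma_dot0)^(alpha - 1),
clamped between the viscosities at configurable truncation shear rates so
the zero-shear singularity of the raw power law never enters the solver.

Three membrane-viscosity laws are supported:

* ``constant`` -- Newtonian surface viscosity ``mu_s``;
* ``strain_rate_power`` -- the Drury-Dembo empirical law
  ``mu_s = mu1 (1 + gbar_m / gamma0)^n`` driven by the area-averaged
  membrane strain rate (a global membrane property);
* ``flow_type_blend`` -- a shear/extension blend
  ``mu_s = (1 - eps) mu_s_shear + eps mu_s_ext`` weighted by the
  flow-type parameter ``eps`` of the cell-free background flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PowerLawFluid", "fluid_viscosity", "MembraneViscosityModel",
           "membrane_viscosity", "flow_type_parameter"]


@dataclass
class PowerLawFluid:
    """Truncated power-law suspending fluid.

    Parameters are in SI units: consistency ``m`` (Pa s), flow index
    ``alpha`` (0 < alpha <= 1 for this application), reference shear rate
    ``gamma_dot0`` (1/s), density ``rho`` (kg/m^3), and truncation shear
    rates ``gamma_dot_min``/``gamma_dot_max`` (1/s) bracketing the
    device's working range.  ``alpha = 1`` recovers a Newtonian fluid with
    viscosity ``m``.
    """

    m: float = 0.60
    alpha: float = 0.64
    gamma_dot0: float = 1.0
    rho: float = 1065.0
    gamma_dot_min: float = 1.0
    gamma_dot_max: float = 1.0e5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("flow index alpha must be in (0, 1]")
        if self.m <= 0 or self.gamma_dot0 <= 0 or self.rho <= 0:
            raise ValueError("m, gamma_dot0 and rho must be positive")
        if not (0 < self.gamma_dot_min < self.gamma_dot_max):
            raise ValueError("need 0 < gamma_dot_min < gamma_dot_max")

    @property
    def mu_max(self) -> float:
        return fluid_viscosity(self.gamma_dot_min, self, clamp=False)

    @property
    def mu_min(self) -> float:
        return fluid_viscosity(self.gamma_dot_max, self, clamp=False)


def fluid_viscosity(gamma_dot, fluid: PowerLawFluid, clamp: bool = True):
    """Truncated power-law viscosity ``m (gdot/gdot0)^(alpha-1)`` in Pa s.

    Accepts scalars or arrays; with ``clamp`` the shear rate is clipped to
    the fluid's truncation bounds (so ``gamma_dot = 0`` returns the
    low-shear plateau viscosity).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    if clamp:
        g = np.clip(g, fluid.gamma_dot_min, fluid.gamma_dot_max)
    mu = fluid.m * (g / fluid.gamma_dot0) ** (fluid.alpha - 1.0)
    return float(mu) if np.isscalar(gamma_dot) else mu


@dataclass
class MembraneViscosityModel:
    """Descriptor of the membrane surface-viscosity law.

    ``kind`` selects the law; the relevant parameters are (all surface
    viscosities in N s/m):

    * ``constant``: ``mu_s``
    * ``strain_rate_power``: ``mu1`` (zero-strain-rate viscosity),
      ``gamma0`` (characteristic strain rate, 1/s), exponent ``n``
    * ``flow_type_blend``: ``mu_s_shear``, ``mu_s_ext``
    """

    kind: str = "constant"
    mu_s: float = 0.0
    mu1: float = 0.0
    gamma0: float = 1.0
    n: float = 0.0
    mu_s_shear: float = 0.0
    mu_s_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "strain_rate_power",
                             "flow_type_blend"):
            raise ValueError(f"unknown membrane viscosity model {self.kind!r}")
        if min(self.mu_s, self.mu1, self.mu_s_shear, self.mu_s_ext) < 0:
            raise ValueError("membrane viscosities must be non-negative")
        if self.kind == "strain_rate_power" and self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")


def membrane_viscosity(model: MembraneViscosityModel, gamma_bar_m: float = 0.0,
                       eps: float = 0.0) -> float:
    """Instantaneous membrane shear viscosity from the active law.

    Parameters
    ----------
    gamma_bar_m : float
        Area-averaged membrane strain rate (1/s); drives the
        Drury-Dembo law.
    eps : float
        Flow-type parameter of the background flow; drives the
        shear/extension blend.  Values below 0 (rotation-dominated) clamp
        to 0 and above 1 clamp to 1, so the blend weight stays in [0, 1].
    """
    if gamma_bar_m < 0:
        raise ValueError("gamma_bar_m must be non-negative")
    if model.kind == "constant":
        return model.mu_s
    if model.kind == "strain_rate_power":
        return model.mu1 * (1.0 + gamma_bar_m / model.gamma0) ** model.n
    w = min(max(eps, 0.0), 1.0)
    return (1.0 - w) * model.mu_s_shear + w * model.mu_s_ext


def flow_type_parameter(velocity_gradients) -> float:
    """Flow-type parameter ``eps = (|gd| - |w|) / (|gd| + |w|)``.

    ``gd = grad(u) + grad(u)^T`` and ``w = grad(u) - grad(u)^T`` with
    Frobenius magnitudes, averaged over the supplied sample of velocity
    gradient tensors (shape ``(n, 3, 3)`` or a single ``(3, 3)``).
    Simple shear gives 0, pure extension +1, rigid rotation -1; a
    quiescent sample contributes 0.
    """
    G = np.asarray(velocity_gradients, dtype=float)
    if G.ndim == 2:
        G = G[None]
    if G.size == 0:
        raise ValueError("empty velocity-gradient sample")
    gd = G + np.swapaxes(G, 1, 2)
    w = G - np.swapaxes(G, 1, 2)
    ngd = np.sqrt(np.einsum("kij,kij->k", gd, gd))
    nw = np.sqrt(np.einsum("kij,kij->k", w, w))
    tot = ngd + nw
    eps = np.where(tot > 0, (ngd - nw) / np.where(tot > 0, tot, 1.0), 0.0)
    return float(eps.mean())
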