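"""First-order small-deformation theory for a capsule in simple shear.

Steady solution for an initially spherical capsule with a Kelvin-Voigt
interface (linearised SK elasticity with shear modulus ``Gs`` and area
modulus ``Ks = kappa Gs``, ``kappa = 1 + 2C``; surface shear viscosity
``mu_s``; zero dilatational surface viscosity) suspended in unbounded
simple shear at zero Reynolds number, to first order in the capillary
number ``Ca = mu0 gdot a / Gs``.

Derivation sketch (the full calculation is classical perturbation theory
on l = 2 spherical modes):

* A steady membrane requires the leading-order interface velocity to be a
  surface isometry, i.e. rigid rotation at half the shear rate; the O(1)
  outer flow is therefore the rigid-sphere-in-shear Stokes solution and
  the inner fluid rotates rigidly (the inner viscosity ratio drops out at
  this order).
* The leading traction jump balances the membrane tension divergence and
  determines the scaled strain field; the membrane viscous tension enters
  through the Boussinesq-type product ``beta = eta* Ca``.
* Steadiness of the strain field under co-rotational transport by the
  tank-treading rotation closes the shape amplitudes.

The resulting in-plane shape amplitudes (shape tensor components along
the straining direction and its 45-degree rotation) are::

    j_parallel = 5/(4 kappa) + (15/4) / (1 + beta^2)
    j_cross    = (15/4) beta / (1 + beta^2)

and the steady Taylor parameter is ``D = (Ca/2) sqrt(j_par^2 + j_x^2)``.
Limits: ``beta = 0`` gives ``D = Ca (15/8 + 5/(8 kappa))`` -- for
``kappa = 3`` (small-strain equivalent of a neo-Hookean membrane) this is
the classical ``25/12 Ca``.  Large membrane viscosity suppresses the
deviatoric response and tilts the capsule toward the flow direction.
Validity: first order in Ca, inner viscosity ratio of order unity.
"""

from __future__ import annotations

import math

__all__ = ["steady_taylor_parameter", "steady_orientation_deg"]


def _shape_amplitudes(Ca: float, eta_star: float, C: float):
    kappa = 1.0 + 2.0 * C
    beta = eta_star * Ca
    denom = 1.0 + beta * beta
    j_par = 5.0 / (4.0 * kappa) + 3.75 / denom
    j_cross = 3.75 * beta / denom
    return j_par, j_cross


def steady_taylor_parameter(Ca: float, eta_star: float = 0.0,
                            lam: float = 1.0, C: float = 1.0) -> float:
    """Steady Taylor parameter ``D`` at first order in ``Ca``.

    ``lam`` is accepted for interface compatibility; an order-one inner
    viscosity ratio does not enter at first order (it modifies transients
    and O(Ca^2) corrections only).
    """
    j_par, j_cross = _shape_amplitudes(Ca, eta_star, C)
    return 0.5 * Ca * math.hypot(j_par, j_cross)


def steady_orientation_deg(Ca: float, eta_star: float = 0.0,
                           C: float = 1.0) -> float:
    """Steady inclination of the long axis from the flow direction (deg).

    45 degrees for a purely elastic membrane, decreasing toward the flow
    direction as the membrane viscosity grows.
    """
    j_par, j_cross = _shape_amplitudes(Ca, eta_star, C)
    return 45.0 - 0.5 * math.degrees(math.atan2(j_cross, j_par))
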