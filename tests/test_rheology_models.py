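import math

import numpy as np
import pytest

from celltransit.rheology_models import (MembraneViscosityModel,
                                         PowerLawFluid, fluid_viscosity,
                                         flow_type_parameter,
                                         membrane_viscosity)


class TestPowerLawFluid:
    def test_reference_viscosity(self):
        # methylcellulose buffer: m = 0.60 Pa s, alpha = 0.64
        fl = PowerLawFluid()
        assert fluid_viscosity(1.0, fl) == pytest.approx(0.60)

    def test_derived_value_at_e(self):
        fl = PowerLawFluid()
        assert fluid_viscosity(math.e, fl) == pytest.approx(
            0.60 * math.exp(-0.36), rel=1e-12)

    def test_zero_shear_clamps_to_low_shear_plateau(self):
        fl = PowerLawFluid()
        assert fluid_viscosity(0.0, fl) == fluid_viscosity(
            fl.gamma_dot_min, fl)

    def test_monotone_nonincreasing_for_shear_thinning(self):
        fl = PowerLawFluid()
        g = np.logspace(-2, 7, 40)
        mu = fluid_viscosity(g, fl)
        assert np.all(np.diff(mu) <= 1e-15)
        # clamped at both ends
        assert mu[0] == pytest.approx(fl.mu_max)
        assert mu[-1] == pytest.approx(fl.mu_min)

    def test_newtonian_limit(self):
        fl = PowerLawFluid(alpha=1.0, m=0.032)
        g = np.logspace(-1, 4, 10)
        assert np.allclose(fluid_viscosity(g, fl), 0.032)

    def test_validation(self):
        with pytest.raises(ValueError):
            PowerLawFluid(alpha=1.2)
        with pytest.raises(ValueError):
            PowerLawFluid(gamma_dot_min=10.0, gamma_dot_max=1.0)
        with pytest.raises(ValueError):
            fluid_viscosity(-1.0, PowerLawFluid())


class TestFlowTypeParameter:
    def test_canonical_flows(self):
        shear = np.zeros((3, 3))
        shear[0, 2] = 1.0                      # u = (gdot z, 0, 0)
        assert flow_type_parameter(shear) == pytest.approx(0.0)
        ext = np.diag([1.0, 0.0, -1.0])        # planar extension
        assert flow_type_parameter(ext) == pytest.approx(1.0)
        rot = np.zeros((3, 3))
        rot[0, 2], rot[2, 0] = 1.0, -1.0       # rigid rotation
        assert flow_type_parameter(rot) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_frame_rotation_and_scaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((5, 3, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        eps0 = flow_type_parameter(G)
        assert flow_type_parameter(Q @ G @ Q.T) == pytest.approx(eps0)
        assert flow_type_parameter(7.3 * G) == pytest.approx(eps0)

    def test_quiescent_sample_gives_zero(self):
        assert flow_type_parameter(np.zeros((4, 3, 3))) == 0.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            flow_type_parameter(np.zeros((0, 3, 3)))


class TestMembraneViscosity:
    def test_constant(self):
        model = MembraneViscosityModel(kind="constant", mu_s=3.3)
        assert membrane_viscosity(model, 17.0, 0.4) == 3.3

    def test_blend_endpoints_and_midpoint(self):
        model = MembraneViscosityModel(kind="flow_type_blend",
                                       mu_s_shear=20.0, mu_s_ext=100.0)
        assert membrane_viscosity(model, eps=0.0) == 20.0
        assert membrane_viscosity(model, eps=1.0) == 100.0
        assert membrane_viscosity(model, eps=0.5) == 60.0

    def test_blend_weight_is_clamped(self):
        model = MembraneViscosityModel(kind="flow_type_blend",
                                       mu_s_shear=20.0, mu_s_ext=100.0)
        assert membrane_viscosity(model, eps=-0.7) == 20.0
        assert membrane_viscosity(model, eps=1.9) == 100.0

    def test_strain_rate_power_value(self):
        # shear-thinning parameter set in device units (V/l)
        model = MembraneViscosityModel(kind="strain_rate_power", mu1=400.0,
                                       gamma0=0.0075, n=-0.8)
        assert membrane_viscosity(model, gamma_bar_m=0.0075) \
            == pytest.approx(400.0 * 2.0 ** -0.8, rel=1e-12)

    def test_zero_exponent_returns_mu1(self):
        model = MembraneViscosityModel(kind="strain_rate_power", mu1=11.0,
                                       gamma0=1.0, n=0.0)
        for g in (0.0, 0.5, 40.0):
            assert membrane_viscosity(model, gamma_bar_m=g) == 11.0

    def test_validation(self):
        with pytest.raises(ValueError):
            MembraneViscosityModel(kind="bogus")
        with pytest.raises(ValueError):
            MembraneViscosityModel(kind="constant", mu_s=-1.0)
        model = MembraneViscosityModel(kind="constant", mu_s=1.0)
        with pytest.raises(ValueError):
            membrane_viscosity(model, gamma_bar_m=-0.1)
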