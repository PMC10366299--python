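import numpy as np
import pytest

from celltransit.lbm_fluid import (D3Q19, FluidLattice, ViscosityLaw,
                                   collide_stream, equilibrium, macroscopic)


def periodic_box(n=8, tau=0.8):
    mask = np.zeros((n, n, n), np.int8)
    return FluidLattice.create(mask, tau0=tau, periodic=(True, True, True))


def plate_channel(H, tau=0.9):
    mask = np.zeros((4, 4, H + 2), np.int8)
    mask[:, :, 0] = D3Q19.WALL
    mask[:, :, -1] = D3Q19.WALL
    lat = FluidLattice.create(mask, tau0=tau, periodic=(True, True, False))
    lat.find_links()
    return lat, mask


class TestCollideStream:
    def test_rest_equilibrium_is_invariant(self):
        lat = periodic_box()
        f0 = lat.f.copy()
        for _ in range(20):
            collide_stream(lat)
        assert np.abs(lat.f - f0).max() < 1e-14

    def test_mass_conservation_periodic(self):
        lat = periodic_box()
        rng = np.random.default_rng(0)
        rho = 1.0 + 0.01 * rng.standard_normal(lat.shape)
        lat.f[...] = equilibrium(rho, np.zeros(lat.shape + (3,)))
        m0 = lat.total_mass()
        for _ in range(50):
            collide_stream(lat)
        assert lat.total_mass() == pytest.approx(m0, rel=1e-13)

    def test_mass_conservation_closed_box(self):
        # half-way bounce-back walls conserve mass exactly
        n = 10
        mask = np.zeros((n, n, n), np.int8)
        mask[0] = mask[-1] = D3Q19.WALL
        mask[:, 0] = mask[:, -1] = D3Q19.WALL
        mask[:, :, 0] = mask[:, :, -1] = D3Q19.WALL
        lat = FluidLattice.create(mask, tau0=0.8)
        lat.find_links()
        rng = np.random.default_rng(1)
        rho = 1.0 + 0.02 * rng.standard_normal(lat.shape)
        u = 0.005 * rng.standard_normal(lat.shape + (3,))
        lat.f[...] = equilibrium(rho, u)
        m0 = lat.total_mass()
        for _ in range(60):
            collide_stream(lat)
        assert lat.total_mass() == pytest.approx(m0, rel=1e-12)

    def test_galilean_uniform_advection(self):
        lat = periodic_box()
        u0 = np.zeros(lat.shape + (3,))
        u0[..., 0] = 0.02
        lat.f[...] = equilibrium(np.ones(lat.shape), u0)
        for _ in range(40):
            collide_stream(lat)
        _, u = macroscopic(lat)
        assert np.allclose(u[..., 0], 0.02, atol=1e-12)

    def test_unstable_relaxation_time_raises(self):
        lat = periodic_box(tau=0.8)
        lat.tau[...] = 0.4
        with pytest.raises(RuntimeError):
            collide_stream(lat)


class TestPoiseuille:
    def test_newtonian_profile(self):
        H = 24
        lat, mask = plate_channel(H)
        nu = (0.9 - 0.5) / 3.0
        g = 1e-6
        lat.force[..., 0][mask == D3Q19.FLUID] = g
        for _ in range(8000):
            collide_stream(lat)
        _, u = macroscopic(lat)
        z = np.arange(1, H + 1) - 0.5 - H / 2
        ua = g / (2 * nu) * ((H / 2) ** 2 - z ** 2)
        assert np.abs(u[2, 2, 1:-1, 0] - ua).max() / ua.max() < 0.01


class TestShearRateRecovery:
    def test_couette_shear_rate(self):
        H = 24
        lat, mask = plate_channel(H, tau=0.8)
        U = 0.02
        lat.uwall = np.array([[0, 0, 0], [-U, 0, 0], [U, 0, 0]], float)
        zmid = 0.5 * (H + 1)
        for k in range(lat.links.shape[0]):
            lat.links[k, 4] = 1 if lat.links[k, 2] < zmid else 2
        for _ in range(6000):
            collide_stream(lat, need_shear=True)
        gdot = 2 * U / H
        _, u = macroscopic(lat)
        z = np.arange(1, H + 1) - 0.5 - H / 2
        assert np.abs(u[2, 2, 1:-1, 0] - gdot * z).max() < 1e-8
        assert lat.shear_rate[2, 2, H // 2] == pytest.approx(gdot, rel=0.02)

    def test_uniform_flow_has_zero_shear(self):
        lat = periodic_box()
        u0 = np.zeros(lat.shape + (3,))
        u0[..., 1] = 0.01
        lat.f[...] = equilibrium(np.ones(lat.shape), u0)
        collide_stream(lat, need_shear=True)
        assert np.abs(lat.shear_rate).max() < 1e-12


class TestPowerLawMachinery:
    def test_alpha_one_reproduces_newtonian_exactly(self):
        lat1 = periodic_box(tau=0.9)
        lat2 = periodic_box(tau=0.9)
        rng = np.random.default_rng(2)
        rho = 1.0 + 0.01 * rng.standard_normal(lat1.shape)
        u = 0.01 * rng.standard_normal(lat1.shape + (3,))
        lat1.f[...] = equilibrium(rho, u)
        lat2.f[...] = lat1.f
        nu = (0.9 - 0.5) / 3.0
        newt = ViscosityLaw(K_pl=nu)
        plaw = ViscosityLaw(K_pl=nu, alpha=1.0, nu_lo=1e-6, nu_hi=10.0)
        for _ in range(25):
            collide_stream(lat1, newt)
            collide_stream(lat2, plaw, update_visc=True)
        assert np.array_equal(lat1.f, lat2.f)

    def test_power_law_relaxation_time_update(self):
        H = 16
        lat, mask = plate_channel(H, tau=1.0)
        law = ViscosityLaw(K_pl=0.01, alpha=0.64, nu_lo=0.05, nu_hi=0.8)
        g = 2e-6
        lat.force[..., 0][mask == D3Q19.FLUID] = g
        for _ in range(3000):
            collide_stream(lat, law, update_visc=True)
        tau = lat.tau[2, 2, 1:-1]
        # shear-thinning: higher viscosity (tau) at the centre than walls
        assert tau[H // 2] > tau[1]
        assert tau.min() >= 3 * law.nu_lo + 0.5 - 1e-12
        assert tau.max() <= 3 * law.nu_hi + 0.5 + 1e-12


class TestBounceBackGeometry:
    def test_q_fractions_in_unit_interval(self):
        lat, _ = plate_channel(8)
        assert lat.links.shape[0] > 0
        assert np.all(lat.link_q > 0) and np.all(lat.link_q <= 1.0)
        # plane walls between nodes: exactly half-way links
        assert np.allclose(lat.link_q, 0.5)

    def test_wall_position_second_order(self):
        # slip velocity at the wall decays ~dx^2 under refinement
        errs = []
        for H in (8, 16, 32):
            lat, mask = plate_channel(H)
            nu = (0.9 - 0.5) / 3.0
            g = 1e-6 * (16.0 / H) ** 2   # keep u_max comparable
            lat.force[..., 0][mask == D3Q19.FLUID] = g
            for _ in range(80 * H * H):
                collide_stream(lat)
            _, u = macroscopic(lat)
            z = np.arange(1, H + 1) - 0.5 - H / 2
            ua = g / (2 * nu) * ((H / 2) ** 2 - z ** 2)
            errs.append(np.abs(u[2, 2, 1:-1, 0] - ua).max() / ua.max())
        assert errs[2] < errs[0]
        # convergence order ~2 (allow 1.5 given the tiny wall error)
        order = np.log(errs[0] / errs[2]) / np.log(4.0)
        assert order > 1.5


class TestPressureBoundary:
    def _duct(self, drho):
        nx, n = 30, 10
        mask = np.zeros((nx, n, n), np.int8)
        mask[:, 0] = mask[:, -1] = D3Q19.WALL
        mask[:, :, 0] = mask[:, :, -1] = D3Q19.WALL
        mask[0][mask[0] == 0] = D3Q19.INLET
        mask[-1][mask[-1] == 0] = D3Q19.OUTLET
        lat = FluidLattice.create(mask, tau0=0.8)
        lat.find_links()
        lat.rho_in = 1.0 + drho / 2
        lat.rho_out = 1.0 - drho / 2
        for _ in range(4000):
            collide_stream(lat)
        fluid = lat.mask[nx // 2] == D3Q19.FLUID
        return float(lat.u[nx // 2, :, :, 0][fluid].sum())

    def test_zero_pressure_difference_gives_no_flux(self):
        assert abs(self._duct(0.0)) < 1e-12

    def test_stokes_linearity(self):
        q1 = self._duct(2e-3)
        q2 = self._duct(4e-3)
        assert q2 / q1 == pytest.approx(2.0, rel=0.01)


def test_checkpoint_roundtrip(tmp_path):
    lat = periodic_box()
    rng = np.random.default_rng(3)
    lat.f[...] = equilibrium(1 + 0.01 * rng.standard_normal(lat.shape),
                             0.01 * rng.standard_normal(lat.shape + (3,)))
    collide_stream(lat)
    path = str(tmp_path / "state.h5")
    lat.checkpoint(path)
    lat2 = periodic_box()
    lat2.restore(path)
    assert np.array_equal(lat.f, lat2.f)
    collide_stream(lat)
    collide_stream(lat2)
    assert np.array_equal(lat.f, lat2.f)
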