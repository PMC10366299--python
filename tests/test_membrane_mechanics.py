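import math

import numpy as np
import pytest

from celltransit.membrane_mechanics import (MembraneMaterial, MembraneState,
                                            assemble_membrane_forces,
                                            bending_energy, bending_forces,
                                            element_strain, mean_curvature,
                                            membrane_viscous_tension,
                                            sk_energy, sk_tensions,
                                            surface_strain_rate)
from celltransit.membrane_mechanics import _element_kinematics
from celltransit.surface_mesh import make_sphere_mesh

REF_TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.2, 0.9, 0.0]])


class TestElementStrain:
    def test_identity(self):
        l1, l2, *_ = element_strain(REF_TRI, REF_TRI)
        assert l1 == pytest.approx(1.0) and l2 == pytest.approx(1.0)

    def test_uniform_scaling(self):
        l1, l2, *_ = element_strain(REF_TRI, 1.1 * REF_TRI)
        assert l1 == pytest.approx(1.1) and l2 == pytest.approx(1.1)

    def test_uniaxial_stretch(self):
        cur = REF_TRI.copy()
        cur[:, 0] *= 2.0
        l1, l2, e1, e2, F = element_strain(REF_TRI, cur)
        assert l1 == pytest.approx(2.0) and l2 == pytest.approx(1.0)
        assert abs(e1 @ np.array([1.0, 0, 0])) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        cur = REF_TRI.copy()
        cur[:, 0] *= 1.37
        moved = cur @ Q.T + rng.standard_normal(3)
        l1a, l2a, *_ = element_strain(REF_TRI, cur)
        l1b, l2b, *_ = element_strain(REF_TRI, moved)
        assert l1b == pytest.approx(l1a, rel=1e-10)
        assert l2b == pytest.approx(l2a, rel=1e-10)

    def test_degenerate_raises(self):
        bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            element_strain(REF_TRI, bad)


class TestSkTensions:
    def test_unstretched_is_tension_free(self):
        assert sk_tensions(1.0, 1.0, 3.7, 12.0) == (0.0, 0.0)

    def test_equibiaxial_value(self):
        # independent symbolic substitution into the SK principal tensions
        t1, t2 = sk_tensions(1.1, 1.1, 1.0, 1.0)
        assert t1 == pytest.approx(0.771561, abs=1e-12)
        assert t2 == pytest.approx(0.771561, abs=1e-12)

    def test_uniaxial_value_hard_membrane(self):
        t1, t2 = sk_tensions(1.2, 1.0, 1.0, 10.0)
        assert t1 == pytest.approx(5.808, abs=1e-12)
        assert t2 == pytest.approx(5.28, abs=1e-12)

    def test_symmetry_under_axis_swap(self):
        t1, t2 = sk_tensions(1.3, 0.9, 2.0, 5.0)
        s1, s2 = sk_tensions(0.9, 1.3, 2.0, 5.0)
        assert t1 == pytest.approx(s2) and t2 == pytest.approx(s1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sk_tensions(0.0, 1.0, 1.0, 1.0)


class TestViscousTension:
    def test_zero_strain_rate(self):
        assert np.allclose(membrane_viscous_tension(np.zeros((2, 2)), 3.0), 0)

    def test_pure_dilatation_gives_no_stress(self):
        # dilatational surface viscosity is neglected
        D = 0.7 * np.eye(2)
        assert np.allclose(membrane_viscous_tension(D, 2.0), 0.0)

    def test_traceless_shear(self):
        D = np.array([[0.3, 0.1], [0.1, -0.3]])
        assert np.allclose(membrane_viscous_tension(D, 2.5), 5.0 * D)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            membrane_viscous_tension(np.array([[0.0, 1.0], [0.0, 0.0]]), 1.0)


class TestSurfaceStrainRate:
    def setup_method(self):
        self.state = MembraneState(make_sphere_mesh(2.0, 3))

    def test_rigid_translation(self):
        self.state.nodal_velocities = np.tile([0.3, -0.1, 0.2],
                                              (self.state.mesh.n_vertices, 1))
        _, gbar = surface_strain_rate(self.state)
        assert gbar < 1e-12

    def test_rigid_rotation(self):
        om = np.array([0.1, -0.2, 0.3])
        self.state.nodal_velocities = np.cross(om, self.state.mesh.vertices)
        _, gbar = surface_strain_rate(self.state)
        assert gbar < 1e-10

    def test_uniform_dilation_rate(self):
        # v = c x gives in-plane D = c P, so gamma_bar = 2c
        c = 0.05
        self.state.nodal_velocities = c * self.state.mesh.vertices
        _, gbar = surface_strain_rate(self.state)
        assert gbar == pytest.approx(2 * c, rel=1e-9)

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            surface_strain_rate(self.state, dt=0.0)


class TestForceAssembly:
    def test_elastic_force_matches_energy_gradient(self):
        rng = np.random.default_rng(0)
        mesh = make_sphere_mesh(1.0, 2)
        mesh.vertices = mesh.vertices * 1.02 \
            + 1e-2 * rng.standard_normal(mesh.vertices.shape)
        state = MembraneState(mesh)
        mat = MembraneMaterial(Gs=1.3, C=5.0, kc=0.0)
        forces, _, _ = assemble_membrane_forces(state, mat)

        def energy(verts):
            b = state.basis
            _, _, l1, l2, _ = _element_kinematics(
                verts, np.zeros_like(verts), b.tris, b.invX)
            return (sk_energy(l1, l2, mat.Gs, mat.C) * b.area_ref).sum()

        eps = 1e-6
        for i in rng.choice(mesh.n_vertices, 8, replace=False):
            for d in range(3):
                vp = mesh.vertices.copy()
                vp[i, d] += eps
                vm = mesh.vertices.copy()
                vm[i, d] -= eps
                grad = -(energy(vp) - energy(vm)) / (2 * eps)
                assert forces[i, d] == pytest.approx(
                    grad, rel=0.01, abs=1e-8 * np.abs(forces).max())

    def test_stress_free_sphere_has_no_elastic_force(self):
        state = MembraneState(make_sphere_mesh(3.0, 3))
        mat = MembraneMaterial(Gs=1.0, C=10.0, kc=0.0)
        forces, gbar, area = assemble_membrane_forces(state, mat)
        assert np.abs(forces).max() < 1e-12
        assert gbar == 0.0

    def test_net_force_and_torque_vanish(self):
        rng = np.random.default_rng(1)
        mesh = make_sphere_mesh(1.0, 3)
        mesh.vertices = mesh.vertices * 1.05 \
            + 5e-3 * rng.standard_normal(mesh.vertices.shape)
        state = MembraneState(mesh)
        state.nodal_velocities = 1e-2 * rng.standard_normal(
            mesh.vertices.shape)
        mat = MembraneMaterial(Gs=2.0, C=8.0, kc=0.0)
        forces, _, _ = assemble_membrane_forces(state, mat,
                                                mu_s_current=0.5)
        scale = np.abs(forces).max()
        assert np.linalg.norm(forces.sum(axis=0)) < 1e-10 * scale
        torque = np.cross(mesh.vertices, forces).sum(axis=0)
        assert np.linalg.norm(torque) < 1e-9 * scale


class TestBending:
    def test_sphere_energy_near_8_pi_kc(self):
        # scale invariant of the curvature-squared energy on a sphere
        for level, radius in ((4, 4.0), (5, 8.5)):
            Eb = bending_energy(make_sphere_mesh(radius, level), kc=1.0)
            assert abs(Eb / (8 * math.pi) - 1) < 0.02

    def test_mean_curvature_of_sphere(self):
        H, _, K, normals = mean_curvature(make_sphere_mesh(4.0, 4))
        assert np.allclose(4.0 * H, 1.0, atol=5e-4)
        assert np.allclose(16.0 * K, 1.0, atol=5e-3)

    def test_spontaneous_curvature_minimum(self):
        # c0 = 2/r makes the sphere an energy minimum: forces ~ 0
        sphere = make_sphere_mesh(4.0, 4)
        f_min = bending_forces(sphere, kc=1.0, c0=0.5)
        deformed = make_sphere_mesh(4.0, 4)
        deformed.vertices = deformed.vertices * (
            1 + 0.1 * (deformed.vertices[:, [2]] / 4.0) ** 2)
        f_def = bending_forces(deformed, kc=1.0)
        assert np.abs(f_min).max() < 0.05 * np.abs(f_def).max()

    def test_net_bending_force_vanishes(self):
        deformed = make_sphere_mesh(3.0, 3)
        deformed.vertices[:, 0] *= 1.3
        f = bending_forces(deformed, kc=2.0)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-12 * np.abs(f).max()


def test_material_validation():
    with pytest.raises(ValueError):
        MembraneMaterial(Gs=-1.0, C=1.0)
    mat = MembraneMaterial(Gs=2.0, C=10.0)
    assert mat.Ks == pytest.approx(42.0)
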