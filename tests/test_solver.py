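"""Membrane kinematics, loads, and equilibrium-solver verification.

The solver is checked against closed-form oracles: uniform-stretch strain
formulas, the equibiaxial membrane tension, the inflated-balloon relation
p = 4H/(R lam^3) (lam^2 - lam^-4) W'(I1), and objectivity/frame-indifference
properties.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from capsfem.geometry import GeometryParams, generate_capsule, make_fixture, rotate_about_axis
from capsfem.materials import RegionMaterial, YeohMaterial, equibiaxial_cauchy_stress
from capsfem.solver import (
    LoadCase,
    MembraneModel,
    Sphere,
    contact_force,
    element_internal_force,
    element_strain,
    pressure_load,
    solve_equilibrium,
    solve_static,
    strain_field,
    total_strain_energy,
)


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


REF_TRI = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.2, 0.8, 0.0]])


class TestElementStrain:
    def test_identical_triangles_give_exact_zero(self):
        E = element_strain(REF_TRI, REF_TRI)
        assert np.all(E == 0.0)

    def test_uniform_biaxial_stretch_closed_form(self):
        lam = 1.23
        E = element_strain(REF_TRI, REF_TRI * lam)
        np.testing.assert_allclose(
            E, np.eye(2) * (lam**2 - 1) / 2, rtol=1e-12, atol=1e-12
        )

    def test_rigid_motion_objectivity(self):
        for seed in range(5):
            Q = _random_rotation(seed)
            moved = REF_TRI @ Q.T + np.array([3.0, -2.0, 5.0])
            E = element_strain(REF_TRI, moved)
            assert np.abs(E).max() < 1e-12

    def test_degenerate_reference_rejected(self):
        bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            element_strain(bad, bad)


class TestElementForces:
    def test_undeformed_forces_vanish(self):
        f = element_internal_force(YeohMaterial(1.0), 1.0, REF_TRI, REF_TRI)
        assert np.abs(f).max() < 1e-14

    def test_forces_self_equilibrate(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            deformed = REF_TRI + 0.1 * rng.normal(size=(3, 3))
            f = element_internal_force(YeohMaterial(2.0, -1.0, 5.0), 1.5, REF_TRI, deformed)
            np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_equibiaxial_membrane_tension_closed_form(self):
        """Boundary reaction of a stretched patch equals h * sigma / lambda.

        For equibiaxial stretch lam of an incompressible membrane, the force
        per unit reference edge length is h * P = h * sigma(lam) / lam.
        """
        lam, h = 1.2, 0.7
        mat = YeohMaterial(1.3, -0.4, 2.0)
        patch = make_fixture("flat_patch", n=4, thickness=h)
        model = MembraneModel(patch, {"patch": RegionMaterial(mat, h)})
        x = patch.nodes * lam
        f = np.zeros_like(x)
        fe = model.element_internal_forces(x[model.triangles])
        np.add.at(f, model.triangles, fe)
        edge = np.flatnonzero(np.isclose(patch.nodes[:, 0], 1.0))
        reaction = f[edge].sum(axis=0)
        expected = h * equibiaxial_cauchy_stress(mat, lam) / lam  # per unit ref length
        assert reaction[0] == pytest.approx(expected, rel=1e-6)
        assert abs(reaction[1]) < 1e-10 * abs(reaction[0])


class TestLoads:
    def test_closed_sphere_pressure_sums_to_zero(self):
        sph = make_fixture("thin_sphere", radius=5.0, subdivisions=2)
        p = 0.01
        f = pressure_load(sph.nodes, sph.triangles, p)
        net = np.linalg.norm(f.sum(axis=0))
        assert net < 1e-9 * p * 4 * np.pi * 25.0

    def test_flat_square_total_force(self):
        patch = make_fixture("flat_patch", n=3)
        f = pressure_load(patch.nodes, patch.triangles, 2.5)
        np.testing.assert_allclose(f.sum(axis=0), [0, 0, 2.5], atol=1e-12)

    def test_pressure_linearity(self):
        patch = make_fixture("flat_patch", n=2)
        f1 = pressure_load(patch.nodes, patch.triangles, 1.0)
        f2 = pressure_load(patch.nodes, patch.triangles, 2.0)
        np.testing.assert_array_equal(f2, 2.0 * f1)

    def test_contact_inactive_outside(self):
        sphere = Sphere((0, 0, 0), 1.0)
        f = contact_force(np.array([[2.0, 0, 0]]), sphere, 10.0)
        assert np.all(f == 0.0)

    def test_contact_penalty_magnitude_and_direction(self):
        sphere = Sphere((0, 0, 0), 1.0)
        f = contact_force(np.array([[0.6, 0, 0]]), sphere, 10.0)
        np.testing.assert_allclose(f[0], [10.0 * 0.4, 0, 0], rtol=1e-12)

    def test_contact_force_is_negative_energy_gradient(self):
        sphere = Sphere((0.3, -0.2, 0.1), 2.0)
        k = 7.0
        x = np.array([1.1, 0.4, 0.6])

        def energy(pt):
            d = max(sphere.radius - np.linalg.norm(pt - sphere.center), 0.0)
            return 0.5 * k * d * d

        g = np.zeros(3)
        h = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            g[i] = (energy(x + e) - energy(x - e)) / (2 * h)
        f = contact_force(x[None], sphere, k)[0]
        np.testing.assert_allclose(f, -g, atol=1e-6)


class TestEquilibrium:
    def test_biaxial_patch_field_is_uniform(self, flat_patch, neo_hookean_patch_material):
        lam = 1.15
        model = MembraneModel(flat_patch, neo_hookean_patch_material)
        b = flat_patch.node_sets["boundary"]
        x0 = flat_patch.nodes.copy()
        x0[b, :2] *= lam
        free = np.ones_like(x0, dtype=bool)
        free[b] = False
        free[:, 2] = False  # in-plane problem
        x, info = solve_equilibrium(model, x0, free, tol_rel=1e-12)
        assert info["converged"]
        E = model.strains(x)
        assert np.ptp(E, axis=0).max() < 1e-10
        np.testing.assert_allclose(E[:, 0, 0], (lam**2 - 1) / 2, atol=1e-10)

    def test_trivial_equilibrium_converges_immediately(self, small_capsule, default_materials):
        case = LoadCase(rotation_schedule=(0.0,), internal_pressure=0.0)
        states = solve_static(small_capsule, default_materials, case)
        assert len(states) == 1
        assert states[0].converged and states[0].n_iterations == 0
        assert np.abs(states[0].displacements).max() == 0.0

    def test_balloon_inflation_matches_closed_form(self):
        """FE equilibrium stretch within 2% of the closed-form balloon root."""
        R, H = 10.0, 0.5
        mat = YeohMaterial(0.1)

        def balloon_p(lam):
            i1 = 2 * lam**2 + lam**-4
            return 4 * H / (R * lam**3) * (lam**2 - lam**-4) * mat.dW_dI1(i1)

        lam_target = 1.1
        p = balloon_p(lam_target)
        lam_check = brentq(lambda l: balloon_p(l) - p, 1.0001, 1.35)
        assert lam_check == pytest.approx(lam_target, rel=1e-6)

        mesh = make_fixture("thin_sphere", radius=R, subdivisions=3, thickness=H)
        model = MembraneModel(mesh, {"sphere": RegionMaterial(mat, H)})
        free = np.ones_like(mesh.nodes, dtype=bool)
        x = mesh.nodes.copy()
        for frac in (0.5, 1.0):
            x, info = solve_equilibrium(model, x, free, pressure=frac * p, tol_rel=1e-8)
            assert info["converged"]
        lam_fe = np.mean(np.linalg.norm(x - x.mean(axis=0), axis=1)) / R
        assert lam_fe == pytest.approx(lam_target, rel=0.02)

    def test_frame_indifference_of_the_solution(self, default_materials):
        """Rigidly rotating mesh + axis rotates the inflated solution.

        Checked in the pressure-only state: once the rotation drives parts of
        the membrane into compression the equilibrium wrinkles and is no
        longer unique, so only the stable inflated configuration admits a
        pointwise comparison (see the methods note).
        """
        mesh = generate_capsule(GeometryParams(n_circ=16, n_axial=4), default_materials)
        case = LoadCase(rotation_schedule=(0.0,), internal_pressure=7e-4)
        states = solve_static(mesh, default_materials, case, tol_rel=1e-10)

        Q = _random_rotation(11)
        mesh_rot = generate_capsule(
            GeometryParams(n_circ=16, n_axial=4), default_materials
        )
        mesh_rot.nodes = mesh.nodes @ Q.T
        case_rot = LoadCase(
            rotation_schedule=(0.0,),
            rotation_axis=Q @ np.asarray(case.rotation_axis),
            rotation_center=Q @ np.asarray(case.rotation_center),
            internal_pressure=7e-4,
        )
        states_rot = solve_static(mesh_rot, default_materials, case_rot, tol_rel=1e-10)
        u_expected = states[-1].displacements @ Q.T
        scale = np.abs(u_expected).max()
        assert scale > 1e-4  # the pressure actually deforms the capsule
        np.testing.assert_allclose(
            states_rot[-1].displacements, u_expected, atol=1e-8 * max(scale, 1.0)
        )

    def test_load_path_independence_under_inflation(self, default_materials):
        """Conservative loading: ramping pressure in 1 vs 3 steps agrees.

        The tension-dominated inflated state is a unique stable equilibrium,
        so the converged solution must not depend on the load path there.
        """
        mesh = generate_capsule(GeometryParams(n_circ=16, n_axial=4), default_materials)
        model = MembraneModel(mesh, default_materials)
        fixed = np.concatenate(
            [mesh.node_sets["glenoid_ring"], mesh.node_sets["humeral_ring"]]
        )
        free = np.ones_like(mesh.nodes, dtype=bool)
        free[fixed] = False
        p = 7e-4
        x_direct, info = solve_equilibrium(
            model, mesh.nodes.copy(), free, pressure=p, tol_rel=1e-10
        )
        assert info["converged"]
        x_ramp = mesh.nodes.copy()
        for frac in (1 / 3, 2 / 3, 1.0):
            x_ramp, info = solve_equilibrium(
                model, x_ramp, free, pressure=frac * p, tol_rel=1e-10
            )
            assert info["converged"]
        rel = np.linalg.norm(x_direct - x_ramp) / np.linalg.norm(
            x_direct - mesh.nodes
        )
        assert rel < 1e-6

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            LoadCase(rotation_schedule=(5.0, 10.0))
        with pytest.raises(ValueError):
            LoadCase(rotation_schedule=(0.0, 10.0, 10.0))


class TestStrainField:
    def test_zero_displacement_gives_exact_zero_strain(self, small_capsule):
        f = strain_field(small_capsule, np.zeros_like(small_capsule.nodes))
        assert np.all(f.green_lagrange == 0.0)
        assert np.all(f.max_principal == 0.0)

    def test_principal_ordering(self, small_capsule):
        rng = np.random.default_rng(0)
        u = 0.05 * rng.normal(size=small_capsule.nodes.shape)
        f = strain_field(small_capsule, u)
        assert np.all(f.max_principal >= f.min_principal)

    def test_energy_zero_at_rest_and_positive_under_stretch(
        self, small_capsule, default_materials
    ):
        assert total_strain_energy(
            small_capsule, default_materials, np.zeros_like(small_capsule.nodes)
        ) == pytest.approx(0.0)
        u = 0.03 * small_capsule.nodes  # uniform 3% inflation of everything
        assert total_strain_energy(small_capsule, default_materials, u) > 0.0
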