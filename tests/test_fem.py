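"""FE verification: element kernels, assembly, rods, loads, solutions."""

import numpy as np
import pytest

import fabrifem as ff
from fabrifem import fem
from fabrifem.constitutive import ElementMaterial, isotropic_compliance, isotropic_stiffness


def iso_materials(mesh, E=1000.0, nu=0.3, rho=1.0):
    C = isotropic_stiffness(E, nu)
    S = isotropic_compliance(E, nu)
    return [ElementMaterial(e, "iso_homo", rho, C, S) for e in range(mesh.n_elements)]


def clamped_system(mesh, mats, fix_sets, f=None):
    K = fem.assemble_stiffness(mesh, mats)
    fixed = np.unique(np.concatenate(
        [(3 * mesh.node_sets[s][:, None] + np.arange(3)).reshape(-1) for s in fix_sets]))
    return fem.LinearSystem(K=K, f=f if f is not None else np.zeros(3 * mesh.n_nodes),
                            fixed_dofs=fixed, fixed_values=np.zeros(len(fixed)),
                            n_nodes=mesh.n_nodes)


class TestElementStiffness:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.p = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        self.p += 0.1 * rng.standard_normal((4, 3))
        self.C = isotropic_stiffness(500.0, 0.25)
        self.Ke, _, self.V = fem.element_stiffness(self.p, self.C)

    def test_rigid_translations_in_null_space(self):
        for axis in range(3):
            u = np.zeros(12)
            u[axis::3] = 1.0
            assert np.abs(self.Ke @ u).max() < 1e-10 * np.abs(self.Ke).max()

    def test_linearized_rigid_rotation_in_null_space(self):
        W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        u = (self.p @ W.T).reshape(-1)
        assert np.abs(self.Ke @ u).max() < 1e-8 * np.abs(self.Ke).max()

    def test_inverted_tet_rejected(self):
        bad = self.p[[0, 2, 1, 3]]
        with pytest.raises(ValueError, match="volume"):
            fem.element_stiffness(bad, self.C)

    def test_uniaxial_stretch_energy_closed_form(self):
        """nu = 0 cube under prescribed stretch: U = E eps^2 V / 2."""
        mesh = ff.box_mesh((1.0, 1.0, 1.0), 1.0)
        E, eps = 800.0, 1e-3
        mats = iso_materials(mesh, E=E, nu=0.0)
        K = fem.assemble_stiffness(mesh, mats)
        u = np.zeros(3 * mesh.n_nodes)
        u[0::3] = eps * mesh.nodes[:, 0]
        energy = 0.5 * u @ (K @ u)
        assert energy == pytest.approx(0.5 * E * eps**2 * 1.0, rel=1e-10)


class TestRods:
    def test_surface_forces_sum_to_reaction(self, femur, all_tables):
        card, lc1, _, _ = all_tables
        mats = iso_materials(femur, E=5000.0)
        system = fem.build_system(femur, mats, lc1)
        result = fem.solve_static(system, femur, mats)
        # rod axial forces transmitted onto the surface nodes
        k_rod = fem.default_rod_stiffness(femur, mats)
        u = result.u
        center = system.center_node
        total = np.zeros(3)
        for sn in femur.node_sets[lc1.joint_surface_set]:
            axis = femur.nodes[sn] - lc1.joint_center_mm
            n = axis / np.linalg.norm(axis)
            total += k_rod * np.outer(n, n) @ (u[center] - u[sn])
        assert np.allclose(total, lc1.reaction_vector(), rtol=1e-6)

    def test_rod_stiffness_saturation(self, femur, all_tables):
        _, lc1, _, _ = all_tables
        mats = iso_materials(femur, E=5000.0)
        base = fem.default_rod_stiffness(femur, mats)
        tips = []
        for k in (base, 2 * base):
            system = fem.build_system(femur, mats, lc1, rod_stiffness=k)
            result = fem.solve_static(system, femur, mats)
            interior = np.linalg.norm(result.u[:femur.n_nodes], axis=1)
            tips.append(interior)
        rel = np.abs(tips[1] - tips[0]).max() / np.abs(tips[0]).max()
        assert rel < 0.01

    def test_zero_length_rod_rejected(self):
        nodes = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="zero-length"):
            fem.rod_stiffness_entries(nodes, np.zeros(3), np.array([0]), 1.0, 2)


class TestApplyLoads:
    def test_total_force_bookkeeping(self, femur, all_tables):
        _, lc1, _, _ = all_tables
        f = fem.apply_loads(femur, lc1, femur.n_nodes + 1, center_node=femur.n_nodes)
        total = f.reshape(-1, 3).sum(axis=0)
        expected = lc1.total_muscle_force() + lc1.reaction_vector()
        assert np.allclose(total, expected, atol=1e-9)

    def test_single_muscle_single_node(self):
        mesh = ff.box_mesh((1.0, 1.0, 1.0), 1.0)
        mesh.node_sets["pull"] = np.array([0])
        lc = ff.LoadCase(name="one",
                         muscle_loads=[ff.MuscleLoad("pull", np.array([0, 0, 1.0]), 10.0)],
                         reaction_direction=np.array([1.0, 0, 0]),
                         reaction_magnitude_N=0.0)
        f = fem.apply_loads(mesh, lc, mesh.n_nodes + 1, center_node=mesh.n_nodes)
        nz = np.flatnonzero(f)
        assert list(nz) == [2]
        assert f[2] == 10.0

    def test_missing_attachment_set_is_named(self, femur, all_tables):
        _, lc1, _, _ = all_tables
        lc1.muscle_loads[0].attachment_set = "no_such_patch"
        try:
            with pytest.raises(ValueError, match="no_such_patch"):
                fem.apply_loads(femur, lc1, femur.n_nodes)
        finally:
            lc1.muscle_loads[0].attachment_set = "Glut_max1"


class TestSolveStatic:
    def test_uniaxial_bar_matches_sigma_l_over_e(self):
        mesh = ff.box_mesh((10.0, 10.0, 40.0), 2.5)
        E, sigma, L = 1500.0, 2.0, 40.0
        mats = iso_materials(mesh, E=E)
        f = fem.face_traction_loads(mesh, "zmax", (0, 0, sigma))
        nodes, zmin = mesh.nodes, mesh.node_sets["zmin"]
        fixed = [3 * n + 2 for n in zmin]
        n0 = int(zmin[np.argmin(np.linalg.norm(nodes[zmin][:, :2], axis=1))])
        n1 = int(zmin[np.argmax(nodes[zmin][:, 0])])
        fixed += [3 * n0, 3 * n0 + 1, 3 * n1 + 1]
        system = fem.LinearSystem(K=fem.assemble_stiffness(mesh, mats), f=f,
                                  fixed_dofs=np.array(sorted(set(fixed))),
                                  fixed_values=np.zeros(len(set(fixed))),
                                  n_nodes=mesh.n_nodes)
        result = fem.solve_static(system, mesh, mats)
        tip = result.u[mesh.node_sets["zmax"], 2].mean()
        assert abs(tip - sigma * L / E) / (sigma * L / E) < 1e-3
        assert result.residual < 1e-8

    def test_patch_test_constant_strain(self):
        """Linear displacement BCs reproduce a constant strain exactly."""
        mesh = ff.box_mesh((2.0, 2.0, 2.0), 1.0)
        A = np.array([[1.0, 0.4, -0.2], [0.1, -0.6, 0.3], [0.2, 0.1, 0.8]]) * 1e-3
        mats = iso_materials(mesh, E=900.0, nu=0.27)
        boundary = mesh.boundary_nodes()
        fixed = (3 * boundary[:, None] + np.arange(3)).reshape(-1)
        values = (mesh.nodes[boundary] @ A.T).reshape(-1)
        system = fem.LinearSystem(K=fem.assemble_stiffness(mesh, mats),
                                  f=np.zeros(3 * mesh.n_nodes), fixed_dofs=fixed,
                                  fixed_values=values, n_nodes=mesh.n_nodes)
        result = fem.solve_static(system, mesh, mats)
        sym = 0.5 * (A + A.T)
        expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                             2 * sym[1, 2], 2 * sym[2, 0], 2 * sym[0, 1]])
        assert np.abs(result.strain - expected).max() < 1e-12

    def test_global_equilibrium_and_energy_balance(self, femur, all_tables):
        card, lc1, _, _ = all_tables
        mats = iso_materials(femur, E=5000.0)
        system = fem.build_system(femur, mats, lc1)
        result = fem.solve_static(system, femur, mats)
        applied = lc1.total_muscle_force() + lc1.reaction_vector()
        fixed_nodes = femur.node_sets["distal_fixed"]
        reaction = result.reactions[fixed_nodes].sum(axis=0)
        assert np.linalg.norm(reaction + applied) / np.linalg.norm(applied) < 1e-8
        # energy stored in tets + rods equals external work
        u = result.u.reshape(-1)
        external = 0.5 * system.f @ u
        internal = 0.5 * u @ (system.K @ u)
        assert abs(external - internal) / abs(external) < 1e-8
        tet_energy = fem.total_strain_energy(result, femur)
        assert tet_energy <= internal * (1 + 1e-8)
        assert tet_energy > 0.5 * internal     # rods store little in saturation

    def test_under_constrained_system_raises(self):
        mesh = ff.box_mesh((1.0, 1.0, 1.0), 1.0)
        mats = iso_materials(mesh)
        system = fem.LinearSystem(K=fem.assemble_stiffness(mesh, mats),
                                  f=np.zeros(3 * mesh.n_nodes),
                                  fixed_dofs=np.array([0]), fixed_values=np.zeros(1),
                                  n_nodes=mesh.n_nodes)
        system.f[5] = 1.0
        with pytest.raises(ValueError):
            fem.solve_static(system, mesh, mats)

    def test_isotropic_model1_equals_model2_displacements(self, femur, all_tables):
        from fabrifem.fabric import ElementStructure
        from test_constitutive import fabric_from_m

        card, lc1, _, _ = all_tables
        s_iso = [ElementStructure(e, 0.4, fabric_from_m((1.0, 1.0, 1.0)))
                 for e in range(femur.n_elements)]
        s_none = [ElementStructure(e, 0.4, None) for e in range(femur.n_elements)]
        m1 = ff.assign_materials(femur, s_iso, "anisotropic", card)
        m2 = ff.assign_materials(femur, s_none, "iso_hetero", card)
        r1 = fem.solve_static(fem.build_system(femur, m1, lc1), femur, m1)
        r2 = fem.solve_static(fem.build_system(femur, m2, lc1), femur, m2)
        scale = np.abs(r2.u).max()
        assert np.abs(r1.u - r2.u).max() < 1e-9 * scale

    def test_refinement_is_consistent(self, all_tables):
        """Halving the element size changes the head displacement modestly."""
        _, lc1, _, _ = all_tables
        tips = []
        for edge in (6.0, 4.0):
            mesh = ff.femur_like_mesh(target_edge_mm=edge)
            mats = iso_materials(mesh, E=5000.0)
            result = fem.solve_static(fem.build_system(mesh, mats, lc1), mesh, mats)
            head = np.flatnonzero(np.linalg.norm(mesh.nodes, axis=1) < 8.0)
            tips.append(np.linalg.norm(result.u[head], axis=1).mean())
        assert abs(tips[1] - tips[0]) / tips[1] < 0.25
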