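"""Tet10 meshing and linear-elastic solver verification."""

import types

import numpy as np
import pytest
import trimesh

from sacroplan.femesh import NodeSets, define_node_sets, tetrahedralize
from sacroplan.fesolve import (LoadCase, assemble_stiffness, compute_stiffness,
                               convergence_sweep, export_inp, read_inp, solve_static)


def _box_assembly(ex, ey, ez):
    tf = trimesh.transformations.translation_matrix((ex / 2, ey / 2, ez / 2))
    return types.SimpleNamespace(bone=trimesh.creation.box(extents=(ex, ey, ez),
                                                           transform=tf),
                                 fragment=None, screws={})


def _bar_model(ex=10.0, ey=10.0, ez=50.0, h=2.5, E=1000.0, nu=0.0):
    mesh = tetrahedralize(_box_assembly(ex, ey, ez), h)
    mesh.young[:] = E
    mesh.poisson_ratio[:] = nu
    z = mesh.nodes[:, 2]
    base = np.flatnonzero(z < 1e-9)
    surf = mesh.surface_nodes()
    top = np.intersect1d(surf, np.flatnonzero(z > ez - 1e-9))
    sets = NodeSets(fixed_endplate=base, fixed_caudal=base,
                    head_load=top, head_measure=top)
    return mesh, sets


class TestTetrahedralize:
    def test_unit_cube_volume_exact(self):
        mesh = tetrahedralize(_box_assembly(1, 1, 1), 0.5)
        assert mesh.total_volume() == pytest.approx(1.0, abs=1e-6)

    def test_element_count_grows_under_refinement(self):
        asm = _box_assembly(10, 10, 10)
        coarse = tetrahedralize(asm, 5.0)
        fine = tetrahedralize(asm, 2.0)
        assert len(fine.elements) > len(coarse.elements)

    def test_interface_nodes_shared(self):
        """Screw-in-block toy: bone and screw meshes share interface nodes
        (no duplicated coordinates), realizing the tie by merging."""
        tf = trimesh.transformations.translation_matrix((5, 5, 5))
        block = trimesh.creation.box(extents=(10, 10, 10), transform=tf)
        cyl = trimesh.creation.cylinder(radius=2.0, height=12.0,
                                        transform=trimesh.transformations.translation_matrix((5, 5, 5)))
        asm = types.SimpleNamespace(bone=block, fragment=None, screws={"S": cyl})
        mesh = tetrahedralize(asm, 1.0)
        assert set(np.unique(mesh.part_labels)) == {"bone", "screw"}
        uniq = np.unique(np.round(mesh.nodes, 9), axis=0)
        assert len(uniq) == len(mesh.nodes)
        shared = np.intersect1d(mesh.node_part()["bone"], mesh.node_part()["screw"])
        assert len(shared) > 0

    def test_positive_jacobians(self):
        mesh = tetrahedralize(_box_assembly(7, 5, 3), 1.0)
        c = mesh.corner_coords()
        det = np.linalg.det(c[:, 1:] - c[:, :1])
        assert np.all(det > 0)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            tetrahedralize(_box_assembly(1, 1, 1), -1.0)


class TestNodeSets:
    def test_caudal_fraction_one_selects_all_surface(self):
        mesh = tetrahedralize(_box_assembly(10, 10, 30), 2.5)
        mesh.part_labels[:] = "bone"
        # need a screw part for head sets: relabel topmost elements
        zc = mesh.corner_coords().mean(axis=1)[:, 2]
        mesh.part_labels[zc > 25] = "screw"
        sets = define_node_sets(mesh, caudal_fraction=1.0,
                                head_spec={"axis_point": (5, 5, 30),
                                           "axis_dir": (0, 0, -1),
                                           "t_range": (0.0, 5.0)})
        parts = mesh.node_part()
        bone_surf = np.setdiff1d(
            np.intersect1d(mesh.surface_nodes(), parts["bone"]), parts["screw"])
        assert set(sets.fixed_caudal) == set(bone_surf)

    def test_caudal_third_matches_bruteforce_scan(self):
        mesh = tetrahedralize(_box_assembly(10, 10, 30), 2.5)
        mesh.part_labels[:] = "bone"
        zc = mesh.corner_coords().mean(axis=1)[:, 2]
        mesh.part_labels[zc > 25] = "screw"
        sets = define_node_sets(mesh, caudal_fraction=1 / 3,
                                head_spec={"axis_point": (5, 5, 30),
                                           "axis_dir": (0, 0, -1),
                                           "t_range": (0.0, 5.0)})
        parts = mesh.node_part()
        surf = np.setdiff1d(
            np.intersect1d(mesh.surface_nodes(), parts["bone"]), parts["screw"])
        zs = mesh.nodes[surf, 2]
        brute = surf[zs <= zs.min() + (zs.max() - zs.min()) / 3 + 1e-9]
        assert set(sets.fixed_caudal) == set(brute)

    def test_head_measure_in_middle_third_band(self):
        mesh = tetrahedralize(_box_assembly(10, 10, 30), 2.5)
        mesh.part_labels[:] = "bone"
        zc = mesh.corner_coords().mean(axis=1)[:, 2]
        mesh.part_labels[zc > 20] = "screw"
        h = 10.0
        sets = define_node_sets(mesh,
                                head_spec={"axis_point": (5, 5, 20),
                                           "axis_dir": (0, 0, 1),
                                           "t_range": (0.0, h)})
        t = mesh.nodes[sets.head_measure, 2] - 20.0
        assert np.all((t >= h / 3 - 1e-6) & (t <= 2 * h / 3 + 1e-6))

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            NodeSets(fixed_endplate=[], fixed_caudal=[1], head_load=[2],
                     head_measure=[2])


class TestSolver:
    def test_zero_load_zero_displacement(self):
        mesh, sets = _bar_model(h=5.0)
        res = solve_static(mesh, sets, LoadCase(0.0, (0, 0, 1)))
        assert np.all(res.displacement == 0.0)

    def test_bar_tip_displacement_matches_closed_form(self):
        """Uniaxial bar under consistent traction: u = FL/(EA) to 0.1%."""
        E, A, L, F = 1000.0, 100.0, 50.0, 200.0
        mesh, sets = _bar_model(E=E)
        res = solve_static(mesh, sets, LoadCase(F, (0, 0, 1)),
                           load_distribution="consistent")
        assert res.mean_u_head == pytest.approx(F * L / (E * A), rel=1e-3)

    def test_cantilever_matches_euler_bernoulli(self):
        """Slender cantilever tip deflection within 5% of FL^3/(3EI)."""
        E = 1000.0
        mesh, sets = _bar_model(ex=4, ey=4, ez=40, h=1.0, E=E)
        res = solve_static(mesh, sets, LoadCase(1.0, (1, 0, 0)),
                           load_distribution="consistent")
        I = 4 * 4**3 / 12
        exact = 1.0 * 40**3 / (3 * E * I)
        ux = res.displacement[sets.head_load, 0].mean()
        assert ux == pytest.approx(exact, rel=0.05)

    def test_reaction_forces_balance_applied_load(self):
        mesh, sets = _bar_model(h=2.5, nu=0.3)
        res = solve_static(mesh, sets, LoadCase(500.0, (0.3, 0.1, 1.0)))
        out_of_balance = res.diagnostics["reaction_sum"] + res.diagnostics["applied_force"]
        assert np.linalg.norm(out_of_balance) / 500.0 < 1e-6

    def test_doubling_modulus_doubles_stiffness(self):
        mesh, sets = _bar_model(h=5.0, nu=0.3)
        load = LoadCase(500.0, (0, 0, 1))
        k1 = solve_static(mesh, sets, load).stiffness
        mesh.young *= 2
        k2 = solve_static(mesh, sets, load).stiffness
        assert k2 == pytest.approx(2 * k1, rel=1e-9)

    def test_rigid_translation_leaves_stiffness_unchanged(self):
        mesh, sets = _bar_model(h=5.0, nu=0.3)
        load = LoadCase(500.0, (0, 0, 1))
        k1 = solve_static(mesh, sets, load).stiffness
        mesh.nodes = mesh.nodes + np.array([123.0, -45.0, 67.0])
        k2 = solve_static(mesh, sets, load).stiffness
        assert k2 == pytest.approx(k1, rel=1e-9)

    def test_unconstrained_system_errors(self):
        mesh, _ = _bar_model(h=5.0)
        with pytest.raises(Exception):
            sets = NodeSets(fixed_endplate=[0], fixed_caudal=[0],
                            head_load=[len(mesh.nodes) - 1],
                            head_measure=[len(mesh.nodes) - 1])
            # a single fixed node leaves rotational rigid-body modes;
            # the solver must flag the singular system
            solve_static(mesh, sets, LoadCase(100.0, (1, 0, 0)))

    def test_stiffness_matches_dense_oracle_on_small_mesh(self):
        """Assembled sparse K equals an independent per-element B-matrix
        assembly (dense, straightforward quadrature) to 1e-8."""
        mesh = tetrahedralize(_box_assembly(2, 2, 2), 1.0)
        mesh.young[:] = 70.0
        mesh.poisson_ratio[:] = 0.25
        K = assemble_stiffness(mesh).toarray()
        K_ref = _dense_reference_stiffness(mesh)
        assert np.abs(K - K_ref).max() <= 1e-8 * np.abs(K_ref).max()


def _dense_reference_stiffness(mesh):
    """Independent tet10 assembly via explicit B matrices and Voigt D."""
    n = len(mesh.nodes)
    K = np.zeros((3 * n, 3 * n))
    qa, qb = 0.5854101966249685, 0.1381966011250105
    gps = [(qa, qb, qb), (qb, qa, qb), (qb, qb, qa), (qb, qb, qb)]

    def shape_grad(xi, eta, zeta):
        l1 = 1 - xi - eta - zeta
        L = [l1, xi, eta, zeta]
        dL = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        g = np.zeros((10, 3))
        for i in range(4):
            g[i] = (4 * L[i] - 1) * dL[i]
        for e, (a, b) in enumerate([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]):
            g[4 + e] = 4 * (L[a] * dL[b] + L[b] * dL[a])
        return g

    for el, E, nu in zip(mesh.elements, mesh.young, mesh.poisson_ratio):
        c = mesh.nodes[el[:4]]
        J = c[1:] - c[:1]
        V = abs(np.linalg.det(J)) / 6
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3:, 3:] = np.eye(3) * mu
        ke = np.zeros((30, 30))
        for gp in gps:
            dNdx = shape_grad(*gp) @ np.linalg.inv(J.T)
            B = np.zeros((6, 30))
            for i in range(10):
                B[0, 3 * i] = dNdx[i, 0]
                B[1, 3 * i + 1] = dNdx[i, 1]
                B[2, 3 * i + 2] = dNdx[i, 2]
                B[3, 3 * i] = dNdx[i, 1]
                B[3, 3 * i + 1] = dNdx[i, 0]
                B[4, 3 * i + 1] = dNdx[i, 2]
                B[4, 3 * i + 2] = dNdx[i, 1]
                B[5, 3 * i] = dNdx[i, 2]
                B[5, 3 * i + 2] = dNdx[i, 0]
            ke += B.T @ D @ B * V / 4
        dof = np.repeat(el, 3) * 3 + np.tile([0, 1, 2], 10)
        K[np.ix_(dof, dof)] += ke
    return K


class TestStiffnessDefinition:
    def test_definition(self):
        res = types.SimpleNamespace(mean_u_head=1.0)
        assert compute_stiffness(res, LoadCase(500.0, (0, 0, 1))) == 500.0

    def test_paper_scale_value(self):
        """500 N over a 0.0756 mm mean head displacement ~ 6.6 kN/mm."""
        res = types.SimpleNamespace(mean_u_head=0.0756)
        k = compute_stiffness(res, LoadCase(500.0, (0, 0, 1)))
        assert k == pytest.approx(500.0 / 0.0756)

    def test_zero_displacement_under_load_errors(self):
        res = types.SimpleNamespace(mean_u_head=0.0)
        with pytest.raises(ValueError):
            compute_stiffness(res, LoadCase(500.0, (0, 0, 1)))


class TestConvergenceSweep:
    def test_toy_block_h_refinement(self):
        """Element count increases monotonically and the two finest meshes
        agree on mean head displacement within the 2% tolerance."""
        def factory(size):
            return _bar_model(ex=10, ey=10, ez=30, h=size, E=500.0, nu=0.3)

        table = convergence_sweep(factory, [2.0, 2.5, 3.0, 5.0, 7.5],
                                  LoadCase(300.0, (0, 0, 1)))
        assert len(table) == 5
        assert (table["error"] == "").all()
        n = table["n_elements"].to_numpy()
        assert np.all(np.diff(n) > 0)  # coarse -> fine ordering
        u = table["mean_u_head_mm"].to_numpy()
        assert abs(u[-1] - u[-2]) / u[-2] < 0.02
        assert bool(table["converged"].iloc[-1])

    def test_needs_two_sizes(self):
        with pytest.raises(ValueError):
            convergence_sweep(lambda s: None, [1.0], LoadCase(1.0, (0, 0, 1)))


class TestInpExport:
    def test_round_trip_single_model(self, tmp_path):
        mesh, sets = _bar_model(h=5.0)
        path = tmp_path / "model.inp"
        export_inp(mesh, sets, LoadCase(500.0, (0, 0, 1)), path)
        nodes, elements = read_inp(path)
        np.testing.assert_allclose(nodes, mesh.nodes, atol=1e-8)
        np.testing.assert_array_equal(np.sort(elements.ravel()),
                                      np.sort(mesh.elements.ravel()))

    def test_two_materials_two_blocks(self, tmp_path):
        mesh, sets = _bar_model(h=5.0)
        mesh.young[: len(mesh.young) // 2] = 2000.0
        path = tmp_path / "model.inp"
        export_inp(mesh, sets, LoadCase(500.0, (0, 0, 1)), path)
        text = path.read_text()
        assert text.count("*MATERIAL") == 2
        assert text.count("TYPE=C3D10") == 2
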