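import math

import numpy as np
import pytest

from tubeflow.coupling import (NetworkField, export_surface_field_table,
                               interface_dirichlet_from_table,
                               project_1d_to_surface, read_surface_field_table,
                               run_3d1d_case, solve_network_1d)
from tubeflow.fixtures import capped_cylinder
from tubeflow.graph import SpatialGraph, make_synthetic_tree
from tubeflow.surface import TriSurface


@pytest.fixture(scope="module")
def y_network():
    return SpatialGraph(np.array([[0, 0, 0], [0, 0, 5], [3, 0, 9], [-3, 0, 9.0]]),
                        np.ones(4), np.array([[0, 1], [1, 2], [1, 3]]))


class TestKirchhoff:
    def test_single_edge_closed_form(self):
        """Q = G dp with G = pi r^4 / (8 mu L); r=1, L=8/pi, dp=8 -> pi^2/8."""
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 8 / math.pi]]),
                         np.ones(2), np.array([[0, 1]]))
        _, Q, _ = solve_network_1d(g, 1.0, {0: 8.0, 1: 0.0})
        assert Q[0] == pytest.approx(math.pi ** 2 / 8, rel=1e-12)

    def test_symmetric_y_splits_flow_in_half(self, y_network):
        _, Q, _ = solve_network_1d(y_network, 1.0, {0: 1.0, 2: 0.0, 3: 0.0})
        assert abs(Q[1] - Q[2]) <= 1e-12
        assert Q[1] + Q[2] == pytest.approx(Q[0], abs=1e-12)

    def test_random_tree_against_dense_oracle(self):
        tree = make_synthetic_tree(3, seed=4)
        term = tree.terminal_nodes()
        bc = {int(term[0]): 10.0, **{int(t): 0.0 for t in term[1:]}}
        p, Q, _ = solve_network_1d(tree, 1.0, bc)
        # Kirchhoff conservation at interior nodes
        net = np.zeros(tree.n_nodes)
        for e, (a, b) in enumerate(tree.edges):
            net[a] -= Q[e]
            net[b] += Q[e]
        interior = np.setdiff1d(np.arange(tree.n_nodes), term)
        assert np.abs(net[interior]).max() <= 1e-10
        assert abs(net[term].sum()) <= 1e-10
        # independent dense solve of the same Kirchhoff system
        G = math.pi * (0.5 * (tree.radii[tree.edges[:, 0]]
                              + tree.radii[tree.edges[:, 1]])) ** 4 \
            / (8.0 * tree.edge_lengths())
        n = tree.n_nodes
        A = np.zeros((n, n))
        for e, (a, b) in enumerate(tree.edges):
            A[a, a] += G[e]
            A[b, b] += G[e]
            A[a, b] -= G[e]
            A[b, a] -= G[e]
        pd = np.zeros(n)
        pd[term] = [bc[int(t)] for t in term]
        free = interior
        pd[free] = np.linalg.solve(A[np.ix_(free, free)],
                                   -A[np.ix_(free, term)] @ pd[term])
        assert np.abs(pd - p.values).max() <= 1e-10

    def test_equal_pressures_warn_zero_flow(self, y_network, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="tubeflow"):
            _, Q, _ = solve_network_1d(y_network, 1.0, {0: 1.0, 2: 1.0, 3: 1.0})
        assert np.abs(Q).max() <= 1e-12
        assert any("zero-flow" in r.message for r in caplog.records)

    def test_insufficient_bcs_rejected(self, y_network):
        with pytest.raises(ValueError, match="two terminals"):
            solve_network_1d(y_network, 1.0, {0: 1.0})

    def test_non_terminal_bc_rejected(self, y_network):
        with pytest.raises(ValueError, match="terminal"):
            solve_network_1d(y_network, 1.0, {0: 1.0, 1: 0.0})

    def test_upwind_transport_fills_downstream(self, y_network):
        _, _, c = solve_network_1d(y_network, 1.0, {0: 1.0, 2: 0.0, 3: 0.0},
                                   transport={"D": 0.0, "inlet": {0: 1.0}})
        assert np.allclose(c.values, 1.0)  # pure advection from the inlet


class TestProjection:
    def test_constant_field(self, y_network):
        surf = capped_cylinder(1.0, 0, 5, n_theta=16, n_z=8)
        f = project_1d_to_surface(NetworkField(np.full(4, 7.0), y_network),
                                  y_network, surf)
        assert np.all(f.values == 7.0)

    def test_linear_field_matches_bruteforce(self):
        n = 21
        g = SpatialGraph(
            np.stack([np.zeros(n), np.zeros(n), np.linspace(0, 10, n)], axis=1),
            np.ones(n), np.stack([np.arange(n - 1), np.arange(1, n)], axis=1))
        f1d = NetworkField(np.linspace(0, 1, n), g)
        surf = capped_cylinder(1.0, 0, 10, n_theta=24, n_z=20)
        f = project_1d_to_surface(f1d, g, surf)
        rng = np.random.default_rng(0)
        for vi in rng.choice(surf.n_vertices, 50, replace=False):
            d = np.linalg.norm(g.nodes - surf.vertices[vi], axis=1)
            assert f.values[vi] == f1d.values[np.argmin(d)]

    def test_two_vessels_no_crosstalk(self):
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 10], [10, 0, 0], [10, 0, 10.0]]),
                         np.ones(4), np.array([[0, 1], [2, 3]]))
        f1d = NetworkField(np.array([0.0, 0.0, 1.0, 1.0]), g)
        c1 = capped_cylinder(1.0, 0, 10, n_theta=16, n_z=8)
        c2 = TriSurface(c1.vertices + [10, 0, 0], c1.faces)
        scene = TriSurface(np.vstack([c1.vertices, c2.vertices]),
                           np.vstack([c1.faces, c2.faces + c1.n_vertices]))
        f = project_1d_to_surface(f1d, g, scene)
        assert np.all(f.values[:c1.n_vertices] == 0.0)
        assert np.all(f.values[c1.n_vertices:] == 1.0)

    def test_empty_field_rejected(self):
        g = SpatialGraph(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2)))
        surf = capped_cylinder(1.0, 0, 5)
        with pytest.raises(ValueError, match="empty"):
            project_1d_to_surface(NetworkField(np.zeros(0), g), g, surf)


class TestTableExport:
    def test_row_count_and_roundtrip(self, tmp_path):
        surf = capped_cylinder(1.0, 0, 5, n_theta=16, n_z=8)
        vals = np.linspace(0, 1, surf.n_vertices)
        field = NetworkField.__new__(NetworkField)  # lightweight stand-in
        from tubeflow.fem import MeshField

        f = MeshField.__new__(MeshField)
        f.values = vals
        f.mesh = None
        f.coords = surf.vertices
        path = tmp_path / "cs.txt"
        export_surface_field_table(f, surf, path)
        lines = path.read_text().splitlines()
        assert len(lines) == surf.n_vertices + 1  # header + one row per vertex
        pts, back = read_surface_field_table(path)
        assert np.array_equal(back, vals)
        assert np.array_equal(pts, surf.vertices)

    def test_size_mismatch_rejected(self, tmp_path):
        surf = capped_cylinder(1.0, 0, 5)
        from tubeflow.fem import MeshField

        f = MeshField.__new__(MeshField)
        f.values = np.zeros(3)
        f.mesh = None
        f.coords = surf.vertices
        with pytest.raises(ValueError, match="vertex count"):
            export_surface_field_table(f, surf, tmp_path / "x.txt")

    def test_exact_match_fast_path(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        vals = np.array([1.0, 2.0, 3.0])
        fn = interface_dirichlet_from_table(pts, vals)
        assert fn(np.array([1.0, 0, 0])) == 2.0
        assert fn(np.array([0.9, 0.05, 0])) == 2.0  # nearest fallback


@pytest.fixture(scope="module")
def straight_case():
    g = SpatialGraph(np.array([[0, 0, -6], [0, 0, 6.0]]),
                     np.ones(2), np.array([[0, 1]]))
    tissue, mesh, surf, sfield = run_3d1d_case(
        g, (-6, -6, -9), (6, 6, 9), spacing=0.4)
    return g, tissue, mesh, surf, sfield


class Test3D1DCase:
    def test_bounds_and_radial_decay(self, straight_case):
        _, tissue, _, _, _ = straight_case
        v = tissue.values
        # soft maximum-principle bound (meshes are not strictly acute)
        assert v.min() >= -1e-3 and v.max() <= 1 + 1e-3
        r = np.linalg.norm(tissue.coords[:, :2], axis=1)
        mid = np.abs(tissue.coords[:, 2]) < 4
        bins = np.linspace(1.8, 6.0, 6)
        means = [v[mid & (r >= bins[i]) & (r < bins[i + 1])].mean()
                 for i in range(len(bins) - 1)]
        assert all(means[i] >= means[i + 1] - 1e-9 for i in range(len(means) - 1))

    def test_interface_dirichlet_exact_on_conforming_mesh(self, straight_case):
        """Interface nodes coincide with surface vertices, so the assigned
        Dirichlet values equal the projected field with no interpolation."""
        from scipy.spatial import cKDTree

        _, tissue, mesh, surf, sfield = straight_case
        iface = np.unique(mesh.boundary_faces[mesh.boundary_labels == 99])
        tree = cKDTree(surf.vertices)
        d, j = tree.query(mesh.nodes[iface])
        assert d.max() <= 1e-12
        assert np.abs(tissue.values[iface] - sfield.values[j]).max() <= 1e-12

    def test_zero_vessel_field_gives_zero_tissue(self):
        g = SpatialGraph(np.array([[0, 0, -4], [0, 0, 4.0]]),
                         np.ones(2), np.array([[0, 1]]))
        tissue, *_ = run_3d1d_case(g, (-5, -5, -7), (5, 5, 7), spacing=0.5,
                                   vessel_concentration=NetworkField(np.zeros(2), g))
        assert np.abs(tissue.values).max() <= 1e-12

    def test_hot_branch_warms_nearby_tissue(self):
        y = SpatialGraph(np.array([[0, 0, -5], [0, 0, 0], [4, 0, 5], [-4, 0, 5.0]]),
                         np.ones(4), np.array([[0, 1], [1, 2], [1, 3]]))
        conc = NetworkField(np.array([0.5, 0.5, 1.0, 0.0]), y)
        tissue, mesh, surf, _ = run_3d1d_case(y, (-8, -8, -9), (8, 8, 9),
                                              spacing=0.5,
                                              vessel_concentration=conc)
        x = tissue.coords[:, 0]
        upper = tissue.coords[:, 2] > 2
        near_hot = tissue.values[upper & (x > 2)].mean()
        near_cold = tissue.values[upper & (x < -2)].mean()
        assert near_hot > near_cold
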