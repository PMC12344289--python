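import math

import numpy as np
import pytest

from tubeflow.fixtures import box_surface, capped_cylinder
from tubeflow.fem import (FluidProperties, FunctionSpace, MeshField,
                          SolverConfig, TransportSpec, boundary_flux,
                          solve_adr, solve_ns_ipcs, solve_poisson)
from tubeflow.meshing import box_tet_mesh, tetrahedralize
from tubeflow.surface import TriSurface


def exact_quadratic(x):
    return 1.0 + x[0] ** 2 + 2.0 * x[1] ** 2


ALL_DIRICHLET = {lab: {"dirichlet": exact_quadratic} for lab in range(1, 7)}


class TestPoisson:
    def test_p2_reproduces_quadratic_exactly(self):
        m = box_tet_mesh(h=1 / 3)
        c = solve_poisson(m, 1.0, -6.0, ALL_DIRICHLET, order=2)
        err = np.abs(c.values - [exact_quadratic(x) for x in c.coords]).max()
        assert err <= 1e-10

    def test_p1_second_order_convergence(self):
        errs = []
        for h in (1 / 4, 1 / 8):
            m = box_tet_mesh(h=h)
            c = solve_poisson(m, 1.0, -6.0, ALL_DIRICHLET, order=1)
            V = FunctionSpace(m, 1)
            cq = V.at_quadrature(c.values)
            eq = np.array([[exact_quadratic(x) for x in row] for row in V.xq])
            errs.append(math.sqrt(np.einsum("q,tq,t->", V.qw, (cq - eq) ** 2,
                                            np.abs(V.detJ))))
        order = math.log2(errs[0] / errs[1])
        assert order == pytest.approx(2.0, abs=0.2)

    def test_constant_dirichlet_gives_constant_field(self):
        m = box_tet_mesh(h=0.25)
        c = solve_poisson(m, 1.0, 0.0,
                          {lab: {"dirichlet": 5.0} for lab in range(1, 7)})
        assert np.abs(c.values - 5.0).max() <= 1e-10

    def test_no_dirichlet_rejected(self):
        m = box_tet_mesh(h=0.5)
        with pytest.raises(ValueError, match="Dirichlet"):
            solve_poisson(m, 1.0, 0.0, {})

    def test_hollow_domain_maximum_principle(self):
        """Vessel wall at c=1, outer box at c=0: field stays in [0, 1] and
        decays with distance from the vessel."""
        box = box_surface((-4, -4, -6), (4, 4, 6), n=6, labelled=True)
        ves = capped_cylinder(1.0, -4.0, 4.0, n_theta=24, n_z=16)
        ves = TriSurface(ves.vertices, ves.faces, np.full(ves.n_faces, 9))
        scene = TriSurface(np.vstack([box.vertices, ves.vertices]),
                           np.vstack([box.faces, ves.faces + box.n_vertices]),
                           np.concatenate([box.face_labels, ves.face_labels]))
        m = tetrahedralize(scene, sizing=0.8, holes=[(0, 0, 0)],
                           method="delaunay")
        bc = {9: {"dirichlet": 1.0}}
        bc.update({lab: {"dirichlet": 0.0} for lab in range(1, 7)})
        c = solve_poisson(m, 1.0, 0.0, bc)
        # soft maximum-principle bound: Delaunay meshes are not strictly
        # acute, so tiny over/undershoots are admissible
        assert c.values.min() >= -1e-3 and c.values.max() <= 1 + 1e-3
        r = np.linalg.norm(c.coords[:, :2], axis=1)
        mid = np.abs(c.coords[:, 2]) < 3
        bins = np.linspace(1.2, 4.0, 5)
        means = [c.values[mid & (r >= bins[i]) & (r < bins[i + 1])].mean()
                 for i in range(len(bins) - 1)]
        assert all(means[i] >= means[i + 1] - 1e-9 for i in range(len(means) - 1))


class TestADR:
    def test_reaction_only_decay(self):
        """u = 0, D = 0, g = -c: spatially uniform exponential decay."""
        m = box_tet_mesh(h=0.5)
        out = solve_adr(m, TransportSpec(D=0.0, decay=1.0),
                        SolverConfig(dt=1e-3, T=1.0), c0=1.0)
        c = out[-1].values
        assert c.std() <= 1e-12
        assert c.mean() == pytest.approx(math.exp(-1.0), rel=1e-3)

    def test_closed_boundary_mass_conservation(self):
        m = box_tet_mesh(h=0.125)
        V = FunctionSpace(m, 1)
        blob = np.exp(-100 * np.sum((V.coords - 0.5) ** 2, axis=1))
        M = V.mass_matrix()
        out = solve_adr(m, TransportSpec(D=0.05),
                        SolverConfig(dt=0.01, T=0.2),
                        c0=MeshField(blob, m, V.coords))
        m0 = (M @ blob).sum()
        m1 = (M @ out[-1].values).sum()
        assert abs(m1 - m0) / m0 <= 1e-8

    def test_supg_advection_translates_blob(self):
        box = box_surface((0, 0, 0), (1, 1, 4), n=1, labelled=True)
        m = tetrahedralize(box, sizing=0.125, method="lattice")
        V = FunctionSpace(m, 1)
        blob = np.exp(-np.sum((V.coords - [0.5, 0.5, 1.0]) ** 2, axis=1)
                      / (2 * 0.2 ** 2))
        vel = MeshField(np.tile([0, 0, 1.0], (m.n_nodes, 1)), m, V.coords)
        out = solve_adr(m, TransportSpec(D=1e-4, velocity=vel),
                        SolverConfig(dt=0.02, T=1.0, supg=True),
                        c0=MeshField(blob, m, V.coords))
        M = V.mass_matrix()
        w0, w1 = M @ blob, M @ out[-1].values
        z0 = (V.coords[:, 2] * w0).sum() / w0.sum()
        z1 = (V.coords[:, 2] * w1).sum() / w1.sum()
        assert z1 - z0 == pytest.approx(1.0, abs=0.05)

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            TransportSpec(D=-1.0)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0, T=1.0)


class TestIPCS:
    def test_zero_forcing_zero_flow(self):
        m = box_tet_mesh(h=0.25)
        cfg = SolverConfig(dt=0.01, T=0.05, bc_table={
            1: {"type": "velocity", "value": (0, 0, 0)},
            2: {"type": "pressure", "value": 0.0},
            3: {"type": "noslip"}, 4: {"type": "noslip"},
            5: {"type": "noslip"}, 6: {"type": "noslip"}})
        st = solve_ns_ipcs(m, FluidProperties(1, 1), cfg)[-1]
        assert np.abs(st.u.values).max() == 0.0
        assert np.abs(st.p.values).max() == 0.0

    def test_plane_poiseuille_profile(self):
        """Pressure-driven slab channel: u(y) = dp y (H - y) / (2 mu L)."""
        box = box_surface((0, 0, 0), (1, 1, 0.25), n=1, labelled=True)
        m = tetrahedralize(box, sizing=1 / 12, method="lattice")
        cfg = SolverConfig(dt=0.025, T=2.5, steady_tol=1e-5, bc_table={
            1: {"type": "pressure", "value": 8.0},
            2: {"type": "pressure", "value": 0.0},
            3: {"type": "noslip"}, 4: {"type": "noslip"},
            5: {"type": "velocity_component", "component": 2, "value": 0.0},
            6: {"type": "velocity_component", "component": 2, "value": 0.0}})
        st = solve_ns_ipcs(m, FluidProperties(1, 1), cfg)[-1]
        centre = np.abs(st.u.coords[:, 1] - 0.5) < 1e-9
        peak = st.u.values[centre, 0].mean()
        assert peak == pytest.approx(1.0, rel=0.02)
        # the projection reduces the discrete divergence at every step
        assert all(after <= before for before, after in st.divergence_history)
        fin = boundary_flux(st, m, 1)
        fout = boundary_flux(st, m, 2)
        assert abs(fin + fout) <= 0.02 * abs(fin)

    def test_missing_pressure_outlet_rejected(self):
        m = box_tet_mesh(h=0.5)
        cfg = SolverConfig(dt=0.01, T=0.02,
                           bc_table={1: {"type": "noslip"}})
        with pytest.raises(ValueError, match="pressure"):
            solve_ns_ipcs(m, FluidProperties(), cfg)

    def test_unknown_bc_type_rejected(self):
        m = box_tet_mesh(h=0.5)
        cfg = SolverConfig(dt=0.01, T=0.02,
                           bc_table={1: {"type": "slippery"},
                                     2: {"type": "pressure", "value": 0.0}})
        with pytest.raises(ValueError, match="unknown bc"):
            solve_ns_ipcs(m, FluidProperties(), cfg)


class TestBoundaryFlux:
    def test_closed_diffusion_all_fluxes_vanish(self):
        m = box_tet_mesh(h=0.25)
        c = solve_poisson(m, 1.0, 0.0,
                          {lab: {"dirichlet": 3.0} for lab in range(1, 7)})
        for lab in range(1, 7):
            assert abs(boundary_flux(c, m, lab)) <= 1e-8

    def test_unknown_label_rejected(self, unit_cube_mesh):
        c = solve_poisson(unit_cube_mesh, 1.0, 0.0, {1: {"dirichlet": 0.0}})
        with pytest.raises(KeyError):
            boundary_flux(c, unit_cube_mesh, 42)
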