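import math

import numpy as np
import pytest

from tubeflow.fixtures import box_surface, capped_cylinder
from tubeflow.graph import SpatialGraph
from tubeflow.meshing import (SizingField, boundary_tags, box_tet_mesh,
                              convert_mesh, read_mesh, sizing_field_from_radii,
                              tetrahedralize)
from tubeflow.surface import TriSurface


def merge(*surfs):
    verts, faces, labels, off = [], [], [], 0
    for s in surfs:
        verts.append(s.vertices)
        faces.append(s.faces + off)
        labels.append(s.face_labels if s.face_labels is not None
                      else np.ones(s.n_faces, dtype=int))
        off += s.n_vertices
    return TriSurface(np.vstack(verts), np.vstack(faces), np.concatenate(labels))


def interface_audit(m):
    """(interface facet count, all shared by exactly one tet per region)."""
    faces = np.vstack([m.tets[:, [0, 2, 1]], m.tets[:, [0, 1, 3]],
                       m.tets[:, [0, 3, 2]], m.tets[:, [1, 2, 3]]])
    owner = np.tile(np.arange(m.n_tets), 4)
    key = np.sort(faces, axis=1)
    uniq, inv, cnt = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    order = np.argsort(inv, kind="stable")
    pos = np.searchsorted(inv[order], np.flatnonzero(cnt == 2))
    f1, f2 = order[pos], order[pos + 1]
    r1, r2 = m.region_id[owner[f1]], m.region_id[owner[f2]]
    iface = r1 != r2
    return int(iface.sum()), bool(np.all(r1[iface] != r2[iface]))


class TestSizing:
    def test_two_parallel_tubes(self):
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 10], [14, 0, 0], [14, 0, 10.0]]),
                         np.array([1.0, 1.0, 4.0, 4.0]),
                         np.array([[0, 1], [2, 3]]))
        thin = capped_cylinder(1.0, 0, 10, n_theta=16, n_z=8)
        thick = capped_cylinder(4.0, 0, 10, n_theta=16, n_z=8)
        thick = TriSurface(thick.vertices + [14, 0, 0], thick.faces)
        s = merge(thin, thick)
        f = sizing_field_from_radii(s, g, k=0.5, h_min=1e-6, h_max=10.0)
        on_thin = s.vertices[:, 0] < 7
        assert np.allclose(f.values[on_thin], 0.5)
        assert np.allclose(f.values[~on_thin], 2.0)

    def test_clamped_to_h_min(self, cylinder_surface, straight_segment):
        f = sizing_field_from_radii(cylinder_surface, straight_segment,
                                    k=0.01, h_min=0.5, h_max=1.0)
        assert np.all(f.values == 0.5)

    def test_tapered_vessel_monotone(self):
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 20.0]]),
                         np.array([1.0, 3.0]), np.array([[0, 1]]))
        # sample the radius at several stations along the axis
        n = 40
        g_dense = SpatialGraph(
            np.stack([np.zeros(n), np.zeros(n), np.linspace(0, 20, n)], axis=1),
            np.linspace(1, 3, n), np.stack([np.arange(n - 1),
                                            np.arange(1, n)], axis=1))
        surf = capped_cylinder(1.0, 0, 20, n_theta=16, n_z=30)
        f = sizing_field_from_radii(surf, g_dense, k=0.5, h_min=1e-6, h_max=10)
        order = np.argsort(surf.vertices[:, 2])
        vals = f.values[order]
        z = surf.vertices[order, 2]
        # monotone non-decreasing along z up to sampling ties
        coarse = [vals[(z >= a) & (z < a + 2)].mean() for a in range(0, 20, 2)]
        assert all(coarse[i] <= coarse[i + 1] + 1e-9 for i in range(len(coarse) - 1))

    def test_empty_skeleton_rejected(self, cylinder_surface):
        g = SpatialGraph(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            sizing_field_from_radii(cylinder_surface, g)

    def test_nonpositive_sizing_rejected(self):
        with pytest.raises(ValueError):
            SizingField(np.array([0.5, -0.1]))


class TestTetrahedralize:
    def test_unit_cube_volume_partition_exact(self, unit_cube_mesh):
        m = unit_cube_mesh
        assert np.all(m.tet_volumes() > 0)
        assert m.volume() == pytest.approx(1.0, abs=1e-9)

    def test_cube_boundary_tags(self, unit_cube_mesh):
        tags = boundary_tags(unit_cube_mesh)
        assert sorted(tags) == [1, 2, 3, 4, 5, 6]
        for _, (nf, area) in tags.items():
            assert area == pytest.approx(1.0, abs=1e-9)

    def test_cube_in_cube_conforming(self):
        outer = box_surface((0, 0, 0), (1, 1, 1), n=1, labelled=True)
        inner = box_surface((0.25, 0.25, 0.25), (0.75, 0.75, 0.75), n=1)
        inner = TriSurface(inner.vertices, inner.faces,
                           np.full(inner.n_faces, 7))
        scene = merge(outer, inner)
        m = tetrahedralize(scene, sizing=0.25,
                           regions=[((0.5, 0.5, 0.5), 2), ((0.1, 0.1, 0.1), 1)])
        inner_vol = m.tet_volumes()[m.region_id == 2].sum()
        assert inner_vol == pytest.approx(0.125, rel=0.01)
        n_iface, one_per_region = interface_audit(m)
        assert n_iface > 0 and one_per_region
        # no tet straddles the inner-cube planes
        for t4 in m.nodes[m.tets]:
            c = t4.mean(axis=0)
            for ax in range(3):
                for plane in (0.25, 0.75):
                    other = [a for a in range(3) if a != ax]
                    if np.all((c[other] > 0.25) & (c[other] < 0.75)):
                        assert not ((t4[:, ax] < plane - 1e-9).any()
                                    and (t4[:, ax] > plane + 1e-9).any())

    def test_hollowed_cylinder_in_box(self):
        box = box_surface((-5, -5, -7), (5, 5, 7), n=8, labelled=True)
        cylinder = capped_cylinder(2.0, -5.0, 5.0, n_theta=40, n_z=20)
        cylinder = TriSurface(cylinder.vertices, cylinder.faces,
                              np.full(cylinder.n_faces, 9))
        m = tetrahedralize(merge(box, cylinder), sizing=0.7,
                           holes=[(0, 0, 0)], method="delaunay")
        exact = 10 * 10 * 14 - math.pi * 4 * 10
        assert m.volume() == pytest.approx(exact, rel=0.02)
        # no tets inside the cylinder
        cent = m.nodes[m.tets].mean(axis=1)
        inside = (np.linalg.norm(cent[:, :2], axis=1) < 1.9) & \
                 (np.abs(cent[:, 2]) < 4.9)
        assert not inside.any()

    def test_cylinder_volume_partition(self, cylinder_surface):
        m = tetrahedralize(cylinder_surface, sizing=0.5, method="delaunay")
        assert m.volume() == pytest.approx(cylinder_surface.enclosed_volume(),
                                           rel=0.005)

    def test_refining_sizing_increases_tet_count(self, cylinder_surface):
        coarse = tetrahedralize(cylinder_surface, sizing=1.0, method="delaunay")
        fine = tetrahedralize(cylinder_surface, sizing=0.6, method="delaunay")
        assert fine.n_tets > coarse.n_tets

    def test_non_watertight_shell_rejected(self):
        sheet = TriSurface(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]),
                           np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="watertight"):
            tetrahedralize(sheet, sizing=0.5)

    def test_seed_outside_shell_rejected(self):
        cube = box_surface(n=1, labelled=True)
        with pytest.raises(ValueError, match="outside"):
            tetrahedralize(cube, sizing=0.5, regions=[((5.0, 5, 5), 1)])

    def test_deterministic_given_seed(self, cylinder_surface):
        a = tetrahedralize(cylinder_surface, sizing=0.8, method="delaunay", seed=3)
        b = tetrahedralize(cylinder_surface, sizing=0.8, method="delaunay", seed=3)
        assert np.array_equal(a.tets, b.tets)
        assert np.array_equal(a.nodes, b.nodes)


class TestConversion:
    def test_msh2_header_and_blocks(self, tmp_path, unit_cube_mesh):
        path = tmp_path / "cube.msh"
        convert_mesh(unit_cube_mesh, path)
        text = path.read_text()
        assert "$MeshFormat\n2.2 0 8\n$EndMeshFormat" in text
        assert text.count("$Elements") == 1
        # both triangles (type 2) and tets (type 4) in one block
        lines = text.split("$Elements\n")[1].splitlines()[1:-1]
        types = {int(l.split()[1]) for l in lines}
        assert types == {2, 4}

    def test_msh2_roundtrip_lossless(self, tmp_path, unit_cube_mesh):
        m = unit_cube_mesh
        path = tmp_path / "m.msh"
        convert_mesh(m, path)
        back = read_mesh(path)
        assert np.abs(back.nodes - m.nodes).max() <= 1e-12
        assert np.array_equal(back.tets, m.tets)
        assert np.array_equal(back.region_id, m.region_id)
        assert np.array_equal(back.boundary_labels, m.boundary_labels)

    def test_boundary_triangle_count_in_file(self, tmp_path, unit_cube_mesh):
        path = tmp_path / "m.msh"
        convert_mesh(unit_cube_mesh, path)
        lines = path.read_text().split("$Elements\n")[1].splitlines()[1:-1]
        n_tri = sum(1 for l in lines if int(l.split()[1]) == 2)
        assert n_tri == len(unit_cube_mesh.boundary_faces)

    def test_vtk_and_xdmf_written(self, tmp_path, unit_cube_mesh):
        convert_mesh(unit_cube_mesh, tmp_path / "m.vtk")
        convert_mesh(unit_cube_mesh, tmp_path / "m.xdmf")
        vtk = (tmp_path / "m.vtk").read_text()
        assert "UNSTRUCTURED_GRID" in vtk
        import xml.etree.ElementTree as ET

        root = ET.parse(tmp_path / "m.xdmf").getroot()
        assert root.tag == "Xdmf"

    def test_unknown_format_rejected(self, tmp_path, unit_cube_mesh):
        with pytest.raises(ValueError, match="format"):
            convert_mesh(unit_cube_mesh, tmp_path / "m.foo")


class TestBoundaryTags:
    def test_unlabelled_surface_gets_default_label(self):
        cube = box_surface(n=1)  # no labels
        m = tetrahedralize(cube, sizing=0.5, method="lattice")
        tags = boundary_tags(m)
        assert list(tags) == [1]
        assert tags[1][1] == pytest.approx(6.0, abs=1e-9)

    def test_y_fixture_caps_match_manifest(self, y_reconstruction):
        labelled = y_reconstruction["labelled"]
        manifest = y_reconstruction["manifest"]
        m = tetrahedralize(labelled, sizing=0.35, method="delaunay")
        tags = boundary_tags(m)
        for r in manifest.records:
            if r.kind == "cap":
                assert tags[r.label][1] == pytest.approx(r.area, rel=0.01)
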