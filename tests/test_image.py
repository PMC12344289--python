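import math

import numpy as np
import pytest

from tubeflow.graph import SpatialGraph
from tubeflow.image import (VoxelImage, extract_isosurface,
                            normalized_distance_field, rasterize_graph,
                            read_image, surface_from_labelmap, write_image)
from tubeflow.surface import diagnose, is_watertight


def capsule_volume(r, L):
    return math.pi * r * r * L + 4.0 / 3.0 * math.pi * r ** 3


class TestRasterize:
    def test_capsule_volume_within_5pct(self, straight_segment):
        img = rasterize_graph(straight_segment, spacing=0.5)
        vol = img.values.sum() * 0.5 ** 3
        assert vol == pytest.approx(capsule_volume(2, 10), rel=0.05)

    def test_centreline_voxel_is_foreground(self, straight_segment):
        img = rasterize_graph(straight_segment, spacing=0.5)
        idx = np.round(img.index([0, 0, 5.0])).astype(int)
        assert img.values[tuple(idx)] == 1

    def test_empty_graph_rejected(self):
        g = SpatialGraph(np.zeros((0, 3)), np.zeros(0), np.zeros((0, 2)))
        with pytest.raises(ValueError, match="empty"):
            rasterize_graph(g, 0.5)

    def test_coarse_spacing_warns_not_raises(self, caplog, straight_segment):
        import logging

        with caplog.at_level(logging.WARNING, logger="tubeflow"):
            rasterize_graph(straight_segment, spacing=5.0)
        assert any("diameter" in r.message for r in caplog.records)


class TestNormalizedDistance:
    def test_wall_and_axis_values(self, straight_segment):
        phi = normalized_distance_field(straight_segment, spacing=0.5)
        mid_axis = np.round(phi.index([0, 0, 5.0])).astype(int)
        assert phi.values[tuple(mid_axis)] == pytest.approx(0.0, abs=1e-12)
        on_wall = np.round(phi.index([2.0, 0, 5.0])).astype(int)
        x = phi.world(on_wall)
        expected = np.linalg.norm(x[:2]) / 2.0
        assert phi.values[tuple(on_wall)] == pytest.approx(expected, rel=1e-6)

    def test_varying_radius_against_dense_oracle(self):
        """phi = min |x-p| / r(p): probe against brute-force minimization
        over a densely resampled centreline (step = spacing / 10)."""
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 10.0]]),
                         np.array([1.0, 3.0]), np.array([[0, 1]]))
        spacing = 0.25
        phi = normalized_distance_field(g, spacing)
        pts, rad = g.resample(step=spacing / 10.0)
        rng = np.random.default_rng(3)
        band = np.argwhere(phi.values < 2.0)
        probes = band[rng.choice(len(band), 20, replace=False)]
        for idx in probes:
            x = phi.world(idx)
            oracle = np.min(np.linalg.norm(pts - x, axis=1) / rad)
            assert phi.values[tuple(idx)] == pytest.approx(oracle, rel=0.02, abs=1e-9)

    def test_band_limited_with_sentinel(self, straight_segment):
        phi = normalized_distance_field(straight_segment, spacing=0.5,
                                        dilation_radius=2)
        assert phi.values.max() == pytest.approx(2.0)  # sentinel outside band

    def test_small_dilation_rejected(self, straight_segment):
        with pytest.raises(ValueError, match="dilation"):
            normalized_distance_field(straight_segment, 0.5, dilation_radius=0)

    def test_foreground_phi_bounded_by_one_plus_slack(self, y_graph):
        spacing = 0.25
        binary = rasterize_graph(y_graph, spacing)
        phi = normalized_distance_field(y_graph, spacing)
        # grids share origin/shape by construction for equal padding settings
        fg = rasterize_graph(y_graph, spacing,
                             padding=int(math.ceil(2 * y_graph.radii.max()
                                                   / spacing)) + 2)
        h = spacing / y_graph.radii.min()
        assert phi.values[fg.values.astype(bool)].max() <= 1 + h


class TestIsosurface:
    def test_sphere_distance_field(self):
        """phi = |x - c| / 5: the phi = 1 surface is a radius-5 sphere."""
        n = 36
        ax = np.arange(n) * 0.5
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = ax[n // 2]
        phi = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) / 5.0
        img = VoxelImage(phi, np.full(3, 0.5), np.zeros(3))
        surf = extract_isosurface(img, 1.0)
        d = diagnose(surf)
        assert d.euler_characteristic == 2
        assert d.n_boundary_edges == 0
        assert d.area == pytest.approx(4 * math.pi * 25, rel=0.05)

    def test_level_out_of_range_rejected(self, straight_segment):
        phi = normalized_distance_field(straight_segment, 0.5)
        with pytest.raises(ValueError, match="level"):
            extract_isosurface(phi, 99.0)

    def test_tube_volume_converges_with_spacing(self, straight_segment):
        """Enclosed volume of the phi = 1 tube approaches the capsule volume
        as the voxel size decreases."""
        errs = []
        for spacing in (0.5, 0.25):
            phi = normalized_distance_field(straight_segment, spacing)
            v = extract_isosurface(phi, 1.0).enclosed_volume()
            errs.append(abs(v - capsule_volume(2, 10)))
        assert errs[1] < errs[0]

    def test_levelset_surface_always_watertight(self, y_graph):
        phi = normalized_distance_field(y_graph, 0.3)
        assert is_watertight(extract_isosurface(phi, 1.0))


class TestLabelmap:
    def make_cube_image(self):
        mask = np.zeros((14, 14, 14), np.uint8)
        mask[2:12, 2:12, 2:12] = 1
        return VoxelImage(mask, np.ones(3), np.zeros(3))

    def test_cube_volume_by_divergence_theorem(self):
        surf = surface_from_labelmap(self.make_cube_image(), 1)
        assert surf.enclosed_volume() == pytest.approx(1000, rel=0.05)

    def test_solid_ball_is_genus_zero(self):
        x, y, z = np.mgrid[0:24, 0:24, 0:24]
        ball = (((x - 11.5) ** 2 + (y - 11.5) ** 2 + (z - 11.5) ** 2) <= 81)
        surf = surface_from_labelmap(VoxelImage(ball.astype(np.uint8),
                                                np.ones(3), np.zeros(3)), 1)
        d = diagnose(surf)
        assert d.genus == 0 and d.n_boundary_edges == 0

    def test_two_blobs_give_two_watertight_components(self):
        mask = np.zeros((20, 10, 10), np.uint8)
        mask[2:6, 3:7, 3:7] = 1
        mask[12:16, 3:7, 3:7] = 1
        surf = surface_from_labelmap(VoxelImage(mask, np.ones(3), np.zeros(3)), 1)
        parts = surf.split_components()
        assert len(parts) == 2
        assert all(is_watertight(p) for p in parts)

    def test_absent_label_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            surface_from_labelmap(self.make_cube_image(), 5)


class TestImageIO:
    @pytest.mark.parametrize("name", ["img.tiff", "img.nhdr"])
    def test_roundtrip(self, tmp_path, name):
        img = VoxelImage(np.arange(24, dtype=np.float64).reshape(2, 3, 4),
                         np.array([1.0, 0.5, 0.25]), np.array([1.0, 2.0, 3.0]))
        write_image(img, tmp_path / name)
        back = read_image(tmp_path / name)
        assert np.array_equal(back.values, img.values)
        assert np.allclose(back.spacing, img.spacing)
        assert np.allclose(back.origin, img.origin)
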