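"""Shared fixtures: all geometry is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tubeflow.fixtures import box_surface, capped_cylinder
from tubeflow.graph import SpatialGraph, make_synthetic_tree
from tubeflow.image import (VoxelImage, extract_isosurface,
                            normalized_distance_field, rasterize_graph)
from tubeflow.labelling import slice_and_label
from tubeflow.meshing import box_tet_mesh
from tubeflow.skeleton import (SkeletonParams, distance_map,
                               extend_terminals_raytrace, rebinarize_surface,
                               skeleton_to_graph, skeletonize_binary)
from tubeflow.surface import TriSurface, remesh_isotropic, smooth_hc


@pytest.fixture(scope="session")
def straight_segment() -> SpatialGraph:
    """Two-node vessel: r = 2, length 10 along z."""
    return SpatialGraph(np.array([[0.0, 0, 0], [0, 0, 10.0]]),
                        np.array([2.0, 2.0]), np.array([[0, 1]]))


@pytest.fixture(scope="session")
def y_graph() -> SpatialGraph:
    """One bifurcation: root radius 1, child radius 0.8."""
    return make_synthetic_tree(1, root_radius=1.0, ratio=0.8, branch_length=8.0)


@pytest.fixture(scope="session")
def gen2_tree() -> SpatialGraph:
    return make_synthetic_tree(2, root_radius=1.0, ratio=0.8, branch_length=8.0)


@pytest.fixture(scope="session")
def y_reconstruction(y_graph):
    """Full reconstruction chain on the Y network at fine resolution.

    Level-set surface -> isotropic remesh -> HC smoothing -> re-binarize ->
    thinning skeleton -> ray-traced terminal extension -> slice/seal/label.
    Shared because it is the most expensive fixture (~15 s).
    """
    spacing = 0.12
    phi = normalized_distance_field(y_graph, spacing)
    surf = extract_isosurface(phi, 1.0)
    surf = remesh_isotropic(surf, target_edge_length=0.16, iterations=4)
    surf = smooth_hc(surf, 8)
    binary = rebinarize_surface(surf, spacing)
    g = skeleton_to_graph(skeletonize_binary(binary),
                          SkeletonParams(prune_length=2.0), distance_map(binary))
    g = extend_terminals_raytrace(g, surf)
    labelled, manifest, caps = slice_and_label(surf, g)
    return {"graph": y_graph, "surface": surf, "skeleton": g,
            "labelled": labelled, "manifest": manifest, "caps": caps,
            "spacing": spacing}


@pytest.fixture(scope="session")
def cylinder_surface() -> TriSurface:
    """Capped cylinder r = 2, z in [-10, 10], finely subdivided."""
    return capped_cylinder(2.0, -10.0, 10.0, n_theta=48, n_z=24)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    return box_tet_mesh(h=0.25)


@pytest.fixture(scope="session")
def gen2_voxelization(gen2_tree):
    """Rasterized generations-2 tree + thinning skeleton + graph."""
    spacing = 0.4
    img = rasterize_graph(gen2_tree, spacing)
    skel = skeletonize_binary(img)
    dist = distance_map(img)
    g = skeleton_to_graph(skel, SkeletonParams(prune_length=2.0), dist)
    return {"tree": gen2_tree, "image": img, "skeleton_image": skel,
            "dist": dist, "graph": g, "spacing": spacing}
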