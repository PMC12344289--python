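"""Centreline extraction from binary images.

Thinning-based skeletons (homotopy-preserving 3D medial-axis thinning) are
converted to :class:`~tubeflow.graph.SpatialGraph` networks whose per-node
radii come from the Euclidean distance transform of the original binary
image.  Thinning terminates skeleton branches short of the true vessel end
(the "retraction" effect); ``extend_terminals_raytrace`` elongates each
terminal sub-segment until it hits the reconstructed surface and promotes
the hit point to the new edge point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._geom import ray_hits, points_in_mesh
from .graph import SpatialGraph
from .image import VoxelImage
from .surface import TriSurface

__all__ = [
    "SkeletonParams",
    "skeletonize_binary",
    "distance_map",
    "skeleton_to_graph",
    "extend_terminals_raytrace",
    "rebinarize_surface",
    "resample_isotropic",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SkeletonParams:
    """Skeleton post-processing parameters (world length units).

    ``prune_length``: side branches hanging off a junction shorter than this
    are removed.  ``filter_length``: isolated skeleton components with total
    length below this are dropped.  ``resolution``: isotropic voxel size the
    binary image is resampled to before thinning (0 keeps the native grid).
    """

    prune_length: float = 0.0
    filter_length: float = 0.0
    resolution: float = 0.0

    def __post_init__(self) -> None:
        if self.prune_length < 0 or self.filter_length < 0 or self.resolution < 0:
            raise ValueError("skeleton parameters must be >= 0")


# -- simple-point machinery (26-connected object, 6-connected background) --

def _build_simple_tables():
    """Adjacency tables over the 3x3x3 neighbourhood for topology tests."""
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    centre = offs.index((0, 0, 0))
    n26 = [i for i in range(27) if i != centre]
    adj26 = [[] for _ in range(27)]
    for a in n26:
        for b in n26:
            if a == b:
                continue
            d = [abs(offs[a][t] - offs[b][t]) for t in range(3)]
            if max(d) <= 1:
                adj26[a].append(b)
    n18 = [i for i in n26 if sum(abs(t) for t in offs[i]) <= 2]
    adj6_18 = [[] for _ in range(27)]
    for a in n18:
        for b in n18:
            if a == b:
                continue
            d = [offs[a][t] - offs[b][t] for t in range(3)]
            if sum(abs(t) for t in d) == 1:
                adj6_18[a].append(b)
    face6 = [i for i in n26 if sum(abs(t) for t in offs[i]) == 1]
    return offs, centre, n26, adj26, n18, adj6_18, face6


_OFFS, _CENTRE, _N26, _ADJ26, _N18, _ADJ6_18, _FACE6 = _build_simple_tables()


def _is_simple(nb: np.ndarray) -> bool:
    """Simple-point test on a flat 27-bool neighbourhood (centre = object).

    Deleting the centre preserves topology iff the object neighbours form
    exactly one 26-component and the background 6-neighbours of the centre
    lie in exactly one 6-component of the background within the
    18-neighbourhood (Malandain-Bertrand characterization).
    """
    # object components in N26
    obj = [i for i in _N26 if nb[i]]
    if not obj:
        return False  # isolated voxel
    seen = {obj[0]}
    stack = [obj[0]]
    while stack:
        u = stack.pop()
        for w in _ADJ26[u]:
            if nb[w] and w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(obj):
        return False
    # background 6-components in N18 touching a face neighbour
    bg_faces = [i for i in _FACE6 if not nb[i]]
    if not bg_faces:
        return False  # interior point
    seen_b = {bg_faces[0]}
    stack = [bg_faces[0]]
    while stack:
        u = stack.pop()
        for w in _ADJ6_18[u]:
            if not nb[w] and w not in seen_b:
                seen_b.add(w)
                stack.append(w)
    return all(f in seen_b for f in bg_faces)


def skeletonize_binary(img: VoxelImage) -> VoxelImage:
    """1-voxel-wide homotopic curve skeleton of a binary image.

    Sequential thinning: border voxels are deleted in order of increasing
    Euclidean distance transform (so the skeleton centres on the medial
    axis) whenever they are simple points and not curve endpoints.  Simple
    point deletions preserve connected components and tunnels by
    construction, so the foreground's Betti numbers are invariant.
    """
    mask = img.values.astype(bool)
    if not mask.any():
        raise ValueError("empty foreground")
    m = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(m)
    shape = m.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    noff = np.array([o @ strides for o in _OFFS])
    flat = m.ravel()
    changed = True
    while changed:
        changed = False
        border = m & ~ndimage.binary_erosion(m)
        cand = np.flatnonzero(border.ravel())
        if not len(cand):
            break
        order = np.argsort(edt.ravel()[cand], kind="stable")
        for v in cand[order]:
            if not flat[v]:
                continue
            nb = flat[v + noff]
            n_obj = int(nb.sum()) - 1  # minus centre
            if n_obj <= 1:
                continue  # endpoint or isolated: anchor
            if _is_simple(nb):
                flat[v] = False
                changed = True
    return VoxelImage(m[1:-1, 1:-1, 1:-1].astype(np.uint8), img.spacing, img.origin)


def distance_map(img: VoxelImage) -> VoxelImage:
    """Euclidean distance transform of the foreground, in world units."""
    edt = ndimage.distance_transform_edt(img.values.astype(bool),
                                         sampling=tuple(img.spacing))
    return VoxelImage(edt, img.spacing, img.origin)


def resample_isotropic(img: VoxelImage, resolution: float) -> VoxelImage:
    """Nearest-neighbour resample of a binary image to an isotropic voxel size."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    zoom = img.spacing / resolution
    vals = ndimage.zoom(img.values.astype(np.uint8), zoom, order=0)
    return VoxelImage(vals, np.full(3, resolution), img.origin)


def rebinarize_surface(s: TriSurface, resolution: float, padding: int = 2) -> VoxelImage:
    """Rasterize a watertight surface to a binary image.

    Voxel centres strictly inside the mesh (even-odd parity test) become
    foreground; used to re-binarize the remeshed/smoothed surface before
    skeletonization, since smoothing has moved the wall off the original
    voxel grid.
    """
    lo = s.vertices.min(axis=0) - padding * resolution
    hi = s.vertices.max(axis=0) + padding * resolution
    shape = np.ceil((hi - lo) / resolution).astype(int) + 1
    idx = np.indices(shape).reshape(3, -1).T
    centres = lo + idx * resolution
    inside = points_in_mesh(s.vertices, s.faces, centres)
    vals = inside.reshape(tuple(shape)).astype(np.uint8)
    return VoxelImage(vals, np.full(3, resolution), lo)


# ---------------------------------------------------------------------------
# Skeleton image -> graph
# ---------------------------------------------------------------------------

def _neighbour_lists(coords: np.ndarray):
    """26-neighbourhood adjacency among skeleton voxels."""
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                nbrs[i].append(j)
    return nbrs


def skeleton_to_graph(skel: VoxelImage, params: SkeletonParams | None = None,
                      dist: VoxelImage | None = None) -> SpatialGraph:
    """Convert a thinning skeleton into a spatial graph with radii.

    Nodes sit at junction clusters and endpoints; edges follow 26-connected
    voxel paths (kept as ``edge_paths``).  Per-node radius is the distance
    transform value at the node voxel.  Branches shorter than
    ``prune_length`` hanging off junctions are removed, then isolated
    components whose total length is below ``filter_length`` are dropped.
    """
    params = params or SkeletonParams()
    if dist is not None and dist.values.shape != skel.values.shape:
        raise ValueError("skeleton / distance image shape mismatch")
    coords = np.argwhere(skel.values.astype(bool))
    if not len(coords):
        raise ValueError("empty skeleton")
    nbrs = _neighbour_lists(coords)
    deg = np.array([len(n) for n in nbrs])
    spacing = skel.spacing

    def radius_at(v: int) -> float:
        if dist is None:
            return float(max(spacing.min(), 1e-12))
        c = coords[v]
        return float(max(dist.values[c[0], c[1], c[2]], 0.25 * spacing.min()))

    # node voxels: endpoints (deg 1), junctions (deg >= 3); junction voxels
    # that touch each other are merged into one node per 26-connected cluster
    is_junction = deg >= 3
    is_end = deg == 1
    cluster_of = -np.ones(len(coords), dtype=int)
    clusters: list[list[int]] = []
    for v in np.flatnonzero(is_junction):
        if cluster_of[v] >= 0:
            continue
        stack = [v]
        cluster_of[v] = len(clusters)
        members = [v]
        while stack:
            u = stack.pop()
            for w in nbrs[u]:
                if is_junction[w] and cluster_of[w] < 0:
                    cluster_of[w] = len(clusters)
                    members.append(w)
                    stack.append(w)
        clusters.append(members)

    node_of_voxel: dict[int, int] = {}
    node_voxels: list[int] = []  # representative voxel per node
    for members in clusters:
        rep = members[int(np.argmin([len(nbrs[m]) for m in members]))]
        # representative = cluster voxel closest to the cluster centroid
        cen = coords[members].mean(axis=0)
        rep = members[int(np.argmin(np.linalg.norm(coords[members] - cen, axis=1)))]
        nid = len(node_voxels)
        node_voxels.append(rep)
        for m in members:
            node_of_voxel[m] = nid
    for v in np.flatnonzero(is_end):
        node_of_voxel[v] = len(node_voxels)
        node_voxels.append(v)
    isolated = np.flatnonzero(deg == 0)
    for v in isolated:
        node_of_voxel[v] = len(node_voxels)
        node_voxels.append(v)

    # walk paths between node voxels through degree-2 chains
    visited_edges: set[tuple[int, int]] = set()
    raw_edges: list[tuple[int, int, list[int]]] = []  # (node_a, node_b, voxel path)
    for v, nid in list(node_of_voxel.items()):
        for w in nbrs[v]:
            if (v, w) in visited_edges:
                continue
            path = [v, w]
            visited_edges.add((v, w))
            prev, cur = v, w
            while cur not in node_of_voxel:
                nxt = [x for x in nbrs[cur] if x != prev]
                if not nxt:
                    break  # dead end without endpoint flag (shouldn't happen)
                # prefer continuing through non-node voxels
                nxt.sort(key=lambda x: x in node_of_voxel)
                step = nxt[0]
                path.append(step)
                visited_edges.add((cur, step))
                prev, cur = cur, step
            if cur in node_of_voxel:
                visited_edges.add((cur, prev))
                nb = node_of_voxel[cur]
                if nb == nid and len(path) <= 2:
                    continue  # internal cluster adjacency
                raw_edges.append((nid, nb, path))

    # leftover pure cycles (all degree 2): break each into 3 arcs
    left = set(range(len(coords))) - set().union(
        *[set(p) for _, _, p in raw_edges]) if raw_edges else set(range(len(coords)))
    left -= set(node_of_voxel)
    while left:
        start = min(left)
        ring = [start]
        prev, cur = start, nbrs[start][0]
        while cur != start:
            ring.append(cur)
            nxt = [x for x in nbrs[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
        left -= set(ring)
        if len(ring) < 3:
            continue
        thirds = [0, len(ring) // 3, 2 * len(ring) // 3]
        ids = []
        for t in thirds:
            node_of_voxel[ring[t]] = len(node_voxels)
            node_voxels.append(ring[t])
            ids.append(node_of_voxel[ring[t]])
        raw_edges.append((ids[0], ids[1], ring[thirds[0]:thirds[1] + 1]))
        raw_edges.append((ids[1], ids[2], ring[thirds[1]:thirds[2] + 1]))
        raw_edges.append((ids[2], ids[0], ring[thirds[2]:] + ring[:1]))

    # deduplicate (paths discovered from both ends)
    seen: set[tuple[int, int, int]] = set()
    edges = []
    for a, b, path in raw_edges:
        key = (min(a, b), max(a, b), len(path), min(path))
        if key in seen:
            continue
        seen.add(key)
        if a == b:
            # self-loop (ring through one junction): break into three arcs
            if len(path) < 4:
                continue
            t1, t2 = len(path) // 3, 2 * len(path) // 3
            for t in (t1, t2):
                node_of_voxel[path[t]] = len(node_voxels)
                node_voxels.append(path[t])
            n1, n2 = node_of_voxel[path[t1]], node_of_voxel[path[t2]]
            edges.append((a, n1, path[:t1 + 1]))
            edges.append((n1, n2, path[t1:t2 + 1]))
            edges.append((n2, b, path[t2:]))
        else:
            edges.append((a, b, path))

    def path_length(path: list[int]) -> float:
        pts = coords[path] * spacing
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) if len(path) > 1 else 0.0

    # prune short branches hanging off junctions
    if params.prune_length > 0:
        changed = True
        while changed:
            changed = False
            ndeg: dict[int, int] = {}
            for a, b, _ in edges:
                ndeg[a] = ndeg.get(a, 0) + 1
                ndeg[b] = ndeg.get(b, 0) + 1
            keep = []
            for a, b, path in edges:
                la = ndeg.get(a, 0) == 1
                lb = ndeg.get(b, 0) == 1
                if (la != lb) and path_length(path) < params.prune_length \
                        and ndeg.get(a if la else b, 0) == 1 and ndeg.get(b if la else a, 0) >= 3:
                    changed = True
                    continue
                keep.append((a, b, path))
            edges = keep

    # drop small isolated components by total length
    if params.filter_length > 0 and edges:
        parent = {}

        def find(x):
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        for a, b, _ in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comp_len: dict[int, float] = {}
        for a, b, path in edges:
            comp_len[find(a)] = comp_len.get(find(a), 0.0) + path_length(path)
        edges = [(a, b, p) for a, b, p in edges
                 if comp_len[find(a)] >= params.filter_length]

    if not edges:
        if len(isolated):
            world = skel.origin + coords * spacing
            nv = [node_voxels[node_of_voxel[v]] for v in isolated]
            return SpatialGraph(world[nv], np.array([radius_at(v) for v in nv]),
                                np.zeros((0, 2), dtype=int))
        raise ValueError("no skeleton branches left after pruning/filtering")

    # merge degree-2 nodes left by pruning into through-paths
    edges = _simplify_degree2(edges)

    used_nodes = sorted({a for a, _, _ in edges} | {b for _, b, _ in edges})
    remap = {n: i for i, n in enumerate(used_nodes)}
    world = skel.origin + coords * spacing
    nodes = np.array([world[node_voxels[n]] for n in used_nodes])
    radii = np.array([radius_at(node_voxels[n]) for n in used_nodes])
    eidx = np.array([[remap[a], remap[b]] for a, b, _ in edges], dtype=int)
    paths = [world[np.asarray(p)] for _, _, p in edges]
    # duplicate edges between the same node pair (tight loops) -> keep longest
    key = np.sort(eidx, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    if len(first) != len(eidx):
        keep = sorted(first)
        eidx = eidx[keep]
        paths = [paths[i] for i in keep]
    return SpatialGraph(nodes, radii, eidx, edge_paths=paths)


def _simplify_degree2(edges):
    """Merge chains around degree-2 nodes created by pruning.

    Merges are skipped when they would create a self-loop or a duplicate
    node pair, so short cycles (e.g. a ring skeleton broken into arcs) keep
    their arc structure.
    """
    while True:
        ndeg: dict[int, list[int]] = {}
        for i, (a, b, _) in enumerate(edges):
            ndeg.setdefault(a, []).append(i)
            ndeg.setdefault(b, []).append(i)
        pairs = {(min(a, b), max(a, b)) for a, b, _ in edges}
        merged_any = False
        for target, el in ndeg.items():
            if len(el) != 2 or el[0] == el[1]:
                continue
            i1, i2 = el
            a1, b1, p1 = edges[i1]
            a2, b2, p2 = edges[i2]
            q1 = list(p1) if b1 == target else list(p1)[::-1]
            s1 = a1 if b1 == target else b1
            q2 = list(p2) if a2 == target else list(p2)[::-1]
            s2 = b2 if a2 == target else a2
            if s1 == s2 or (min(s1, s2), max(s1, s2)) in pairs:
                continue
            merged = (s1, s2, q1 + q2[1:])
            edges = [e for j, e in enumerate(edges) if j not in (i1, i2)] + [merged]
            merged_any = True
            break
        if not merged_any:
            return edges


# ---------------------------------------------------------------------------
# Terminal extension by ray tracing
# ---------------------------------------------------------------------------

def extend_terminals_raytrace(g: SpatialGraph, s: TriSurface) -> SpatialGraph:
    """Elongate every terminal sub-segment until it meets the surface.

    For each degree-1 node, a ray from the penultimate point through the
    terminal is intersected with the surface; the first hit at or beyond the
    terminal becomes the new terminal position (radius inherited).  Only
    degree-1 nodes move.
    """
    nodes = g.nodes.copy()
    paths = None
    if g.edge_paths is not None:
        paths = [None if p is None else np.asarray(p, dtype=float).copy()
                 for p in g.edge_paths]
    from .graph import terminal_direction

    deg = g.degrees()
    for t in np.flatnonzero(deg == 1):
        (eidx,) = np.where((g.edges == t).any(axis=1))
        e = int(eidx[0])
        a, b = g.edges[e]
        d = terminal_direction(g, t, lookback=2.0 * float(g.radii[t]))
        if d is None:
            continue
        term = nodes[t]
        # cast from slightly inside so a terminal already on the surface
        # still registers a (zero-length) extension
        delta = 0.5 * float(g.radii[t])
        origin = term - d * delta
        ts, _ = ray_hits(s.vertices, s.faces, origin, d)
        beyond = ts[ts >= delta - 1e-9]
        if not len(beyond):
            raise ValueError(f"terminal {t}: extension ray misses the surface")
        hit = origin + d * float(beyond[0])
        nodes[t] = hit
        # the hit point joins the skeleton as the new edge point; the old
        # terminal voxel stays as an interior path point
        if paths is not None and paths[e] is not None:
            if np.linalg.norm(hit - term) < 1e-12:
                continue
            if b == t:
                paths[e] = np.vstack([paths[e], hit])
            else:
                paths[e] = np.vstack([hit, paths[e]])
    return SpatialGraph(nodes, g.radii.copy(), g.edges.copy(), edge_paths=paths)
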