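"""Spatial graph networks: centrelines with per-node radii.

A :class:`SpatialGraph` is the common currency between the reconstruction,
skeletonization, labelling and 1D-solver stages: a set of 3D node positions,
a positive radius per node, and edges between node indices.  Edges may carry
an optional polyline (``edge_paths``) for curved segments; endpoints of the
polyline coincide with the node positions.

I/O is plain text: a pair of CSV tables (nodes: ``id,x,y,z,radius``; edges:
``id_a,id_b``) or a legacy-VTK POLYDATA file with LINES cells and a point-data
``radius`` array.  Units are caller-defined and never converted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpatialGraph",
    "GraphSummary",
    "read_graph",
    "write_graph",
    "make_synthetic_tree",
    "summarize",
]


@dataclass
class SpatialGraph:
    """Centreline network with per-node radii.

    Parameters
    ----------
    nodes : (N, 3) float array
        World coordinates of the nodes.
    radii : (N,) float array
        Positive radius at each node (same length units as ``nodes``).
    edges : (E, 2) int array
        Pairs of node indices; no self-loops, no duplicate (unordered) pairs.
    edge_paths : list of (M_i, 3) arrays, optional
        Ordered polyline per edge, including both endpoint coordinates.
    """

    nodes: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    edge_paths: list | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.nodes)
        if len(self.radii) != n:
            raise ValueError("radii length must match node count")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("non-finite node coordinates")
        if n and not np.all(np.isfinite(self.radii)):
            raise ValueError("non-finite radii")
        if n and np.any(self.radii <= 0):
            raise ValueError("all radii must be > 0")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop edge")
            key = np.sort(self.edges, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise ValueError("duplicate edge")
        if self.edge_paths is not None and len(self.edge_paths) != len(self.edges):
            raise ValueError("edge_paths length must match edge count")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.edges.size:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def terminal_nodes(self) -> np.ndarray:
        """Indices of degree-1 nodes."""
        return np.flatnonzero(self.degrees() == 1)

    def edge_lengths(self) -> np.ndarray:
        """Per-edge length: polyline length when a path exists, else chord."""
        if self.n_edges == 0:
            return np.zeros(0)
        out = np.empty(self.n_edges)
        for i, (a, b) in enumerate(self.edges):
            if self.edge_paths is not None and self.edge_paths[i] is not None:
                p = np.asarray(self.edge_paths[i])
                out[i] = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            else:
                out[i] = np.linalg.norm(self.nodes[a] - self.nodes[b])
        return out

    def resample(self, step: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample points densely along every edge.

        Returns ``(points, radii)`` where the centreline (polyline if present,
        chord otherwise) of each edge is sampled at spacing ``<= step`` and the
        radius is linearly interpolated between the endpoint node radii by
        arclength.
        """
        pts, rad = [], []
        for i, (a, b) in enumerate(self.edges):
            if self.edge_paths is not None and self.edge_paths[i] is not None:
                poly = np.asarray(self.edge_paths[i], dtype=float)
            else:
                poly = np.vstack([self.nodes[a], self.nodes[b]])
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            L = seg.sum()
            if L == 0:
                pts.append(poly[:1])
                rad.append([self.radii[a]])
                continue
            s = np.concatenate([[0.0], np.cumsum(seg)])
            n = max(2, int(math.ceil(L / step)) + 1)
            t = np.linspace(0.0, L, n)
            x = np.stack([np.interp(t, s, poly[:, k]) for k in range(3)], axis=1)
            r = self.radii[a] + (self.radii[b] - self.radii[a]) * (t / L)
            pts.append(x)
            rad.append(r)
        if not pts:
            return np.zeros((0, 3)), np.zeros(0)
        return np.vstack(pts), np.concatenate(rad)


def terminal_direction(g: SpatialGraph, t: int, lookback: float) -> np.ndarray | None:
    """Outward direction of the terminal sub-segment at node ``t``.

    The direction is taken from the path point about ``lookback`` arclength
    behind the terminal, which filters the voxel-step quantization of
    thinning skeletons (a single voxel step can be ~19 degrees off-axis).
    Returns a unit vector, or None for a degenerate (zero-length) segment.
    """
    (eidx,) = np.where((g.edges == t).any(axis=1))
    e = int(eidx[0])
    a, b = g.edges[e]
    if g.edge_paths is not None and g.edge_paths[e] is not None and len(g.edge_paths[e]) > 2:
        poly = np.asarray(g.edge_paths[e], dtype=float)
        poly = poly if b == t else poly[::-1]
        rev = poly[::-1]  # terminal first
        seg = np.linalg.norm(np.diff(rev, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])  # arclength from terminal
        k = int(np.searchsorted(s, lookback))
        k = min(max(k, 1), len(poly) - 1)
        back = rev[k]
    else:
        back = g.nodes[a if b == t else b]
    d = g.nodes[t] - back
    n = np.linalg.norm(d)
    return None if n == 0 else d / n


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    n_terminals: int
    n_bifurcations: int
    total_length: float
    radius_min: float
    radius_max: float


def summarize(g: SpatialGraph) -> GraphSummary:
    """Counts, total centreline length and radius range of a network."""
    deg = g.degrees()
    return GraphSummary(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        n_terminals=int(np.sum(deg == 1)),
        n_bifurcations=int(np.sum(deg >= 3)),
        total_length=float(g.edge_lengths().sum()),
        radius_min=float(g.radii.min()) if g.n_nodes else math.nan,
        radius_max=float(g.radii.max()) if g.n_nodes else math.nan,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def make_synthetic_tree(
    generations: int,
    root_radius: float = 1.0,
    ratio: float = 0.8,
    branch_length: float = 8.0,
    branch_angle: float = 40.0,
    seed: int = 0,
) -> SpatialGraph:
    """Deterministic binary branching tree.

    The root segment points along +z; each junction spawns two children
    deviating by ``+-branch_angle`` degrees in a plane whose azimuth rotates
    by a golden-angle increment per generation (plus a small seeded jitter so
    that distinct seeds give distinct but reproducible trees).  Child radius
    and length shrink by ``ratio`` per generation, emulating the wide
    diameter range of airway/vascular trees at desk scale.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [np.zeros(3)]
    radii = [root_radius]
    edges: list[tuple[int, int]] = []

    def grow(parent: int, direction: np.ndarray, length: float, radius: float, gen: int) -> None:
        tip = nodes[parent] + direction * length
        nodes.append(tip)
        radii.append(radius)
        tip_i = len(nodes) - 1
        edges.append((parent, tip_i))
        if gen >= generations:
            return
        # orthonormal frame around the branch direction
        a = np.array([1.0, 0.0, 0.0])
        if abs(direction @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(direction, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        az = 2.399963 * gen + rng.uniform(-0.2, 0.2)
        u = math.cos(az) * e1 + math.sin(az) * e2
        th = math.radians(branch_angle)
        for sign in (+1.0, -1.0):
            d = math.cos(th) * direction + sign * math.sin(th) * u
            d /= np.linalg.norm(d)
            grow(tip_i, d, length * ratio, radius * ratio, gen + 1)

    grow(0, np.array([0.0, 0.0, 1.0]), branch_length, root_radius, 0)
    return SpatialGraph(np.array(nodes), np.array(radii), np.array(edges))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _edge_table_path(path: Path) -> Path:
    return path.with_name(path.stem + "_edges" + path.suffix)


def read_graph(path, format: str = None, default_radius: float | None = None) -> SpatialGraph:
    """Read a spatial graph from CSV tables or a legacy-VTK polyline file.

    ``format`` is inferred from the extension when omitted (.csv / .vtk).
    CSV input is the node table ``id,x,y,z,radius``; the edge table
    ``id_a,id_b`` is looked up at ``<stem>_edges.csv`` next to it.  A missing
    radius column is an error unless ``default_radius`` is given.
    """
    path = Path(path)
    if format is None:
        format = "vtk-polyline" if path.suffix.lower() == ".vtk" else "csv"
    if format == "csv":
        return _read_csv(path, default_radius)
    if format == "vtk-polyline":
        return _read_vtk_polyline(path, default_radius)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(g: SpatialGraph, path, format: str = None) -> None:
    path = Path(path)
    if format is None:
        format = "vtk-polyline" if path.suffix.lower() == ".vtk" else "csv"
    if format == "csv":
        _write_csv(g, path)
    elif format == "vtk-polyline":
        _write_vtk_polyline(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def _read_csv(path: Path, default_radius: float | None) -> SpatialGraph:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    ids, nodes, radii = [], [], []
    for row in rows:
        ids.append(int(row["id"]))
        nodes.append([float(row["x"]), float(row["y"]), float(row["z"])])
        if "radius" in row and row["radius"] not in (None, ""):
            radii.append(float(row["radius"]))
        elif default_radius is not None:
            radii.append(float(default_radius))
        else:
            raise ValueError(f"{path}: missing radius and no default supplied")
    order = {nid: i for i, nid in enumerate(ids)}
    epath = _edge_table_path(path)
    edges = []
    if epath.exists():
        with open(epath, newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append([order[int(row["id_a"])], order[int(row["id_b"])]])
    return SpatialGraph(np.array(nodes, dtype=float).reshape(-1, 3),
                        np.array(radii, dtype=float),
                        np.array(edges, dtype=int).reshape(-1, 2))


def _write_csv(g: SpatialGraph, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "z", "radius"])
        for i, (p, r) in enumerate(zip(g.nodes, g.radii)):
            w.writerow([i, repr(float(p[0])), repr(float(p[1])), repr(float(p[2])), repr(float(r))])
    with open(_edge_table_path(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b"])
        for a, b in g.edges:
            w.writerow([int(a), int(b)])


def _write_vtk_polyline(g: SpatialGraph, path: Path) -> None:
    # Node points first, then interior polyline points, so every cell's first
    # and last point index is a graph node.
    pts = [p for p in g.nodes]
    rad = [r for r in g.radii]
    cells = []
    for i, (a, b) in enumerate(g.edges):
        if g.edge_paths is not None and g.edge_paths[i] is not None:
            poly = np.asarray(g.edge_paths[i], dtype=float)
            interior = poly[1:-1]
            idx = [int(a)]
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            L = seg.sum()
            s = np.concatenate([[0.0], np.cumsum(seg)])
            for j, q in enumerate(interior):
                pts.append(q)
                t = s[j + 1] / L if L > 0 else 0.0
                rad.append(g.radii[a] + (g.radii[b] - g.radii[a]) * t)
                idx.append(len(pts) - 1)
            idx.append(int(b))
        else:
            idx = [int(a), int(b)]
        cells.append(idx)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspatial graph\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        total = sum(len(c) + 1 for c in cells)
        fh.write(f"LINES {len(cells)} {total}\n")
        for c in cells:
            fh.write(" ".join(map(str, [len(c), *c])) + "\n")
        fh.write(f"POINT_DATA {len(pts)}\nSCALARS radius double 1\nLOOKUP_TABLE default\n")
        for r in rad:
            fh.write(f"{float(r)!r}\n")


def _read_vtk_polyline(path: Path, default_radius: float | None) -> SpatialGraph:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        for i, t in enumerate(tokens):
            if t == word:
                return i
        return -1
    ip = find("POINTS")
    if ip < 0:
        raise ValueError(f"{path}: no POINTS block")
    npts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3:ip + 3 + 3 * npts], dtype=float).reshape(npts, 3)
    il = find("LINES")
    cells = []
    if il >= 0:
        ncells = int(tokens[il + 1])
        k = il + 3
        for _ in range(ncells):
            m = int(tokens[k])
            cells.append([int(t) for t in tokens[k + 1:k + 1 + m]])
            k += m + 1
    ir = find("radius")
    if ir >= 0:
        # SCALARS radius double 1 / LOOKUP_TABLE default / values...
        k = ir
        while tokens[k] != "LOOKUP_TABLE":
            k += 1
        radius = np.array(tokens[k + 2:k + 2 + npts], dtype=float)
    elif default_radius is not None:
        radius = np.full(npts, float(default_radius))
    else:
        raise ValueError(f"{path}: no radius array and no default supplied")
    # nodes are the endpoints of the line cells
    node_ids = sorted({c[0] for c in cells} | {c[-1] for c in cells}) if cells else list(range(npts))
    remap = {nid: i for i, nid in enumerate(node_ids)}
    edges, paths = [], []
    has_path = False
    for c in cells:
        edges.append([remap[c[0]], remap[c[-1]]])
        if len(c) > 2:
            has_path = True
            paths.append(coords[np.array(c)])
        else:
            paths.append(None)
    return SpatialGraph(
        coords[node_ids] if node_ids else coords,
        radius[node_ids] if node_ids else radius,
        np.array(edges, dtype=int).reshape(-1, 2),
        edge_paths=paths if has_path else None,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
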