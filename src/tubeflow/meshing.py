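"""Tetrahedral meshing and mesh format conversion.

Two complementary meshing strategies sit behind :func:`tetrahedralize`:

* ``delaunay`` — Delaunay triangulation of the shell vertices plus graded
  interior points, filtered by an even-odd containment test per closed
  shell.  Shell vertices enter the node set unperturbed, so cavity and
  exterior boundaries pass exactly through the input surface vertices (the
  property the 3D-1D coupling relies on).
* ``lattice`` — a rectilinear grid whose planes are snapped to axis-aligned
  shell faces, split into six tetrahedra per cell (Freudenthal).  Volumes
  of box domains are partitioned exactly and multi-domain interfaces on
  axis-aligned planes are conforming with no straddling elements.

Element size is driven by a radius-dependent :class:`SizingField` on the
surface (``h = clamp(k * r_nearest_skeleton_node, h_min, h_max)``), so small
vessels are finely resolved while large ones stay coarse.

Conversion targets are Gmsh MSH v2 ASCII (physical groups = boundary labels
and region ids), legacy VTK unstructured grids and ASCII XDMF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from ._geom import MeshProximity, points_in_mesh
from .graph import SpatialGraph
from .surface import TriSurface, is_watertight

__all__ = [
    "SizingField",
    "TetMesh",
    "sizing_field_from_radii",
    "tetrahedralize",
    "box_tet_mesh",
    "convert_mesh",
    "read_mesh",
    "boundary_tags",
]


@dataclass
class SizingField:
    """Per-surface-vertex target edge length (length units, > 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if np.any(self.values <= 0):
            raise ValueError("sizing values must be > 0")


@dataclass
class TetMesh:
    """Tetrahedral mesh with region attributes and labelled boundary faces."""

    nodes: np.ndarray
    tets: np.ndarray
    region_id: np.ndarray
    boundary_faces: np.ndarray
    boundary_labels: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        self.region_id = np.asarray(self.region_id, dtype=int).reshape(-1)
        self.boundary_faces = np.asarray(self.boundary_faces, dtype=int).reshape(-1, 3)
        self.boundary_labels = np.asarray(self.boundary_labels, dtype=int).reshape(-1)
        if len(self.region_id) != len(self.tets):
            raise ValueError("region_id length must match tet count")
        if len(self.boundary_labels) != len(self.boundary_faces):
            raise ValueError("boundary label/face mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                         np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0

    def boundary_areas(self) -> np.ndarray:
        p = self.nodes[self.boundary_faces]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def volume(self) -> float:
        return float(self.tet_volumes().sum())


# ---------------------------------------------------------------------------
# Sizing
# ---------------------------------------------------------------------------

def sizing_field_from_radii(s: TriSurface, g: SpatialGraph, k: float = 0.5,
                            h_min: float = 1e-6, h_max: float = math.inf) -> SizingField:
    """Radius-driven target edge length per surface vertex.

    ``h(v) = clamp(k * r(nearest skeleton node to v), h_min, h_max)`` with
    the nearest node by Euclidean distance.
    """
    if g.n_nodes == 0:
        raise ValueError("empty skeleton")
    tree = cKDTree(g.nodes)
    _, j = tree.query(s.vertices, workers=-1)
    return SizingField(np.clip(k * g.radii[j], h_min, h_max))


# ---------------------------------------------------------------------------
# Tetrahedralization
# ---------------------------------------------------------------------------

def _orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    vol = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                    np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    flip = vol < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def _signatures(shells, points: np.ndarray) -> np.ndarray:
    """(N, n_shells) bool: inside test per closed shell."""
    sig = np.zeros((len(points), len(shells)), dtype=bool)
    for i, sh in enumerate(shells):
        lo, hi = sh.vertices.min(axis=0), sh.vertices.max(axis=0)
        inbox = np.all((points >= lo - 1e-12) & (points <= hi + 1e-12), axis=1)
        if inbox.any():
            sig[inbox, i] = points_in_mesh(sh.vertices, sh.faces, points[inbox])
    return sig


def _interior_points_graded(shells, sig_keep, h_surface: np.ndarray,
                            surf_pts: np.ndarray, lo, hi, rng) -> np.ndarray:
    """Graded interior lattice: octave levels between min and max sizing."""
    tree = cKDTree(surf_pts)
    hmin = float(h_surface.min())
    hmax = float(h_surface.max())
    levels = [hmin]
    while levels[-1] * 2.0 < hmax * 0.999:
        levels.append(levels[-1] * 2.0)
    pts = []
    for j, h in enumerate(levels):
        ax = [np.arange(lo[k] + 0.5 * h, hi[k], h) for k in range(3)]
        if any(len(a) == 0 for a in ax):
            continue
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        d, nn = tree.query(grid, workers=-1)
        hloc = h_surface[nn]
        top = j == len(levels) - 1
        band = (hloc >= h * 0.999) if top else ((hloc >= h * 0.999) & (hloc < 2.0 * h))
        grid = grid[band]
        d = d[band]
        hl = hloc[band]
        # clearance from the surfaces so Delaunay keeps shell vertices on
        # the boundary; d is a lower bound via surface vertices
        grid = grid[d > 0.7 * hl]
        hl = hl[d > 0.7 * hl]
        if len(grid):
            grid = grid + rng.uniform(-0.12, 0.12, grid.shape) * hl[:, None]
            pts.append(grid)
    if not pts:
        return np.zeros((0, 3))
    return np.vstack(pts)


def tetrahedralize(
    s: TriSurface,
    sizing: SizingField | float | None = None,
    regions: list | None = None,
    holes: list | None = None,
    quality: float = 1.6,
    method: str = "auto",
    seed: int = 0,
) -> TetMesh:
    """Fill the volume bounded by labelled watertight shells with tetrahedra.

    ``s`` may contain several closed shells (nested for multi-domain or
    cavity meshing).  ``regions`` is a list of ``(seed_point, region_id)``;
    ``holes`` a list of points inside cavities to be left empty.  ``sizing``
    is a uniform edge length, or a :class:`SizingField` on the surface
    vertices; omitted, it defaults to the mean input edge length.  The
    ``quality`` radius-edge bound is advisory: point spacing is chosen to
    keep Delaunay element quality near it, but no Steiner refinement is
    performed.  Boundary and interface faces inherit the label of the
    nearest input face.
    """
    shells = s.split_components()
    for sh in shells:
        if not is_watertight(sh):
            raise ValueError("every shell must be watertight")
    if isinstance(sizing, SizingField):
        h_surface = sizing.values
        if len(h_surface) != s.n_vertices:
            raise ValueError("sizing field length must match surface vertices")
    else:
        h = float(sizing) if sizing is not None else s.mean_edge_length()
        h_surface = np.full(s.n_vertices, h)

    regions = list(regions or [])
    holes = [np.asarray(p, dtype=float) for p in (holes or [])]
    if method == "auto":
        method = "lattice" if _all_boxes(shells) else "delaunay"
    if method == "lattice":
        mesh = _tetra_lattice(s, shells, float(np.median(h_surface)), regions, holes)
    elif method == "delaunay":
        mesh = _tetra_delaunay(s, shells, h_surface, regions, holes, seed)
    else:
        raise ValueError(f"unknown meshing method {method!r}")
    return mesh


def _all_boxes(shells) -> bool:
    for sh in shells:
        for k in range(3):
            if len(np.unique(np.round(sh.vertices[:, k], 9))) != 2:
                return False
    return True


def _region_of(sig_row, region_sigs, hole_sigs, default_id):
    t = tuple(sig_row)
    if t in hole_sigs:
        return None
    if t in region_sigs:
        return region_sigs[t]
    if not any(sig_row):
        return None  # outside everything
    return default_id


def _classify(shells, centroids, regions, holes):
    sig = _signatures(shells, centroids)
    region_sigs = {}
    if regions:
        seed_sig = _signatures(shells, np.asarray([p for p, _ in regions]))
        for (p, rid), row in zip(regions, seed_sig):
            if not any(row):
                raise ValueError(f"region seed {p} lies outside every shell")
            region_sigs[tuple(row)] = int(rid)
    hole_sigs = set()
    if holes:
        hole_sig = _signatures(shells, np.asarray(holes))
        for p, row in zip(holes, hole_sig):
            if not any(row):
                raise ValueError(f"hole seed {p} lies outside every shell")
            hole_sigs.add(tuple(row))
    default_id = 1 if not regions else None
    out = np.full(len(centroids), -10**9, dtype=object)
    ids = np.empty(len(centroids), dtype=float)
    for i in range(len(centroids)):
        r = _region_of(sig[i], region_sigs, hole_sigs, default_id)
        ids[i] = np.nan if r is None else r
    return ids


def _boundary_from_tets(nodes, tets, region_id, input_surface: TriSurface):
    """Exterior + interface facets with labels from the nearest input face."""
    faces = np.vstack([tets[:, [0, 2, 1]], tets[:, [0, 1, 3]],
                       tets[:, [0, 3, 2]], tets[:, [1, 2, 3]]])
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                  return_counts=True)
    boundary = []
    # exterior: facet used once
    once = counts == 1
    idx_once = np.flatnonzero(once[inv])
    boundary.extend(idx_once.tolist())
    # interface: facet used twice by tets of different regions (report once)
    twice = np.flatnonzero(counts == 2)
    order = np.argsort(inv, kind="stable")
    pos = np.searchsorted(inv[order], twice)
    f1 = order[pos]
    f2 = order[pos + 1]
    diff = region_id[owner[f1]] != region_id[owner[f2]]
    boundary.extend(f1[diff].tolist())
    bidx = np.asarray(boundary, dtype=int)
    bfaces = faces[bidx]
    # orient exterior faces outward relative to their owner tet
    own = owner[bidx]
    cent_t = nodes[tets[own]].mean(axis=1)
    p = nodes[bfaces]
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    inward = np.einsum("ij,ij->i", nrm, cent_t - p.mean(axis=1)) > 0
    bfaces[inward] = bfaces[inward][:, [0, 2, 1]]
    # labels from the geometrically nearest input face
    labels = np.ones(len(bfaces), dtype=int)
    if input_surface.face_labels is not None and len(input_surface.faces):
        prox = MeshProximity(input_surface.vertices, input_surface.faces)
        _, _, j = prox.query(nodes[bfaces].mean(axis=1))
        labels = input_surface.face_labels[j].astype(int)
    return bfaces, labels


def _tetra_delaunay(s, shells, h_surface, regions, holes, seed) -> TetMesh:
    rng = np.random.default_rng(seed)
    lo = s.vertices.min(axis=0)
    hi = s.vertices.max(axis=0)
    interior = _interior_points_graded(shells, None, h_surface, s.vertices, lo, hi, rng)
    if len(interior):
        # drop candidate points that are outside every shell or in a hole
        ids = _classify(shells, interior, regions, holes)
        interior = interior[~np.isnan(ids)]
    nodes = np.vstack([s.vertices, interior]) if len(interior) else s.vertices.copy()
    tri = Delaunay(nodes)
    tets = _orient_tets(nodes, np.asarray(tri.simplices, dtype=int))
    vols = np.einsum("ij,ij->i", nodes[tets[:, 1]] - nodes[tets[:, 0]],
                     np.cross(nodes[tets[:, 2]] - nodes[tets[:, 0]],
                              nodes[tets[:, 3]] - nodes[tets[:, 0]])) / 6.0
    scale = float(np.linalg.norm(hi - lo))
    tets = tets[vols > 1e-14 * scale ** 3]
    cent = nodes[tets].mean(axis=1)
    ids = _classify(shells, cent, regions, holes)
    keep = ~np.isnan(ids)
    tets = tets[keep]
    region_id = ids[keep].astype(int)
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes2 = nodes[used]
    tets2 = remap[tets]
    bfaces, blabels = _boundary_from_tets(nodes2, tets2, region_id, s)
    return TetMesh(nodes2, tets2, region_id, bfaces, blabels)


_FREUDENTHAL = np.array([
    [0, 1, 3, 7], [0, 1, 7, 5], [0, 5, 7, 4],
    [0, 3, 2, 7], [0, 2, 6, 7], [0, 6, 4, 7],
])


def _tetra_lattice(s, shells, h, regions, holes) -> TetMesh:
    lo = s.vertices.min(axis=0)
    hi = s.vertices.max(axis=0)
    axes = []
    for k in range(3):
        base = list(np.linspace(lo[k], hi[k], max(2, int(round((hi[k] - lo[k]) / h)) + 1)))
        # snap in axis-aligned shell planes (box faces)
        planes = set()
        for sh in shells:
            u = np.unique(np.round(sh.vertices[:, k], 9))
            if len(u) == 2:
                planes.update(u.tolist())
        coords = np.asarray(sorted(set(np.round(base, 9)) | planes))
        # drop near-duplicates
        keep = [coords[0]]
        for c in coords[1:]:
            if c - keep[-1] > 1e-6 * max(h, 1.0):
                keep.append(c)
        axes.append(np.asarray(keep))
    nx, ny, nz = (len(a) for a in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    I, J, K = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = np.stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I, J + 1, K), nid(I + 1, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I, J + 1, K + 1),
        nid(I + 1, J + 1, K + 1)], axis=1)
    tets = corner[:, _FREUDENTHAL].reshape(-1, 4)
    tets = _orient_tets(nodes, tets)
    cent = nodes[tets].mean(axis=1)
    ids = _classify(shells, cent, regions, holes)
    keep = ~np.isnan(ids)
    tets = tets[keep]
    region_id = ids[keep].astype(int)
    if not len(tets):
        raise ValueError("no elements inside the domain at this resolution")
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes2 = nodes[used]
    tets2 = remap[tets]
    bfaces, blabels = _boundary_from_tets(nodes2, tets2, region_id, s)
    return TetMesh(nodes2, tets2, region_id, bfaces, blabels)


def box_tet_mesh(lo=(0, 0, 0), hi=(1, 1, 1), h: float = 0.25) -> TetMesh:
    """Structured box mesh with side labels 1..6 (-x,+x,-y,+y,-z,+z)."""
    from .fixtures import box_surface

    surf = box_surface(lo, hi, n=1, labelled=True)
    return tetrahedralize(surf, sizing=h, method="lattice")


# ---------------------------------------------------------------------------
# Conversion: MSH v2 ASCII, legacy VTK, ASCII XDMF
# ---------------------------------------------------------------------------

def convert_mesh(m: TetMesh, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".msh": "msh2-ascii", ".vtk": "vtk", ".xdmf": "xdmf"}.get(
            path.suffix.lower())
    if format == "msh2-ascii":
        _write_msh2(m, path)
    elif format == "vtk":
        _write_vtk(m, path)
    elif format == "xdmf":
        _write_xdmf(m, path)
    else:
        raise ValueError(f"unknown mesh format {format!r}")


def read_mesh(path) -> TetMesh:
    path = Path(path)
    if path.suffix.lower() != ".msh":
        raise ValueError("only MSH v2 ASCII reading is supported")
    return _read_msh2(path)


def _write_msh2(m: TetMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{m.n_nodes}\n")
        for i, p in enumerate(m.nodes, start=1):
            fh.write(f"{i} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write("$EndNodes\n")
        ne = len(m.boundary_faces) + m.n_tets
        fh.write(f"$Elements\n{ne}\n")
        eid = 1
        for f, lab in zip(m.boundary_faces, m.boundary_labels):
            fh.write(f"{eid} 2 2 {int(lab)} {int(lab)} "
                     f"{f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
            eid += 1
        for t, rid in zip(m.tets, m.region_id):
            fh.write(f"{eid} 4 2 {int(rid)} {int(rid)} "
                     f"{t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


def _read_msh2(path) -> TetMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def seek(tag):
        nonlocal i
        while lines[i].strip() != tag:
            i += 1
        i += 1

    seek("$MeshFormat")
    if not lines[i].startswith("2.2"):
        raise ValueError("not a MSH v2 ASCII file")
    seek("$Nodes")
    n = int(lines[i])
    i += 1
    nodes = np.empty((n, 3))
    for r in range(n):
        t = lines[i + r].split()
        nodes[r] = [float(t[1]), float(t[2]), float(t[3])]
    i += n
    seek("$Elements")
    ne = int(lines[i])
    i += 1
    tris, tlabs, tets, rids = [], [], [], []
    for r in range(ne):
        t = lines[i + r].split()
        etype = int(t[1])
        ntags = int(t[2])
        tags = [int(x) for x in t[3:3 + ntags]]
        conn = [int(x) - 1 for x in t[3 + ntags:]]
        if etype == 2:
            tris.append(conn)
            tlabs.append(tags[0] if tags else 1)
        elif etype == 4:
            tets.append(conn)
            rids.append(tags[0] if tags else 1)
    return TetMesh(nodes, np.asarray(tets, dtype=int),
                   np.asarray(rids, dtype=int),
                   np.asarray(tris, dtype=int).reshape(-1, 3),
                   np.asarray(tlabs, dtype=int))


def _write_vtk(m: TetMesh, path, point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntubeflow mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {m.n_nodes} double\n")
        for p in m.nodes:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"CELLS {m.n_tets} {5 * m.n_tets}\n")
        for t in m.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {m.n_tets}\n")
        fh.write("10\n" * m.n_tets)
        fh.write(f"CELL_DATA {m.n_tets}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        for r in m.region_id:
            fh.write(f"{int(r)}\n")
        if point_data:
            fh.write(f"POINT_DATA {m.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{float(v)!r}\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")


def write_vtk_fields(m: TetMesh, path, point_data: dict) -> None:
    """Legacy-VTK export of nodal fields on a tet mesh (visualization)."""
    _write_vtk(m, path, point_data=point_data)


def _write_xdmf(m: TetMesh, path) -> None:
    path = Path(path)
    geom = "\n".join(" ".join(repr(float(x)) for x in p) for p in m.nodes)
    topo = "\n".join(" ".join(str(int(x)) for x in t) for t in m.tets)
    rid = "\n".join(str(int(r)) for r in m.region_id)
    xml = f"""<?xml version="1.0" ?>
<Xdmf Version="3.0">
  <Domain>
    <Grid Name="mesh" GridType="Uniform">
      <Topology TopologyType="Tetrahedron" NumberOfElements="{m.n_tets}">
        <DataItem Dimensions="{m.n_tets} 4" Format="XML">
{topo}
        </DataItem>
      </Topology>
      <Geometry GeometryType="XYZ">
        <DataItem Dimensions="{m.n_nodes} 3" Format="XML">
{geom}
        </DataItem>
      </Geometry>
      <Attribute Name="region" Center="Cell" AttributeType="Scalar">
        <DataItem Dimensions="{m.n_tets}" Format="XML">
{rid}
        </DataItem>
      </Attribute>
    </Grid>
  </Domain>
</Xdmf>
"""
    path.write_text(xml)


# ---------------------------------------------------------------------------
# Boundary bookkeeping
# ---------------------------------------------------------------------------

def boundary_tags(m: TetMesh) -> dict[int, tuple[int, float]]:
    """Per-label boundary face count and total area."""
    areas = m.boundary_areas()
    out: dict[int, tuple[int, float]] = {}
    for lab in np.unique(m.boundary_labels):
        sel = m.boundary_labels == lab
        out[int(lab)] = (int(sel.sum()), float(areas[sel].sum()))
    return out
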