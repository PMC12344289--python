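"""Terminal slicing, cap sealing and boundary labelling.

To impose inlet/outlet conditions the tubular surface must end in flat,
well-triangulated cross-sections.  Each terminal branch is sliced by a plane
through a skeleton edge point with the terminal sub-segment direction as its
normal; only the connected patch of faces nearest the edge point is affected
so the infinite plane cannot clip unrelated branches.  The openings are then
sealed with planar Delaunay caps, every cap gets a distinct integer label
(the wall is label 1), and a plain-text boundary-condition manifest records
label, kind, centroid, outward normal and area per surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import SpatialGraph, terminal_direction
from .surface import TriSurface, boundary_edges, _boundary_loops, is_watertight

__all__ = [
    "SlicePlane",
    "BCRecord",
    "BCManifest",
    "terminal_slice_planes",
    "slice_terminal",
    "seal_openings",
    "label_surfaces",
    "write_bc_manifest",
    "read_bc_manifest",
    "slice_and_label",
]

WALL_LABEL = 1


@dataclass
class SlicePlane:
    """Slicing plane: skeleton edge point + outward terminal direction."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("zero normal")
        self.normal = n / norm


@dataclass
class BCRecord:
    label: int
    kind: str  # "wall" | "cap"
    centroid: np.ndarray
    normal: np.ndarray | None
    area: float
    condition: str = ""


@dataclass
class BCManifest:
    records: list = field(default_factory=list)

    def validate(self) -> None:
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in manifest")
        for r in self.records:
            if r.kind == "cap" and r.normal is not None:
                if abs(np.linalg.norm(r.normal) - 1.0) > 1e-9:
                    raise ValueError(f"cap {r.label}: normal not unit length")

    def by_label(self, label: int) -> BCRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Slice planes from a skeleton
# ---------------------------------------------------------------------------

def terminal_slice_planes(g: SpatialGraph, pullback: float = 1.0) -> list[SlicePlane]:
    """One slicing plane per terminal node of the skeleton.

    The plane passes through the (ray-traced) terminal edge point pulled
    back inward along the terminal direction by ``pullback`` local radii, so
    caps sit on a cylindrical rather than flared section.  The normal points
    outward (towards the terminal).
    """
    planes = []
    deg = g.degrees()
    for t in np.flatnonzero(deg == 1):
        d = terminal_direction(g, t, lookback=2.0 * float(g.radii[t]))
        if d is None:
            continue
        planes.append(SlicePlane(g.nodes[t] - d * pullback * g.radii[t], d))
    return planes


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------

def _face_components(faces: np.ndarray, subset: np.ndarray) -> np.ndarray:
    """Connected-component label per face of ``subset`` (edge adjacency)."""
    sub = faces[subset]
    e = {}
    comp = -np.ones(len(subset), dtype=int)
    for i, f in enumerate(sub):
        for k in range(3):
            a, b = f[k], f[(k + 1) % 3]
            e.setdefault((min(a, b), max(a, b)), []).append(i)
    adj = [[] for _ in range(len(sub))]
    for fl in e.values():
        for i in fl:
            for j in fl:
                if i != j:
                    adj[i].append(j)
    c = 0
    for i in range(len(sub)):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if comp[w] < 0:
                    comp[w] = c
                    stack.append(w)
        c += 1
    return comp


def slice_terminal(s: TriSurface, plane: SlicePlane, g: SpatialGraph | None = None,
                   local_radii: float = 3.0) -> TriSurface:
    """Cut one terminal branch with a plane, leaving a planar boundary loop.

    Only the connected patch of faces within ``local_radii`` local radii of
    the plane point is considered (the Boolean locality constraint), so the
    infinite plane cannot affect distant branches.  Faces of the patch
    strictly beyond the plane (signed distance > 0 along the normal) are
    removed; crossing triangles are split so the new boundary lies exactly
    in the plane.  An orientation guard rejects planes whose normal points
    into the vessel (which would remove the long side).
    """
    if g is not None:
        r_local = float(g.radii[np.argmin(np.linalg.norm(g.nodes - plane.point, axis=1))])
    else:
        r_local = float(np.linalg.norm(np.ptp(s.vertices, axis=0))) * 0.05
    rad = local_radii * r_local
    cent = s.face_centroids()
    near = np.flatnonzero(np.linalg.norm(cent - plane.point, axis=1) <= rad)
    if not len(near):
        raise ValueError("plane does not intersect the local branch")
    comp = _face_components(s.faces, near)
    nearest = int(np.argmin(np.linalg.norm(cent[near] - plane.point, axis=1)))
    patch = near[comp == comp[nearest]]

    sd = (s.vertices - plane.point) @ plane.normal
    # snap vertices essentially on the plane
    tol = 1e-9 * float(np.linalg.norm(np.ptp(s.vertices, axis=0)))
    snap = np.abs(sd) < tol
    verts = s.vertices.copy()
    verts[snap] -= sd[snap, None] * plane.normal
    sd[snap] = 0.0

    patch_set = set(patch.tolist())
    side = sd[s.faces]  # (F, 3)
    remove = np.zeros(s.n_faces, dtype=bool)
    crossing = []
    for f in patch:
        fs = side[f]
        if np.all(fs >= 0) and np.any(fs > 0):
            remove[f] = True
        elif np.any(fs > 0) and np.any(fs < 0):
            crossing.append(f)
    if not crossing and not remove.any():
        raise ValueError("plane does not intersect the local branch")

    # orientation guard: the sliced-off stub must be the minor part of the patch
    areas = s.face_areas()
    cut_area = areas[remove].sum() + 0.5 * areas[crossing].sum() if len(crossing) \
        else areas[remove].sum()
    patch_area = areas[patch].sum()
    if cut_area > 0.6 * patch_area:
        raise ValueError("slice normal appears to point inward (would remove "
                         "the long side of the branch); flip the normal")

    new_verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def cut_point(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            t = sd[a] / (sd[a] - sd[b])
            p = verts[a] + t * (verts[b] - verts[a])
            p -= ((p - plane.point) @ plane.normal) * plane.normal
            new_verts.append(p)
            cache[key] = len(new_verts) - 1
        return cache[key]

    new_faces = []
    labels = [] if s.face_labels is not None else None
    crossing_set = set(crossing)
    for f in range(s.n_faces):
        if remove[f] or f in crossing_set:
            continue
        new_faces.append(list(s.faces[f]))
        if labels is not None:
            labels.append(s.face_labels[f])
    for f in crossing_set:
        tri = list(s.faces[f])
        dd = [sd[v] for v in tri]
        neg = [i for i in range(3) if dd[i] < 0]
        pos = [i for i in range(3) if dd[i] > 0]
        zer = [i for i in range(3) if dd[i] == 0]
        lab = s.face_labels[f] if s.face_labels is not None else None
        if len(neg) == 1 and len(pos) == 2:
            i = neg[0]
            a, b, c = tri[i], tri[(i + 1) % 3], tri[(i + 2) % 3]
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            new_faces.append([a, pab, pca])
            if labels is not None:
                labels.append(lab)
        elif len(neg) == 2 and len(pos) == 1:
            i = pos[0]
            a, b, c = tri[i], tri[(i + 1) % 3], tri[(i + 2) % 3]
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            new_faces.append([pab, b, c])
            new_faces.append([pab, c, pca])
            if labels is not None:
                labels.extend([lab, lab])
        else:  # one vertex on the plane, others split
            i = zer[0]
            a, b, c = tri[i], tri[(i + 1) % 3], tri[(i + 2) % 3]
            if sd[b] > 0:
                b, c = c, b
                pbc = cut_point(c, b)
                new_faces.append([a, pbc, b])
            else:
                pbc = cut_point(b, c)
                new_faces.append([a, b, pbc])
            if labels is not None:
                labels.append(lab)
    out = TriSurface(np.asarray(new_verts), np.asarray(new_faces, dtype=int),
                     None if labels is None else np.asarray(labels, dtype=int))
    # every *new* boundary edge must lie in the slicing plane; off-plane
    # boundary means the removed side was not a closed stub (normal points
    # into the vessel, or the plane missed the branch)
    pre_boundary = {(min(a, b), max(a, b)) for a, b in boundary_edges(s.faces)}
    for a, b in boundary_edges(out.faces):
        if (min(a, b), max(a, b)) in pre_boundary:
            continue
        d = max(abs((out.vertices[a] - plane.point) @ plane.normal),
                abs((out.vertices[b] - plane.point) @ plane.normal))
        if d > max(tol, 1e-9):
            raise ValueError("slice removed an unbounded region (normal likely "
                             "points inward); flip the normal")
    return out


# ---------------------------------------------------------------------------
# Sealing
# ---------------------------------------------------------------------------

def seal_openings(s: TriSurface, planarity_tol: float = 1e-6):
    """Seal every planar boundary loop with a graded flat cap.

    Each loop is filled with concentric rings of Steiner points shrinking
    towards the loop centroid, connected by triangle strips and a centre
    fan.  The ring count is chosen so cap triangle sizes match the rim edge
    length; the construction is watertight by design for the star-shaped
    cross-sections produced by terminal slicing.  Returns
    ``(watertight surface, list of cap face-index arrays)``.
    """
    if is_watertight(s):
        return TriSurface(s.vertices.copy(), s.faces.copy(), s.face_labels), []
    loops = _boundary_loops(s.faces)
    verts = [s.vertices]
    nv = s.n_vertices
    all_faces = list(map(list, s.faces))
    caps = []
    scale = float(np.linalg.norm(np.ptp(s.vertices, axis=0)))
    for loop in loops:
        P = s.vertices[loop]
        centroid = P.mean(axis=0)
        # fit plane by SVD; check planarity
        U, S, Vt = np.linalg.svd(P - centroid)
        nrm = Vt[2]
        dev = np.abs((P - centroid) @ nrm).max()
        if dev > max(planarity_tol * max(scale, 1.0), 1e-12):
            raise ValueError(f"boundary loop is not planar (deviation {dev:.3g})")
        n = len(loop)
        rim_len = np.linalg.norm(np.diff(np.vstack([P, P[:1]]), axis=0), axis=1)
        ell = float(rim_len.mean())
        rmean = float(np.linalg.norm(P - centroid, axis=1).mean())
        K = max(1, int(round(rmean / max(ell, 1e-300))))
        rings = [list(loop)]
        for k in range(1, K):
            sfac = (K - k) / K
            ring_pts = centroid + sfac * (P - centroid)
            rings.append(list(range(nv, nv + n)))
            verts.append(ring_pts)
            nv += n
        centre = nv
        verts.append(centroid[None])
        nv += 1
        cap_faces = []
        for k in range(K - 1):
            outer, inner = rings[k], rings[k + 1]
            for i in range(n):
                j = (i + 1) % n
                cap_faces.append([outer[j], outer[i], inner[i]])
                cap_faces.append([outer[j], inner[i], inner[j]])
        last = rings[-1]
        for i in range(n):
            j = (i + 1) % n
            cap_faces.append([last[j], last[i], centre])
        start = len(all_faces)
        all_faces.extend(cap_faces)
        caps.append(np.arange(start, start + len(cap_faces)))
    labels = None
    if s.face_labels is not None:
        labels = np.concatenate([s.face_labels,
                                 np.zeros(len(all_faces) - s.n_faces, dtype=int)])
    out = TriSurface(np.vstack(verts), np.asarray(all_faces, dtype=int), labels)
    if not is_watertight(out):
        raise ValueError("sealing failed to restore watertightness")
    return out, caps


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------

def label_surfaces(s: TriSurface, caps: list) -> tuple[TriSurface, BCManifest]:
    """Assign label 1 to the wall and 2..K+1 to caps (deterministic order).

    Caps are sorted by centroid lexicographically so labels are stable
    across runs; the manifest records centroid, outward unit normal and
    area per cap plus one wall record.
    """
    seen: set[int] = set()
    for c in caps:
        cs = set(np.asarray(c).tolist())
        if seen & cs:
            raise ValueError("overlapping cap face sets")
        seen |= cs
    labels = np.full(s.n_faces, WALL_LABEL, dtype=int)
    areas = s.face_areas()
    normals = s.face_normals()
    cents = s.face_centroids()

    def cap_centroid(c):
        a = areas[c]
        return (cents[c] * a[:, None]).sum(axis=0) / a.sum()

    order = sorted(range(len(caps)),
                   key=lambda i: tuple(np.round(cap_centroid(caps[i]), 9)))
    records = []
    wall_faces = np.setdiff1d(np.arange(s.n_faces), np.concatenate(
        [np.asarray(c) for c in caps]) if caps else np.zeros(0, dtype=int))
    wa = areas[wall_faces]
    wall_centroid = (cents[wall_faces] * wa[:, None]).sum(axis=0) / wa.sum() \
        if len(wall_faces) else np.zeros(3)
    records.append(BCRecord(WALL_LABEL, "wall", wall_centroid, None, float(wa.sum())))
    for k, i in enumerate(order):
        c = np.asarray(caps[i])
        labels[c] = k + 2
        n = normals[c].sum(axis=0)
        n = n / np.linalg.norm(n)
        records.append(BCRecord(k + 2, "cap", cap_centroid(c), n, float(areas[c].sum())))
    m = BCManifest(records)
    m.validate()
    return TriSurface(s.vertices.copy(), s.faces.copy(), labels), m


def assign_conditions(m: BCManifest, rule: str = "largest_area_inlet",
                      wall_condition: str = "noslip") -> BCManifest:
    """Fill free-text condition descriptors (largest-area cap = inlet)."""
    caps = [r for r in m.records if r.kind == "cap"]
    inlet = max(caps, key=lambda r: r.area) if caps else None
    for r in m.records:
        if r.kind == "wall":
            r.condition = wall_condition
        elif r is inlet:
            r.condition = "inlet"
        else:
            r.condition = "outlet"
    return m


def slice_and_label(s: TriSurface, g: SpatialGraph, pullback: float = 1.0):
    """Slice every terminal, seal, label: returns (surface, manifest, caps)."""
    cur = s
    for plane in terminal_slice_planes(g, pullback=pullback):
        cur = slice_terminal(cur, plane, g)
    sealed, caps = seal_openings(cur)
    labelled, manifest = label_surfaces(sealed, caps)
    return labelled, assign_conditions(manifest), caps


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def write_bc_manifest(m: BCManifest, path) -> None:
    """One whitespace-separated record per line:
    label kind cx cy cz nx ny nz area condition"""
    m.validate()
    with open(path, "w") as fh:
        fh.write("# label kind cx cy cz nx ny nz area condition\n")
        for r in m.records:
            n = r.normal if r.normal is not None else (math.nan,) * 3
            fh.write(f"{r.label} {r.kind} "
                     f"{float(r.centroid[0])!r} {float(r.centroid[1])!r} {float(r.centroid[2])!r} "
                     f"{float(n[0])!r} {float(n[1])!r} {float(n[2])!r} "
                     f"{float(r.area)!r} {r.condition or '-'}\n")


def read_bc_manifest(path) -> BCManifest:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t = line.split()
            normal = np.array([float(t[5]), float(t[6]), float(t[7])])
            records.append(BCRecord(
                label=int(t[0]), kind=t[1],
                centroid=np.array([float(t[2]), float(t[3]), float(t[4])]),
                normal=None if math.isnan(normal[0]) else normal,
                area=float(t[8]),
                condition="" if t[9] == "-" else " ".join(t[9:])))
    m = BCManifest(records)
    m.validate()
    return m
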