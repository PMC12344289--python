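"""Low-level geometric queries on triangle meshes.

Self-contained vectorized implementations of the three spatial queries the
pipeline needs — ray casting (Moller-Trumbore), point-in-mesh parity tests
and closest-point-on-surface — backed by numpy and a cKDTree / 2D-bin
prefilter.  Inputs are raw (vertices, faces) arrays so both TriSurface and
trimesh objects can use them.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ray_hits", "points_in_mesh", "closest_points"]


def ray_hits(vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray,
             direction: np.ndarray, eps: float = 1e-12):
    """All intersections of one ray with a triangle soup.

    Returns ``(t, face_index)`` arrays sorted by the positive ray parameter
    ``t`` (watertight-ish Moller-Trumbore, brute force over faces).
    """
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    d = np.asarray(direction, dtype=float)
    o = np.asarray(origin, dtype=float)
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = o - v0
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = np.einsum("j,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > eps)
    idx = np.flatnonzero(hit)
    order = np.argsort(t[idx])
    return t[idx][order], idx[order]


def _bin_faces_2d(vertices, faces, cell):
    """Map 2D grid cells (in xy) to the face indices overlapping them."""
    tri = vertices[faces][:, :, :2]
    lo = np.floor(tri.min(axis=1) / cell).astype(int)
    hi = np.floor(tri.max(axis=1) / cell).astype(int)
    bins: dict[tuple[int, int], list[int]] = {}
    for f in range(len(faces)):
        for i in range(lo[f, 0], hi[f, 0] + 1):
            for j in range(lo[f, 1], hi[f, 1] + 1):
                bins.setdefault((i, j), []).append(f)
    return bins


def points_in_mesh(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Parity (even-odd) containment test for many points.

    Casts a +z ray from every point and counts crossings.  Query xy
    coordinates are nudged by an irrational sub-tolerance offset so rays do
    not pass exactly through mesh edges or vertices.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    if len(faces) == 0:
        return np.zeros(len(points), dtype=bool)
    scale = float(np.ptp(vertices, axis=0).max())
    jitter = np.array([scale * 1.618033988749895e-9, scale * 2.23606797749979e-9])
    tri_all = vertices[faces]
    # bin faces on a 2D grid sized to the median triangle extent
    ext = np.median(np.ptp(tri_all[:, :, :2], axis=1)) or scale / 64
    cell = max(ext * 2.0, scale * 1e-6)
    bins = _bin_faces_2d(vertices, faces, cell)
    xy = points[:, :2] + jitter
    keys = np.floor(xy / cell).astype(int)
    inside = np.zeros(len(points), dtype=bool)
    # group queries by bin so each candidate set is fetched once
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    ks = keys[order]
    breaks = np.flatnonzero(np.any(np.diff(ks, axis=0) != 0, axis=1)) + 1
    groups = np.split(order, breaks)
    for grp in groups:
        key = (int(keys[grp[0], 0]), int(keys[grp[0], 1]))
        cand = bins.get(key)
        if not cand:
            continue
        tri = tri_all[cand]  # (F,3,3)
        px = xy[grp, 0][:, None]
        py = xy[grp, 1][:, None]
        x = tri[:, :, 0][None]
        y = tri[:, :, 1][None]
        z = tri[:, :, 2]
        # 2D point-in-triangle via signed areas, vectorized (P, F)
        x0, x1, x2 = x[:, :, 0], x[:, :, 1], x[:, :, 2]
        y0, y1, y2 = y[:, :, 0], y[:, :, 1], y[:, :, 2]
        d0 = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
        d1 = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        d2 = (x0 - x2) * (py - y2) - (y0 - y2) * (px - x2)
        inxy = ((d0 >= 0) & (d1 >= 0) & (d2 >= 0)) | ((d0 <= 0) & (d1 <= 0) & (d2 <= 0))
        # z of the supporting plane at (px, py)
        area2 = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
        area2 = np.where(np.abs(area2) < 1e-300, 1e-300, area2)
        w0 = ((x1 - px) * (y2 - py) - (y1 - py) * (x2 - px)) / area2
        w1 = ((x2 - px) * (y0 - py) - (y2 - py) * (x0 - px)) / area2
        w2 = 1.0 - w0 - w1
        zp = w0 * z[None, :, 0] + w1 * z[None, :, 1] + w2 * z[None, :, 2]
        crossings = (inxy & (zp > points[grp, 2][:, None])).sum(axis=1)
        inside[grp] = (crossings % 2) == 1
    return inside


def _point_triangle_closest(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for paired (N,3) points / (N,3,3) tris."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class MeshProximity:
    """Closest-point queries against a fixed triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        self.tri = self.vertices[self.faces]
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        # triangle circumradius bound: max centroid-to-vertex distance
        self.rad = np.linalg.norm(self.tri - self.centroids[:, None], axis=2).max(axis=1)
        self.rmax = float(self.rad.max()) if len(self.rad) else 0.0

    def query(self, points: np.ndarray, k: int = 8):
        """Closest surface points: returns (closest, distance, face_index)."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        k = min(k, len(self.faces))
        d, j = self.tree.query(points, k=k, workers=-1)
        if k == 1:
            d, j = d[:, None], j[:, None]
        # exact distances to the k candidate triangles
        P = np.repeat(points, k, axis=0)
        T = self.tri[j.ravel()]
        cp = _point_triangle_closest(P, T).reshape(len(points), k, 3)
        dist = np.linalg.norm(cp - points[:, None], axis=2)
        best = np.argmin(dist, axis=1)
        rows = np.arange(len(points))
        best_d = dist[rows, best]
        # candidate set is guaranteed complete when the kth centroid is
        # farther than best_d + rmax; fall back to a ball query otherwise
        incomplete = np.flatnonzero(d[:, -1] < best_d + self.rmax) if k < len(self.faces) else []
        closest = cp[rows, best]
        fidx = j[rows, best]
        for i in incomplete:
            cand = self.tree.query_ball_point(points[i], best_d[i] + self.rmax + 1e-12)
            if not cand:
                continue
            cand = np.asarray(cand)
            cpi = _point_triangle_closest(np.repeat(points[i][None], len(cand), axis=0),
                                          self.tri[cand])
            di = np.linalg.norm(cpi - points[i], axis=1)
            bi = np.argmin(di)
            if di[bi] < best_d[i]:
                best_d[i] = di[bi]
                closest[i] = cpi[bi]
                fidx[i] = cand[bi]
        return closest, best_d, fidx


def closest_points(vertices, faces, points):
    """One-shot convenience wrapper around :class:`MeshProximity`."""
    return MeshProximity(vertices, faces).query(points)
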