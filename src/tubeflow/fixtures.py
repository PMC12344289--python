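"""Parametric synthetic surfaces and meshes used as test/benchmark fixtures.

These stand in for the non-deposited imaging datasets of the application
domains (airway trees, microvascular networks, embedded vessels): simple
analytic shapes whose volumes, areas and flow solutions are known in closed
form, so every pipeline stage can be validated quantitatively.
"""

from __future__ import annotations

import math

import numpy as np

from .surface import TriSurface

__all__ = ["capped_cylinder", "box_surface", "noisy_sphere", "icosphere"]


def capped_cylinder(radius: float = 2.0, z0: float = -10.0, z1: float = 10.0,
                    n_theta: int = 48, n_z: int = 24, n_r: int | None = None) -> TriSurface:
    """Watertight cylinder along z with flat triangulated end caps.

    The wall is subdivided in both directions and the caps use concentric
    rings, so faces are locally small (as marching cubes + remeshing would
    produce); outward orientation.
    """
    n_r = n_r or max(2, int(round(n_theta / (2 * math.pi))))
    th = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    zs = np.linspace(z0, z1, n_z + 1)
    verts = []
    idx = {}
    for iz, z in enumerate(zs):
        for it, t in enumerate(th):
            idx[("w", iz, it)] = len(verts)
            verts.append([radius * math.cos(t), radius * math.sin(t), z])
    faces = []
    for iz in range(n_z):
        for it in range(n_theta):
            a = idx[("w", iz, it)]
            b = idx[("w", iz, (it + 1) % n_theta)]
            c = idx[("w", iz + 1, it)]
            d = idx[("w", iz + 1, (it + 1) % n_theta)]
            faces.append([a, b, d])
            faces.append([a, d, c])
    # caps: concentric rings + centre point
    for side, z, sign in (("lo", z0, -1.0), ("hi", z1, 1.0)):
        ring_prev = [idx[("w", 0 if side == "lo" else n_z, it)] for it in range(n_theta)]
        for ir in range(1, n_r):
            r = radius * (n_r - ir) / n_r
            ring = []
            for it, t in enumerate(th):
                ring.append(len(verts))
                verts.append([r * math.cos(t), r * math.sin(t), z])
            for it in range(n_theta):
                a, b = ring_prev[it], ring_prev[(it + 1) % n_theta]
                c, d = ring[it], ring[(it + 1) % n_theta]
                if sign > 0:
                    faces.append([a, b, d])
                    faces.append([a, d, c])
                else:
                    faces.append([a, d, b])
                    faces.append([a, c, d])
            ring_prev = ring
        centre = len(verts)
        verts.append([0.0, 0.0, z])
        for it in range(n_theta):
            a, b = ring_prev[it], ring_prev[(it + 1) % n_theta]
            if sign > 0:
                faces.append([a, b, centre])
            else:
                faces.append([a, centre, b])
    return TriSurface(np.asarray(verts, dtype=float), np.asarray(faces, dtype=int))


def box_surface(lo=(0.0, 0.0, 0.0), hi=(1.0, 1.0, 1.0), n: int = 1,
                labelled: bool = False) -> TriSurface:
    """Axis-aligned box, each side an n x n triangulated grid.

    With ``labelled=True`` the six sides carry face labels 1..6 in the order
    -x, +x, -y, +y, -z, +z.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    verts: list = []
    vid: dict = {}

    def v(p):
        key = tuple(np.round(p, 12))
        if key not in vid:
            vid[key] = len(verts)
            verts.append(p)
        return vid[key]

    faces, labels = [], []
    sides = [(0, 0.0, 1), (0, 1.0, 2), (1, 0.0, 3), (1, 1.0, 4), (2, 0.0, 5), (2, 1.0, 6)]
    for axis, side, lab in sides:
        u_axis, v_axis = [a for a in range(3) if a != axis]
        for i in range(n):
            for j in range(n):
                corners = []
                for di, dj in ((0, 0), (1, 0), (1, 1), (0, 1)):
                    p = np.empty(3)
                    p[axis] = lo[axis] + side * (hi[axis] - lo[axis])
                    p[u_axis] = lo[u_axis] + (i + di) / n * (hi[u_axis] - lo[u_axis])
                    p[v_axis] = lo[v_axis] + (j + dj) / n * (hi[v_axis] - lo[v_axis])
                    corners.append(v(p))
                a, b, c, d = corners
                # outward orientation depends on which side of the axis
                flip = (side == 0.0) == (axis != 1)
                flip = False
                nrm = np.zeros(3)
                nrm[axis] = 1.0 if side == 1.0 else -1.0
                p0, p1, p2 = np.asarray(verts[a]), np.asarray(verts[b]), np.asarray(verts[c])
                if np.cross(p1 - p0, p2 - p0) @ nrm > 0:
                    faces.append([a, b, c])
                    faces.append([a, c, d])
                else:
                    faces.append([a, c, b])
                    faces.append([a, d, c])
                labels += [lab, lab]
    return TriSurface(np.asarray(verts, dtype=float), np.asarray(faces, dtype=int),
                      np.asarray(labels, dtype=int) if labelled else None)


def icosphere(radius: float = 5.0, subdivisions: int = 3) -> TriSurface:
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))


def noisy_sphere(radius: float = 5.0, noise: float = 0.2, subdivisions: int = 3,
                 seed: int = 0) -> TriSurface:
    """Icosphere with uniform radial noise (fixed seed): smoothing fixture."""
    s = icosphere(radius, subdivisions)
    rng = np.random.default_rng(seed)
    scale = 1.0 + rng.uniform(-noise / radius, noise / radius, (s.n_vertices, 1))
    return TriSurface(s.vertices * scale, s.faces)
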