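"""Finite-element solvers on tetrahedral meshes.

Continuous Lagrange spaces of order 1 (P1) and 2 (P2) on affine tetrahedra,
with quadrature built by a Duffy (collapsed-cube) transform of tensor
Gauss-Legendre rules, so all polynomial forms are integrated exactly.

Solvers:

* :func:`solve_poisson` — steady diffusion ``-D lap(c) = f`` (Galerkin,
  direct sparse factorization);
* :func:`solve_adr` — transient advection-diffusion-reaction
  ``dc/dt = div(D grad c) - div(u c) + (s - k c)`` with implicit-Euler
  stepping and optional SUPG stabilization;
* :func:`solve_ns_ipcs` — incompressible Navier-Stokes by the incremental
  pressure-correction scheme (IPCS): a semi-implicit tentative-velocity
  step (Crank-Nicolson viscous midpoint, explicit convection, full-stress
  form with open-boundary traction terms), a pressure Poisson update and
  an L2 velocity projection.  Element pairs: equal-order P1-P1 (the
  projection step provides the pressure coupling, so no inf-sup
  stabilization term is required) or Taylor-Hood P2-P1.

Boundary conditions are keyed by the integer labels of
``TetMesh.boundary_faces`` (the labels written by the labelling stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .meshing import TetMesh

__all__ = [
    "FluidProperties",
    "TransportSpec",
    "SolverConfig",
    "MeshField",
    "FlowState",
    "FunctionSpace",
    "solve_poisson",
    "solve_adr",
    "solve_ns_ipcs",
    "boundary_flux",
    "divergence_l2",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class FluidProperties:
    """Newtonian fluid: density rho and dynamic viscosity mu."""

    rho: float = 1.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be > 0")


@dataclass
class TransportSpec:
    """Advection-diffusion-reaction data: D, velocity, g(c) = s - k c."""

    D: float = 1.0
    velocity: "MeshField | None" = None
    source: float = 0.0
    decay: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.decay < 0:
            raise ValueError("decay rate must be >= 0")


@dataclass
class SolverConfig:
    dt: float = 0.01
    T: float = 1.0
    element_order: str = "p1-p1"  # flow: "p1-p1" | "p2-p1"; scalars: "p1" | "p2"
    body_force: tuple = (0.0, 0.0, 0.0)
    bc_table: dict = field(default_factory=dict)
    supg: bool = False
    steady_tol: float = 0.0  # stop early when ||du||/||u|| drops below (0 = off)

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.T:
            raise ValueError("need 0 < dt <= T")


@dataclass
class MeshField:
    """Nodal field on a function space (scalar or 3-vector)."""

    values: np.ndarray
    mesh: TetMesh
    coords: np.ndarray  # dof coordinates (n_dofs, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.coords)
        if self.values.shape not in ((n,), (n, 3)):
            raise ValueError("field length must match dof count (x1 or x3)")


@dataclass
class FlowState:
    u: MeshField
    p: MeshField


# ---------------------------------------------------------------------------
# Quadrature (Duffy transform of tensor Gauss-Legendre)
# ---------------------------------------------------------------------------

def _tet_quadrature(n: int = 3):
    """Points (Q, 3) in reference coords (x, y, z) and weights summing to 1/6."""
    g, w = np.polynomial.legendre.leggauss(n)
    g = 0.5 * (g + 1.0)
    w = 0.5 * w
    pts, wts = [], []
    for iu, u in enumerate(g):
        for iv, v in enumerate(g):
            for iw, t in enumerate(g):
                x = u
                y = v * (1 - u)
                z = t * (1 - u) * (1 - v)
                jac = (1 - u) ** 2 * (1 - v)
                pts.append((x, y, z))
                wts.append(w[iu] * w[iv] * w[iw] * jac)
    return np.asarray(pts), np.asarray(wts)


def _tri_quadrature(n: int = 3):
    """Duffy quadrature on the reference triangle (weights sum to 1/2)."""
    g, w = np.polynomial.legendre.leggauss(n)
    g = 0.5 * (g + 1.0)
    w = 0.5 * w
    pts, wts = [], []
    for iu, u in enumerate(g):
        for iv, v in enumerate(g):
            pts.append((u, v * (1 - u)))
            wts.append(w[iu] * w[iv] * (1 - u))
    return np.asarray(pts), np.asarray(wts)


# ---------------------------------------------------------------------------
# Lagrange spaces
# ---------------------------------------------------------------------------

_EDGE_LOCAL = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def _p_basis(order: int, lam: np.ndarray):
    """Values and reference gradients of the Lagrange basis.

    ``lam``: (Q, 4) barycentric coordinates.  Returns values (Q, nb) and
    gradients w.r.t. reference coords x,y,z (Q, nb, 3), using
    d lam0 = (-1,-1,-1), d lam_i = e_i.
    """
    Q = len(lam)
    dlam = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    if order == 1:
        vals = lam.copy()
        grads = np.broadcast_to(dlam, (Q, 4, 3)).copy()
        return vals, grads
    if order == 2:
        nb = 10
        vals = np.empty((Q, nb))
        grads = np.empty((Q, nb, 3))
        for i in range(4):
            li = lam[:, i]
            vals[:, i] = li * (2 * li - 1)
            grads[:, i] = ((4 * li - 1)[:, None]) * dlam[i]
        for k, (i, j) in enumerate(_EDGE_LOCAL):
            li, lj = lam[:, i], lam[:, j]
            vals[:, 4 + k] = 4 * li * lj
            grads[:, 4 + k] = 4 * (lj[:, None] * dlam[i] + li[:, None] * dlam[j])
        return vals, grads
    raise ValueError("order must be 1 or 2")


class FunctionSpace:
    """Scalar continuous Lagrange space (P1 or P2) on a TetMesh."""

    def __init__(self, mesh: TetMesh, order: int = 1, quad: int = 3):
        self.mesh = mesh
        self.order = order
        nn = mesh.n_nodes
        if order == 1:
            self.cell_dofs = mesh.tets.copy()
            self.coords = mesh.nodes.copy()
        elif order == 2:
            e = np.vstack([mesh.tets[:, [i, j]] for i, j in _EDGE_LOCAL])
            key = np.sort(e, axis=1)
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            edge_dof = nn + inv.reshape(6, -1).T  # (T, 6)
            self.cell_dofs = np.hstack([mesh.tets, edge_dof])
            mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
            self.coords = np.vstack([mesh.nodes, mid])
            self._edge_lookup = {tuple(k): nn + i for i, k in enumerate(map(tuple, uniq))}
        else:
            raise ValueError("order must be 1 or 2")
        self.n_dofs = len(self.coords)
        # element geometry
        p = mesh.nodes[mesh.tets]
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
        self.detJ = np.linalg.det(J)
        self.Jinv = np.linalg.inv(J)
        # quadrature and basis tables
        xq, wq = _tet_quadrature(quad)
        lam = np.column_stack([1 - xq.sum(axis=1), xq])
        self.qw = wq
        self.qlam = lam
        self.N, dNref = _p_basis(order, lam)          # (Q, nb), (Q, nb, 3)
        # physical gradients: (T, Q, nb, 3) via Jinv^T
        self.dN = np.einsum("qbk,tkl->tqbl", dNref, self.Jinv)
        # physical quadrature points (T, Q, 3): x = sum_i lam_i p_i
        self.xq = np.einsum("qb,tbk->tqk", lam, p)
        self.nb = self.N.shape[1]

    # -- assembly helpers ---------------------------------------------------
    def _scatter(self, ke: np.ndarray) -> sparse.csr_matrix:
        """ke: (T, nb, nb) element matrices -> global sparse."""
        T, nb, _ = ke.shape
        rows = np.repeat(self.cell_dofs, nb, axis=1).ravel()
        cols = np.tile(self.cell_dofs, (1, nb)).ravel()
        return sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                 shape=(self.n_dofs, self.n_dofs)).tocsr()

    def mass_matrix(self, coef: float = 1.0) -> sparse.csr_matrix:
        ke = np.einsum("q,qa,qb->ab", self.qw, self.N, self.N)
        ke = coef * np.einsum("t,ab->tab", np.abs(self.detJ), ke)
        return self._scatter(ke)

    def stiffness_matrix(self, coef: float = 1.0) -> sparse.csr_matrix:
        ke = coef * np.einsum("q,tqak,tqbk,t->tab", self.qw, self.dN, self.dN,
                              np.abs(self.detJ))
        return self._scatter(ke)

    def partial_matrix(self, a: int, b: int) -> sparse.csr_matrix:
        """int d_a(phi_test) d_b(phi_trial)."""
        ke = np.einsum("q,tqa,tqb,t->tab", self.qw, self.dN[:, :, :, a],
                       self.dN[:, :, :, b], np.abs(self.detJ))
        return self._scatter(ke)

    def convection_matrix(self, u_at_q: np.ndarray) -> sparse.csr_matrix:
        """int (u . grad phi_trial) phi_test; u_at_q: (T, Q, 3)."""
        ug = np.einsum("tqk,tqbk->tqb", u_at_q, self.dN)
        ke = np.einsum("q,qa,tqb,t->tab", self.qw, self.N, ug, np.abs(self.detJ))
        return self._scatter(ke)

    def supg_matrices(self, u_at_q: np.ndarray, tau: np.ndarray):
        """Streamline terms: (tau u.grad v, u.grad c) and (tau u.grad v, c)."""
        ugb = np.einsum("tqk,tqbk->tqb", u_at_q, self.dN)
        kaa = np.einsum("q,t,tqa,tqb,t->tab", self.qw, tau, ugb, ugb,
                        np.abs(self.detJ))
        kab = np.einsum("q,t,tqa,qb,t->tab", self.qw, tau, ugb, self.N,
                        np.abs(self.detJ))
        return self._scatter(kaa), self._scatter(kab)

    def load_vector(self, f) -> np.ndarray:
        """(f, v) with f scalar constant or callable f(x)->scalar."""
        if callable(f):
            fq = np.apply_along_axis(lambda x: f(x), 2, self.xq)
        else:
            fq = np.full(self.xq.shape[:2], float(f))
        fe = np.einsum("q,qa,tq,t->ta", self.qw, self.N, fq, np.abs(self.detJ))
        vec = np.zeros(self.n_dofs)
        np.add.at(vec, self.cell_dofs.ravel(), fe.ravel())
        return vec

    def interpolate(self, f) -> np.ndarray:
        """Nodal interpolation of f(x) (callable) or a constant."""
        if callable(f):
            return np.array([f(x) for x in self.coords], dtype=float)
        return np.full(self.n_dofs, float(f))

    def at_quadrature(self, values: np.ndarray) -> np.ndarray:
        """Evaluate a dof vector at the quadrature points: (T, Q[, 3])."""
        if values.ndim == 1:
            return np.einsum("qb,tb->tq", self.N, values[self.cell_dofs])
        return np.einsum("qb,tbk->tqk", self.N, values[self.cell_dofs])

    def grad_at_quadrature(self, values: np.ndarray) -> np.ndarray:
        if values.ndim == 1:
            return np.einsum("tqbk,tb->tqk", self.dN, values[self.cell_dofs])
        return np.einsum("tqbk,tbm->tqkm", self.dN, values[self.cell_dofs])

    # -- boundary -----------------------------------------------------------
    def boundary_dofs(self, labels) -> np.ndarray:
        """Dofs lying on boundary faces with any of the given labels."""
        labels = {labels} if np.isscalar(labels) else set(labels)
        sel = np.isin(self.mesh.boundary_labels, list(labels))
        faces = self.mesh.boundary_faces[sel]
        dofs = set(faces.ravel().tolist())
        if self.order == 2:
            for f in faces:
                for i in range(3):
                    a, b = f[i], f[(i + 1) % 3]
                    d = self._edge_lookup.get((min(a, b), max(a, b)))
                    if d is not None:
                        dofs.add(d)
        return np.asarray(sorted(dofs), dtype=int)

    def face_owner_map(self):
        """owner tet index and local facet for every boundary face."""
        facet_local = [(0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3)]
        lookup = {}
        for t, tet in enumerate(self.mesh.tets):
            for loc in facet_local:
                key = tuple(sorted(tet[list(loc)]))
                lookup[key] = t
        owners = np.array([lookup[tuple(sorted(f))] for f in self.mesh.boundary_faces])
        return owners


# ---------------------------------------------------------------------------
# Boundary-face quadrature utilities
# ---------------------------------------------------------------------------

class _FaceQuad:
    """Quadrature data on a set of labelled boundary faces of a space."""

    def __init__(self, V: FunctionSpace, face_idx: np.ndarray, n: int = 3):
        self.V = V
        m = V.mesh
        self.faces = m.boundary_faces[face_idx]
        owners_all = V.face_owner_map()
        self.owners = owners_all[face_idx]
        uv, w2 = _tri_quadrature(n)
        p = m.nodes[self.faces]  # (F, 3, 3)
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        nrm = np.cross(e1, e2)
        self.jac = np.linalg.norm(nrm, axis=1)  # 2*area
        self.normal = nrm / self.jac[:, None]
        self.w2 = w2
        # physical quadrature points (F, Q, 3)
        self.xq = (p[:, None, 0]
                   + uv[None, :, 0, None] * e1[:, None]
                   + uv[None, :, 1, None] * e2[:, None])
        # barycentric coords of the quad points inside the owner tets
        tp = m.nodes[m.tets[self.owners]]  # (F, 4, 3)
        J = np.stack([tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0],
                      tp[:, 3] - tp[:, 0]], axis=2)
        Jinv = np.linalg.inv(J)
        loc = np.einsum("fkl,fql->fqk", Jinv, self.xq - tp[:, None, 0])
        lam = np.concatenate([1 - loc.sum(axis=2, keepdims=True), loc], axis=2)
        F, Q = lam.shape[:2]
        vals, grads_ref = _p_basis(V.order, lam.reshape(-1, 4))
        self.Nf = vals.reshape(F, Q, -1)                       # (F, Q, nb)
        g = grads_ref.reshape(F, Q, -1, 3)
        self.dNf = np.einsum("fqbk,fkl->fqbl", g, Jinv)        # physical grads
        self.cell_dofs = V.cell_dofs[self.owners]              # (F, nb)

    def area(self) -> float:
        return float((self.jac * self.w2.sum()).sum())


# ---------------------------------------------------------------------------
# Dirichlet elimination solver
# ---------------------------------------------------------------------------

class _DirichletSystem:
    def __init__(self, A: sparse.csr_matrix, fixed: np.ndarray, n: int):
        self.n = n
        self.fixed = fixed
        mask = np.ones(n, dtype=bool)
        mask[fixed] = False
        self.free = np.flatnonzero(mask)
        self.Aff = A[self.free][:, self.free].tocsc()
        self.Afd = A[self.free][:, fixed].tocsr()
        self.lu = splu(self.Aff)

    def solve(self, b: np.ndarray, xd: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n)
        x[self.fixed] = xd
        rhs = b[self.free] - self.Afd @ xd
        x[self.free] = self.lu.solve(rhs)
        return x


def _dirichlet_values(V: FunctionSpace, dofs: np.ndarray, value) -> np.ndarray:
    if callable(value):
        return np.array([value(x) for x in V.coords[dofs]], dtype=float)
    return np.full(len(dofs), float(value))


# ---------------------------------------------------------------------------
# Poisson
# ---------------------------------------------------------------------------

def solve_poisson(m: TetMesh, D: float, source, bc: dict,
                  order: int = 1) -> MeshField:
    """Steady diffusion ``-D lap(c) = source`` with labelled BCs.

    ``bc``: label -> {"dirichlet": value-or-callable} or
    {"neumann": flux-density}.  At least one Dirichlet label is required.
    """
    V = FunctionSpace(m, order)
    K = V.stiffness_matrix(D)
    b = V.load_vector(source)
    fixed, fvals = _collect_dirichlet(V, bc)
    if not len(fixed):
        raise ValueError("Poisson problem needs at least one Dirichlet label")
    for lab, spec in bc.items():
        if isinstance(spec, dict) and "neumann" in spec:
            idx = np.flatnonzero(m.boundary_labels == lab)
            fq = _FaceQuad(V, idx)
            g = spec["neumann"]
            gq = np.full(fq.xq.shape[:2], float(g)) if not callable(g) else \
                np.apply_along_axis(g, 2, fq.xq)
            fe = np.einsum("q,fqa,fq,f->fa", fq.w2, fq.Nf, gq, fq.jac)
            np.add.at(b, fq.cell_dofs.ravel(), fe.ravel())
    sys = _DirichletSystem(K, fixed, V.n_dofs)
    x = sys.solve(b, fvals)
    return MeshField(x, m, V.coords)


def _collect_dirichlet(V: FunctionSpace, bc: dict):
    fixed, vals = [], []
    for lab, spec in bc.items():
        if isinstance(spec, dict) and "dirichlet" in spec:
            dofs = V.boundary_dofs(lab)
            fixed.append(dofs)
            vals.append(_dirichlet_values(V, dofs, spec["dirichlet"]))
    if not fixed:
        return np.zeros(0, dtype=int), np.zeros(0)
    allf = np.concatenate(fixed)
    allv = np.concatenate(vals)
    # deduplicate, last wins deterministically by label order
    _, first = np.unique(allf, return_index=True)
    return allf[first], allv[first]


# ---------------------------------------------------------------------------
# Advection-diffusion-reaction
# ---------------------------------------------------------------------------

def solve_adr(m: TetMesh, spec: TransportSpec, cfg: SolverConfig,
              c0: MeshField | float = 0.0, store_every: int = 0):
    """Implicit-Euler Galerkin time stepping of the ADR equation.

    Returns the list of stored :class:`MeshField` snapshots (always
    including the final state).  With pure diffusion, zero reaction and
    natural (zero-flux) boundaries the total mass ``int c dV`` is conserved
    to solver precision at every step.
    """
    order = 2 if cfg.element_order in ("p2", "p2-p1") else 1
    V = FunctionSpace(m, order)
    M = V.mass_matrix()
    Mstab = M  # time/reaction operator; SUPG augments it consistently
    A_adv = None
    if spec.velocity is not None:
        uq = V.at_quadrature(_as_space_vector(spec.velocity, V))
        A_adv = V.convection_matrix(uq)
        if cfg.supg:
            # tau = h / (2 |u|) with element size from the volume
            h = (6.0 * np.abs(V.detJ) / math.sqrt(2.0)) ** (1.0 / 3.0)
            umag = np.maximum(np.linalg.norm(uq, axis=2).max(axis=1), 1e-12)
            tau = h / (2.0 * umag)
            Saa, Sab = V.supg_matrices(uq, tau)
            A_adv = A_adv + Saa
            Mstab = M + Sab
    A = Mstab * (1.0 / cfg.dt + spec.decay) + V.stiffness_matrix(spec.D)
    if A_adv is not None:
        A = A + A_adv
    c = V.interpolate(c0) if not isinstance(c0, MeshField) else \
        np.asarray(c0.values, dtype=float).copy()
    fixed, fvals = _collect_dirichlet(V, cfg.bc_table)
    b_source = V.load_vector(spec.source)
    if cfg.supg and spec.velocity is not None and spec.source:
        b_source = b_source + Sab @ np.full(V.n_dofs, float(spec.source))
    if len(fixed):
        sys = _DirichletSystem(A, fixed, V.n_dofs)
    else:
        lu = splu(A.tocsc())
    nsteps = int(round(cfg.T / cfg.dt))
    out = []
    for step in range(nsteps):
        b = Mstab @ c * (1.0 / cfg.dt) + b_source
        if len(fixed):
            c = sys.solve(b, fvals)
        else:
            c = lu.solve(b)
        if store_every and (step + 1) % store_every == 0:
            out.append(MeshField(c.copy(), m, V.coords))
    if not out or store_every == 0 or nsteps % store_every:
        out.append(MeshField(c.copy(), m, V.coords))
    return out


def _as_space_vector(fieldv: MeshField, V: FunctionSpace) -> np.ndarray:
    vals = np.asarray(fieldv.values, dtype=float)
    if vals.shape == (V.n_dofs, 3):
        return vals
    if vals.shape == (V.mesh.n_nodes, 3) and V.order == 2:
        # extend a vertex field to edge midpoints by averaging
        ed = V.coords[V.mesh.n_nodes:]
        from scipy.spatial import cKDTree
        # midpoints are averages of their edge endpoints: reconstruct exactly
        out = np.empty((V.n_dofs, 3))
        out[:V.mesh.n_nodes] = vals
        for key, dof in V._edge_lookup.items():
            out[dof] = 0.5 * (vals[key[0]] + vals[key[1]])
        return out
    raise ValueError("velocity field does not match the transport space")


# ---------------------------------------------------------------------------
# IPCS Navier-Stokes
# ---------------------------------------------------------------------------

def _vector_dofs(dofs: np.ndarray, n: int, comps=(0, 1, 2)) -> np.ndarray:
    return np.concatenate([dofs + c * n for c in comps])


def solve_ns_ipcs(m: TetMesh, props: FluidProperties, cfg: SolverConfig,
                  store_every: int = 0, callback=None):
    """Incompressible Navier-Stokes via the incremental pressure-correction
    scheme.

    Per step: (1) tentative velocity from the semi-implicit momentum
    equation (Crank-Nicolson viscous midpoint, explicit convection
    ``rho (u^n . grad) u^n``, full stress ``sigma = 2 mu eps(u) - p I`` with
    the open-boundary terms ``int p n.v - mu (grad u n).v ds``); (2)
    pressure correction ``lap p^{n+1} = lap p^n - (rho/dt) div u*``;
    (3) projection ``u^{n+1} = u* - (dt/rho) grad(p^{n+1} - p^n)``.

    ``cfg.bc_table``: label -> one of
      {"type": "noslip"} | {"type": "velocity", "value": (vx,vy,vz) or f(x,t)}
      | {"type": "pressure", "value": p} | {"type": "velocity_component",
      "component": k, "value": v}.
    Returns stored :class:`FlowState` snapshots (final state always last).
    """
    if cfg.dt <= 0:
        raise ValueError("dt must be positive")
    rho, mu = props.rho, props.mu
    order_u = 2 if cfg.element_order == "p2-p1" else 1
    Vu = FunctionSpace(m, order_u)
    Vp = FunctionSpace(m, 1)
    nu, npr = Vu.n_dofs, Vp.n_dofs

    Ms = Vu.mass_matrix()
    Mv = sparse.block_diag([Ms] * 3).tocsr()
    # full-stress viscous operator: 2 mu eps(u):eps(v)
    Klap = Vu.stiffness_matrix()
    blocks = [[None] * 3 for _ in range(3)]
    for a in range(3):
        for b in range(3):
            Kab = Vu.partial_matrix(a, b)
            blocks[a][b] = mu * (Kab if a != b else (Klap + Kab))
    Avisc = sparse.bmat(blocks).tocsr()

    # pressure coupling (p, div v) as a (3 nu, np) matrix
    pq = Vp.N  # pressure basis at (shared) quadrature points
    Dblocks = []
    for a in range(3):
        ke = np.einsum("q,tqa,qb,t->tab", Vu.qw, Vu.dN[:, :, :, a], pq,
                       np.abs(Vu.detJ))
        rows = np.repeat(Vu.cell_dofs, Vp.cell_dofs.shape[1], axis=1).ravel()
        cols = np.tile(Vp.cell_dofs, (1, Vu.nb)).ravel()
        Dblocks.append(sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                         shape=(nu, npr)).tocsr())
    Dmat = sparse.vstack(Dblocks).tocsr()          # (p, dv_a/dx_a) stacked

    # gradient coupling (grad p, v)
    Gblocks = []
    for a in range(3):
        ke = np.einsum("q,qa,tqb,t->tab", Vu.qw, Vu.N, Vp.dN[:, :, :, a],
                       np.abs(Vu.detJ))
        rows = np.repeat(Vu.cell_dofs, Vp.cell_dofs.shape[1], axis=1).ravel()
        cols = np.tile(Vp.cell_dofs, (1, Vu.nb)).ravel()
        Gblocks.append(sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                         shape=(nu, npr)).tocsr())
    Gmat = sparse.vstack(Gblocks).tocsr()

    Kp = Vp.stiffness_matrix()

    # boundary conditions ---------------------------------------------------
    bl = m.boundary_labels
    vel_fixed: list[np.ndarray] = []
    vel_value: list = []       # parallel: callable(x, t) -> scalar, per dof
    p_fixed: list[np.ndarray] = []
    p_vals: list[np.ndarray] = []
    open_labels = []
    for lab, spec in cfg.bc_table.items():
        kind = spec.get("type")
        if kind == "noslip":
            dofs = Vu.boundary_dofs(lab)
            vel_fixed.append(_vector_dofs(dofs, nu))
            vel_value.append(np.zeros(3 * len(dofs)))
        elif kind == "velocity":
            dofs = Vu.boundary_dofs(lab)
            val = spec["value"]
            if callable(val):
                vel_fixed.append(_vector_dofs(dofs, nu))
                vel_value.append(("func", val, dofs))
            else:
                v = np.asarray(val, dtype=float)
                vel_fixed.append(_vector_dofs(dofs, nu))
                vel_value.append(np.concatenate([np.full(len(dofs), v[c])
                                                 for c in range(3)]))
        elif kind == "velocity_component":
            dofs = Vu.boundary_dofs(lab)
            c = int(spec["component"])
            vel_fixed.append(dofs + c * nu)
            vel_value.append(np.full(len(dofs), float(spec["value"])))
        elif kind == "pressure":
            dofs = Vp.boundary_dofs(lab)
            p_fixed.append(dofs)
            p_vals.append(np.full(len(dofs), float(spec["value"])))
            open_labels.append(lab)
        elif kind == "open":
            open_labels.append(lab)
        else:
            raise ValueError(f"unknown bc type {kind!r} for label {lab}")
    if not p_fixed:
        raise ValueError("IPCS needs at least one pressure (outlet) label")

    def velocity_dirichlet(t: float):
        if not vel_fixed:
            return np.zeros(0, dtype=int), np.zeros(0)
        idx = np.concatenate(vel_fixed)
        vals = []
        for v in vel_value:
            if isinstance(v, tuple):
                _, fn, dofs = v
                arr = np.asarray([fn(x, t) for x in Vu.coords[dofs]], dtype=float)
                vals.append(arr.T.ravel())  # (3, n) -> concat per component
            else:
                vals.append(v)
        allv = np.concatenate(vals)
        _, first = np.unique(idx, return_index=True)
        return idx[first], allv[first]

    pf = np.concatenate(p_fixed)
    pv = np.concatenate(p_vals)
    _, first = np.unique(pf, return_index=True)
    pf, pv = pf[first], pv[first]

    # open-boundary traction terms ------------------------------------------
    open_idx = np.flatnonzero(np.isin(bl, open_labels)) if open_labels else \
        np.zeros(0, dtype=int)
    Bn = sparse.csr_matrix((3 * nu, npr))
    Sn = sparse.csr_matrix((3 * nu, 3 * nu))
    if len(open_idx):
        fq = _FaceQuad(Vu, open_idx)
        fqp = _FaceQuad(Vp, open_idx)
        nbu = Vu.nb
        nbp = Vp.nb
        # int p n_a v_a ds
        rows_u = np.repeat(fq.cell_dofs, nbp, axis=1)
        cols_p = np.tile(fqp.cell_dofs, (1, nbu))
        bnb = []
        for a in range(3):
            ke = np.einsum("q,fqa,fqb,f,f->fab", fq.w2, fq.Nf, fqp.Nf,
                           fq.normal[:, a], fq.jac)
            bnb.append(sparse.coo_matrix(
                (ke.ravel(), (rows_u.ravel(), cols_p.ravel())),
                shape=(nu, npr)).tocsr())
        Bn = sparse.vstack(bnb).tocsr()
        # int (grad u_a . n) v_a ds  (same scalar operator per component)
        ke = np.einsum("q,fqa,fqbk,fk,f->fab", fq.w2, fq.Nf, fq.dNf,
                       fq.normal, fq.jac)
        rows = np.repeat(fq.cell_dofs, nbu, axis=1).ravel()
        cols = np.tile(fq.cell_dofs, (1, nbu)).ravel()
        Ssc = sparse.coo_matrix((ke.ravel(), (rows, cols)),
                                shape=(nu, nu)).tocsr()
        Sn = sparse.block_diag([Ssc] * 3).tocsr()

    Aop = Avisc - mu * Sn
    A1 = (rho / cfg.dt) * Mv + 0.5 * Aop

    # body force
    ones = Vu.load_vector(1.0)
    Fb = np.concatenate([float(cfg.body_force[a]) * ones for a in range(3)])

    t = 0.0
    vf, vvals = velocity_dirichlet(t)
    sys1 = _DirichletSystem(A1.tocsr(), vf, 3 * nu)
    sys2 = _DirichletSystem(Kp, pf, npr)
    sys3 = _DirichletSystem(Mv.tocsr(), vf, 3 * nu)

    u = np.zeros(3 * nu)
    u[vf] = vvals
    p = np.zeros(npr)
    p[pf] = pv
    nsteps = int(round(cfg.T / cfg.dt))
    out = []
    div_history = []
    for step in range(nsteps):
        t += cfg.dt
        vf_t, vvals_t = velocity_dirichlet(t)
        conv = _convection_vector(Vu, u, rho)
        b1 = (rho / cfg.dt) * (Mv @ u) - 0.5 * (Aop @ u) - conv \
            + Dmat @ p - Bn @ p + Fb
        ustar = sys1.solve(b1, vvals_t)
        b2 = Kp @ p - (rho / cfg.dt) * (Dmat.T @ ustar)
        pnew = sys2.solve(b2, pv)
        b3 = Mv @ ustar - (cfg.dt / rho) * (Gmat @ (pnew - p))
        unew = sys3.solve(b3, vvals_t)
        div_history.append((divergence_l2(Vu, ustar), divergence_l2(Vu, unew)))
        if not np.all(np.isfinite(unew)):
            raise RuntimeError(f"IPCS diverged at step {step + 1}")
        du = np.linalg.norm(unew - u) / max(np.linalg.norm(unew), 1e-300)
        u, p = unew, pnew
        if callback is not None:
            callback(step, u, p)
        if store_every and (step + 1) % store_every == 0:
            out.append(_make_state(u, p, m, Vu, Vp))
        if cfg.steady_tol and du < cfg.steady_tol:
            break
    out.append(_make_state(u, p, m, Vu, Vp))
    out[-1].divergence_history = div_history  # type: ignore[attr-defined]
    return out


def _make_state(u, p, m, Vu, Vp) -> FlowState:
    nu = Vu.n_dofs
    uf = MeshField(np.stack([u[:nu], u[nu:2 * nu], u[2 * nu:]], axis=1), m, Vu.coords)
    return FlowState(uf, MeshField(p.copy(), m, Vp.coords))


def _convection_vector(Vu: FunctionSpace, u: np.ndarray, rho: float) -> np.ndarray:
    nu = Vu.n_dofs
    uvec = np.stack([u[:nu], u[nu:2 * nu], u[2 * nu:]], axis=1)
    uq = Vu.at_quadrature(uvec)                      # (T, Q, 3)
    gq = Vu.grad_at_quadrature(uvec)                 # (T, Q, 3, m) du_m/dx_k
    adv = np.einsum("tqk,tqkm->tqm", uq, gq)         # (u . grad) u
    fe = rho * np.einsum("q,qa,tqm,t->tam", Vu.qw, Vu.N, adv, np.abs(Vu.detJ))
    vec = np.zeros(3 * nu)
    for a in range(3):
        np.add.at(vec, Vu.cell_dofs.ravel() + a * nu, fe[:, :, a].ravel())
    return vec


def divergence_l2(V: FunctionSpace, u: np.ndarray) -> float:
    """L2 norm of div(u) for a stacked velocity vector."""
    nu = V.n_dofs
    uvec = np.stack([u[:nu], u[nu:2 * nu], u[2 * nu:]], axis=1)
    g = V.grad_at_quadrature(uvec)                   # (T, Q, k, m)
    div = g[:, :, 0, 0] + g[:, :, 1, 1] + g[:, :, 2, 2]
    val = np.einsum("q,tq,t->", V.qw, div ** 2, np.abs(V.detJ))
    return math.sqrt(max(val, 0.0))


# ---------------------------------------------------------------------------
# Boundary fluxes
# ---------------------------------------------------------------------------

def boundary_flux(state, m: TetMesh, label: int, D: float = 1.0) -> float:
    """``int_Gamma u . n dA`` for a flow state / vector field, or
    ``int_Gamma -D grad(c) . n dA`` for a scalar field, over one label."""
    if isinstance(state, FlowState):
        fieldv = state.u
    else:
        fieldv = state
    if label not in m.boundary_labels:
        raise KeyError(f"unknown boundary label {label}")
    idx = np.flatnonzero(m.boundary_labels == label)
    vals = np.asarray(fieldv.values, dtype=float)
    order = 1 if len(vals) == m.n_nodes else 2
    V = FunctionSpace(m, order)
    fq = _FaceQuad(V, idx)
    if vals.ndim == 2:
        uq = np.einsum("fqb,fbk->fqk", fq.Nf, vals[fq.cell_dofs])
        un = np.einsum("fqk,fk->fq", uq, fq.normal)
        return float(np.einsum("q,fq,f->", fq.w2, un, fq.jac))
    gq = np.einsum("fqbk,fb->fqk", fq.dNf, vals[fq.cell_dofs])
    gn = np.einsum("fqk,fk->fq", gq, fq.normal)
    return float(-D * np.einsum("q,fq,f->", fq.w2, gn, fq.jac))
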