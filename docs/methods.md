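# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `tubeflow`, stage by stage in pipeline order.

## Spatial graphs and synthetic fixtures

A network is nodes (3D world coordinates), strictly positive per-node radii,
and edges; curved segments carry optional polylines whose endpoints coincide
with node positions. Radii live on nodes; where an edge radius is needed
(1D conductances, rasterization) it is interpolated linearly between the
endpoint radii by arclength. Units are caller-defined and never converted.

The synthetic tree generator produces deterministic binary trees: the root
segment points along +z; each junction spawns two children deviating by a
fixed branching angle (default 40 degrees, in the physiological range for
airway and arterial bifurcations) in a plane whose azimuth advances by the
golden angle per generation plus a small seeded jitter. Child radius and
length shrink by a fixed ratio (default 0.8, close to the Murray-law
daughter/parent ratio 2^(-1/3) ~ 0.79 for symmetric bifurcations; default
segment length 8 radius units keeps branches long relative to their
diameter so junction geometry stays resolvable). These fixtures emulate the
*geometry class* of airway/vascular trees — branching topology, tapering
radii, wide diameter range — but not imaging noise, surface texture,
non-circular lumina or touching vessels, so passing tests demonstrate
correctness of the geometric/numerical machinery, not robustness to
real-image segmentation artefacts.

## Reconstruction

**From images.** Marching cubes on the 0/1 mask at level 0.5, with a
one-voxel pad (on the background side) so objects touching the array bounds
still close. The voxel convention is voxel-centred: world = origin +
index * spacing, 0-based.

**From graphs.** The normalized distance field
`phi(x) = min_p |x - p| / r(p)` over centreline points `p` makes the tube
wall the `phi = 1` isosurface even with varying radii. For efficiency phi
is evaluated only on a band of voxels within a configurable dilation radius
of the rasterized network (default `ceil(2 r_max / spacing)` voxels, which
guarantees the phi = 1 level is interior to the band); outside the band the
field holds the sentinel 2.0 — never NaN — so marching cubes stays
well defined. The centreline is resampled at step spacing/2 before distance
queries, bounding the chord error of the sampled minimum well below voxel
size. The exact minimizer search uses a k-nearest-neighbour candidate set
whose k grows with the radius ratio `r_max/r_min`, falling back gracefully
for strongly heterogeneous networks; probes against dense brute-force
minimization agree to < 2%.

## Surface processing

**Isotropic remeshing** follows the classic incremental scheme: split edges
longer than 4/3 of the target length, collapse edges shorter than 4/5
(guarded by the link condition so the mesh stays closed and manifold), flip
edges to equalize vertex valences, then relax vertices to their neighbour
centroid and project back onto the input surface. Target edge length is
derived from a requested vertex count via `V ~ 2A / (sqrt(3) l^2)` with up
to three feedback rounds, landing within ~10% of the request. On marching
cubes staircase surfaces this reduces triangle-area spread substantially;
on inputs that are already near-regular the steady-state regularity
(area CV ~ 0.15) may match rather than beat the input.

**HC smoothing** is the Vollmer–Mendoza–Humphrey scheme: a uniform
Laplacian step followed by subtracting the weighted mean (beta for the
vertex, 1 − beta for its neighbours) of the displacement vectors from a
blend (alpha) of original and previous positions. Defaults alpha = 0.1,
beta = 0.6 are the common literature values; 15 steps on a noisy sphere
drift the enclosed volume by ~1%, versus ~40% shrinkage for the
plain-Laplacian control with the same step count.

**Hole repair** closes each boundary loop with a fan to the loop centroid
(orientation inherited from the loop's winding). Adequate for the small
quasi-planar holes smoothing can open; it is not a general mesh fixer.

## Skeletonization

Thinning is sequential simple-point removal: a border voxel may be deleted
iff its 26-neighbourhood object voxels form one 26-connected component and
the background 6-neighbours lie in one 6-connected component of the
18-neighbourhood background (Malandain–Bertrand characterization), and it
is not a curve endpoint (exactly one object neighbour). Candidates are
processed in increasing Euclidean-distance-transform order, which centres
the skeleton on the medial axis; simple-point deletion preserves Betti
numbers (components and tunnels) by construction — verified on cylinder
(b0=1, b1=0) and solid-torus (b0=1, b1=1) fixtures. The sequential
formulation was chosen over parallel sub-iteration thinning after the
latter class proved able to delete entire even-width structures.

The skeleton image becomes a graph by classifying voxels by 26-neighbour
count: endpoints (1), path voxels (2), junctions (>= 3, merged per
26-connected cluster with the node at the cluster member nearest the
cluster centroid). Edge paths retain the voxel polylines; node radii are
the distance-transform values at node voxels (in world units). Pure cycles
(rings) are broken into three arcs so no self-loops or duplicate node pairs
arise. Branches hanging off junctions shorter than `prune_length` are
removed iteratively, then isolated components with total length below
`filter_length` are dropped, then chains through leftover degree-2 nodes
are merged. The optional `resolution` parameter resamples the binary image
to an isotropic voxel size before thinning (nearest neighbour).

Thinning retracts branch tips by roughly one radius. Terminal extension
casts a ray through each degree-1 node along the terminal direction and
appends the first surface hit as the new edge point. The terminal
*direction* is taken from the path point ~2 radii of arclength behind the
tip, not the adjacent voxel: a single voxel step is quantized to 26
directions (up to ~19 degrees off-axis), which would tilt slicing planes
and inflate cap areas by 1/cos(theta). Ray casting is brute-force
Moller–Trumbore over all faces (exact; fine at fixture scales).

Before skeletonization the processed surface is rasterized back to a
binary image by an even-odd parity test of voxel centres, since remeshing
and smoothing have moved the wall off the original grid.

## Slicing, sealing, labelling

A slicing plane is the terminal edge point pulled back inward by one local
radius (so caps sit on a cylindrical, not flared, section) with the
terminal direction as outward normal. Locality: only the connected face
patch within 3 local radii of the plane point participates, so the
infinite plane cannot clip unrelated branches. Crossing triangles are split
exactly on the plane (vertices within 1e-9 of the bounding-box scale are
snapped); two guards reject bad planes: the removed area must be the minor
share of the local patch, and every new boundary edge must lie in the
plane (otherwise the removed region was unbounded, i.e. the normal pointed
inward).

Caps are built from concentric rings of Steiner points shrinking linearly
to the loop centroid, connected by triangle strips and a centre fan; the
ring count matches the mean rim edge length, so cap element sizes match
the adjacent wall density (never a single fan). This construction is
watertight by design for the star-shaped cross-sections terminal slicing
produces; strongly non-convex openings would need a constrained
triangulation and are out of scope.

Wall faces get label 1; caps get 2..K+1 sorted lexicographically by
centroid, making labels deterministic across runs. The manifest (one text
line per surface: label, kind, centroid, outward normal, area, condition)
is the hand-off to the solvers; the default condition rule marks the
largest-area cap as the inlet and the rest as outlets, and is configurable.

## Meshing

The sizing field is `h(v) = clamp(k r_nn(v), h_min, h_max)` with `r_nn`
the radius of the nearest skeleton node; default k = 0.5 (~4 elements per
diameter). Grading is realized as a spatially varying isotropic size, not
metric-tensor anisotropy.

Two meshing strategies:

* **delaunay** — nodes are all shell vertices (unperturbed) plus interior
  points from octave-level lattices matched to the local sizing, jittered
  deterministically (seeded) to avoid degenerate cospherical
  configurations, with clearance ~0.7 h from the surfaces. A scipy
  Delaunay triangulation is filtered by even-odd containment signatures
  per closed shell; region seeds map signatures to region ids, hole seeds
  mark signatures to drop. Because no interior point enters a cavity, all
  facets bounding a cavity connect surface vertices only: cavity
  interfaces pass exactly through the input surface vertices, which is
  what makes the 3D–1D interface transfer exact. Quality: point spacing
  keeps radius-edge ratios reasonable, but no Steiner refinement is
  performed, so slivers can occur; the `quality` parameter is advisory.
* **lattice** — a rectilinear grid with planes snapped to axis-aligned
  shell faces, six tetrahedra per cell (Freudenthal). Box volumes are
  partitioned exactly (sum of tet volumes = box volume to rounding), and
  multi-domain interfaces on axis-aligned planes are conforming with no
  straddling element. Chosen automatically when every shell is a box.

Boundary and interface facets inherit the label of the geometrically
nearest input face. MSH v2 ASCII files carry boundary labels and region
ids as physical/geometric tags and round-trip losslessly (`repr` float
serialization); legacy VTK and ASCII XDMF are write-only visualization /
interchange targets.

## Finite elements

P1 and P2 Lagrange spaces on affine tetrahedra. Quadrature is a Duffy
(collapsed-cube) transform of tensor Gauss–Legendre rules (3 points per
axis by default), exact for all polynomial forms used; P2 reproduces
quadratic manufactured solutions to solver precision (~1e-14) and P1
converges at order 2.000 in L2. Dirichlet conditions are applied by
elimination; systems are solved by direct sparse LU (SuperLU), giving
residuals at machine precision — appropriate at desk scale (<= ~1e5 dofs),
with iterative solvers an obvious extension point.

**ADR.** Implicit-Euler Galerkin stepping of
`dc/dt = div(D grad c) - div(u c) + s - k c` with the advective form of
the transport term; with closed boundaries, zero reaction and pure
diffusion, total mass `1^T M c` is conserved identically because
`K 1 = 0`. Optional SUPG stabilization adds the streamline terms with
`tau = h / (2 |u|)` consistently to the mass, transport and source
operators (an inconsistent splitting of these terms is unstable). The
implicit-Euler decay bias at dt = 1e-3 over unit time is ~5e-4 relative.

**IPCS Navier–Stokes.** The incremental pressure-correction splitting:

1. tentative velocity from the semi-implicit momentum equation —
   Crank–Nicolson midpoint for the full stress `2 mu eps(u)`, explicit
   convection `rho (u^n . grad) u^n`, and the open-boundary terms
   `int p n . v ds - mu int (grad u n) . v ds` so that a prescribed
   pressure at an open boundary acts as the physical traction;
2. pressure correction: `(grad p^{n+1}, grad q) = (grad p^n, grad q)
   - (rho/dt)(div u*, q)` with pressure Dirichlet values at open labels;
3. projection: `M u^{n+1} = M u* - (dt/rho) G (p^{n+1} - p^n)`.

All matrices are factorized once; each step costs three triangular solves
plus convection assembly. Equal-order P1–P1 is the default: in this
splitting the pressure is obtained from a Poisson problem, not a saddle
point, so no inf-sup stabilization term is needed (pressure checkerboard
modes are not representable in the discrete pressure Laplacian).
Taylor–Hood P2–P1 is available through the same generic assembler.
Explicit convection imposes a CFL-type step restriction `u dt / h < ~1`;
the per-step L2 norm of the discrete divergence decreases from u* to
u^{n+1} at every projection, which the solver records. Benchmarks: plane
Poiseuille (pressure-driven slab, slip side walls) recovers the analytic
peak `dp H^2 / (8 mu L)` within ~1%; pipe Poiseuille recovers
`dp R^2 / (4 mu L)` within ~4% at h = R/6, with inlet/outlet fluxes
balancing to ~1%.

Boundary-condition types: `noslip`, `velocity` (constant or `f(x, t)`,
e.g. a parabolic profile scaled by a time waveform), `velocity_component`
(for symmetry/slip planes), `pressure` (which also marks the label as an
open boundary), `open`.

## 3D–1D coupling

Nodal pressures solve the Kirchhoff system with Poiseuille edge
conductances `G = pi r^4 / (8 mu L)` (r = mean endpoint radius); edge
flows are `Q = G dp`. Steady network transport upwinds the advective flux
by the sign of Q with axial diffusion `D A / L` and Dirichlet inlets. The
1D field is projected onto the reconstructed surface by nearest centreline
node (ties broken by lowest index) and exported as an `x y z value` table.
Because the hollowed tissue mesh's cavity boundary passes exactly through
the vessel surface vertices, consuming that table as interface Dirichlet
data needs no interpolation: the exact-match fast path assigns the
projected values bit-for-bit. Coupling is one-way (vessel to tissue);
two-way exchange and time-dependent intravascular fields are out of scope.

## Pipeline, determinism, problem sizes

All randomness (tree jitter, mesh point jitter, noise fixtures) flows from
one seed recorded in the run report; reports separate timings from
diagnostics so two seeded runs are byte-identical apart from the timing
block. Every stage validates its output (watertightness, positive volumes,
label coverage) before the next starts and failures abort with the stage
name, keeping partial artefacts.

Default fixture scales are desk-sized deliberately: reconstruction grids of
~10^5–10^6 voxels, surfaces of 2k–20k vertices, tet meshes of 5k–50k
elements, and flow benchmarks of ~50–150 time steps, which keep the full
test suite and the acceptance script in the minutes range on one CPU while
staying in the asymptotic regime the convergence checks need. The same
code paths scale to larger problems, at the cost of the direct solvers'
memory growth and the Python-loop portions of remeshing/thinning.

## Known limitations

* The tet mesher guarantees conformity and exact cavity interfaces but not
  a dihedral-angle bound; FEM on its meshes is validated by the benchmark
  solutions rather than by element-quality certificates.
* Exterior Delaunay boundaries re-triangulate the input shell's vertex
  set; very coarse shells (e.g. an 8-vertex box) should be subdivided
  before meshing or solved on the lattice mesher.
* The thinning loop is sequential Python: fine for 1e4–1e5 foreground
  voxels, slow beyond.
* Hole repair and cap sealing assume quasi-planar, star-shaped openings.
* No turbulence, compressibility, fluid–structure interaction, or
  lumped-parameter outflow models; the flow solvers target laminar
  regimes.
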