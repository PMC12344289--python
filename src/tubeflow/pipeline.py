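"""Configuration-driven orchestration of the full pipeline.

One config file drives: reconstruct (graph/image/surface -> watertight
surface) -> process (remesh + smooth) -> skeletonize (thinning + graph +
ray-traced terminal extension) -> label (slice/seal/label + BC manifest)
-> size -> mesh (tetrahedra) -> convert (MSH/VTK/XDMF) -> solve (Poisson /
ADR / Navier-Stokes) -> export.  Every stage validates its output before
the next starts, all randomness flows from one recorded seed, and a
machine-readable JSON report collects per-stage counts and diagnostics
(timings are kept in a separate block so reports are reproducible).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import yaml

from . import fem, labelling, meshing, skeleton as skel
from .fixtures import box_surface
from .graph import SpatialGraph, make_synthetic_tree, read_graph, summarize, write_graph
from .image import (VoxelImage, extract_isosurface, normalized_distance_field,
                    read_image, surface_from_labelmap)
from .labelling import slice_and_label, write_bc_manifest
from .meshing import convert_mesh, sizing_field_from_radii, tetrahedralize, boundary_tags
from .surface import (TriSurface, diagnose, is_watertight, read_surface,
                      remesh_isotropic, repair_watertight, smooth_hc, write_surface)

logger = logging.getLogger("tubeflow")

__all__ = ["PipelineConfig", "run_pipeline", "make_case_fixture", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; mirrors one row of a per-case parameter summary."""

    # exactly one input kind
    graph_file: str | None = None
    image_file: str | None = None
    surface_file: str | None = None
    output_dir: str = "tubeflow_out"
    seed: int = 0
    # reconstruction
    spacing: float = 0.3
    image_label: int = 1
    # surface processing
    remesh_target_points: int | None = None
    remesh_edge_length: float | None = None
    smooth_steps: int = 10
    smooth_alpha: float = 0.1
    smooth_beta: float = 0.6
    # skeleton
    skeleton_resolution: float = 0.0
    prune_length: float = 0.0
    filter_length: float = 0.0
    # labelling
    cap_pullback: float = 1.0
    # sizing / meshing
    sizing_k: float = 0.5
    h_min: float = 0.1
    h_max: float = 1.0
    mesh_method: str = "delaunay"
    quality: float = 1.6
    # solver
    solve: str = "none"  # none | poisson | adr | ns
    solver: dict = dfield(default_factory=dict)
    # stage toggles
    stages: list = dfield(default_factory=lambda: [
        "reconstruct", "process", "skeletonize", "label", "size", "mesh",
        "convert", "solve", "export"])

    def validate(self) -> None:
        inputs = [self.graph_file, self.image_file, self.surface_file]
        if sum(x is not None for x in inputs) != 1:
            raise ValueError("config must name exactly one input "
                             "(graph_file | image_file | surface_file)")
        for f in inputs:
            if f is not None and not Path(f).exists():
                raise ValueError(f"input file not found: {f}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "timings": {}}
    state: dict = {}

    def stage(name):
        return name in cfg.stages

    def record(name, t0, **info):
        report["stages"][name] = info
        report["timings"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-12s %s", name, info)

    try:
        # ---------------- reconstruct ----------------
        t0 = time.perf_counter()
        if cfg.graph_file:
            g = read_graph(cfg.graph_file)
            state["input_graph"] = g
            if stage("reconstruct"):
                phi = normalized_distance_field(g, cfg.spacing)
                surf = extract_isosurface(phi, 1.0)
                state["surface"] = surf
                record("reconstruct", t0, method="level-set",
                       n_vertices=surf.n_vertices, n_faces=surf.n_faces,
                       watertight=is_watertight(surf))
        elif cfg.image_file:
            img = read_image(cfg.image_file)
            if stage("reconstruct"):
                surf = surface_from_labelmap(img, cfg.image_label)
                state["surface"] = surf
                record("reconstruct", t0, method="marching-cubes",
                       n_vertices=surf.n_vertices, n_faces=surf.n_faces,
                       watertight=is_watertight(surf))
        else:
            surf = read_surface(cfg.surface_file)
            state["surface"] = surf
            record("reconstruct", t0, method="load",
                   n_vertices=surf.n_vertices, n_faces=surf.n_faces,
                   watertight=is_watertight(surf))
        surf = state.get("surface")
        if surf is not None and not is_watertight(surf):
            raise RuntimeError("reconstruction did not produce a watertight surface")

        # ---------------- process ----------------
        if stage("process") and surf is not None:
            t0 = time.perf_counter()
            if cfg.remesh_target_points:
                surf = remesh_isotropic(surf, target_points=cfg.remesh_target_points)
            elif cfg.remesh_edge_length:
                surf = remesh_isotropic(surf, target_edge_length=cfg.remesh_edge_length)
            surf = smooth_hc(surf, cfg.smooth_steps, cfg.smooth_alpha, cfg.smooth_beta)
            if not is_watertight(surf):
                surf = repair_watertight(surf)
            d = diagnose(surf)
            state["surface"] = surf
            write_surface(surf, out / "surface.ply")
            record("process", t0, n_vertices=surf.n_vertices,
                   watertight=is_watertight(surf),
                   area_cv=round(d.triangle_area_cv, 4),
                   enclosed_volume=round(d.enclosed_volume, 6))

        # ---------------- skeletonize ----------------
        if stage("skeletonize"):
            t0 = time.perf_counter()
            res = cfg.skeleton_resolution or cfg.spacing
            binary = skel.rebinarize_surface(surf, res)
            sk = skel.skeletonize_binary(binary)
            dist = skel.distance_map(binary)
            params = skel.SkeletonParams(cfg.prune_length, cfg.filter_length, res)
            g2 = skel.skeleton_to_graph(sk, params, dist)
            g2 = skel.extend_terminals_raytrace(g2, surf)
            state["skeleton"] = g2
            write_graph(g2, str(out / "skeleton.vtk"))
            s = summarize(g2)
            record("skeletonize", t0, n_nodes=s.n_nodes, n_edges=s.n_edges,
                   n_terminals=s.n_terminals, n_bifurcations=s.n_bifurcations,
                   total_length=round(s.total_length, 6))
        g_skel = state.get("skeleton", state.get("input_graph"))

        # ---------------- label ----------------
        if stage("label"):
            t0 = time.perf_counter()
            labelled, manifest, caps = slice_and_label(surf, g_skel,
                                                       pullback=cfg.cap_pullback)
            if not is_watertight(labelled):
                raise RuntimeError("labelled surface lost watertightness")
            state["surface"] = surf = labelled
            state["manifest"] = manifest
            write_bc_manifest(manifest, out / "boundary_conditions.txt")
            write_surface(labelled, out / "labelled_surface.ply")
            record("label", t0, n_labels=int(len(manifest.records)),
                   n_caps=len(caps),
                   watertight=is_watertight(labelled))

        # ---------------- size ----------------
        sizing = None
        if stage("size") and g_skel is not None:
            t0 = time.perf_counter()
            sizing = sizing_field_from_radii(surf, g_skel, cfg.sizing_k,
                                             cfg.h_min, cfg.h_max)
            record("size", t0, h_min=float(sizing.values.min()),
                   h_max=float(sizing.values.max()))

        # ---------------- mesh ----------------
        mesh = None
        if stage("mesh"):
            t0 = time.perf_counter()
            mesh = tetrahedralize(surf, sizing=sizing, quality=cfg.quality,
                                  method=cfg.mesh_method, seed=cfg.seed)
            if np.any(mesh.tet_volumes() <= 0):
                raise RuntimeError("mesher produced non-positive tetrahedra")
            state["mesh"] = mesh
            record("mesh", t0, n_nodes=mesh.n_nodes, n_tets=mesh.n_tets,
                   volume=round(mesh.volume(), 6),
                   boundary_labels={str(k): v[0] for k, v in
                                    boundary_tags(mesh).items()})

        # ---------------- convert ----------------
        if stage("convert") and mesh is not None:
            t0 = time.perf_counter()
            convert_mesh(mesh, out / "mesh.msh")
            convert_mesh(mesh, out / "mesh.vtk")
            convert_mesh(mesh, out / "mesh.xdmf")
            record("convert", t0, formats=["msh2-ascii", "vtk", "xdmf"])

        # ---------------- solve ----------------
        if stage("solve") and cfg.solve != "none" and mesh is not None:
            t0 = time.perf_counter()
            info = _run_solver(cfg, mesh, state, out)
            record("solve", t0, **info)

        report["ok"] = True
    except Exception as exc:
        report["ok"] = False
        report["error"] = {"stage": _last_stage(report), "message": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _last_stage(report):
    stages = list(report["stages"])
    return stages[-1] if stages else "init"


def _bc_from_manifest(manifest, solver_cfg, mode):
    """Translate manifest conditions into solver boundary tables."""
    bc = {}
    for r in manifest.records:
        if mode == "ns":
            if r.condition == "noslip" or r.kind == "wall":
                bc[r.label] = {"type": "noslip"}
            elif r.condition == "inlet":
                bc[r.label] = {"type": "pressure",
                               "value": float(solver_cfg.get("inlet_pressure", 1.0))}
            else:
                bc[r.label] = {"type": "pressure",
                               "value": float(solver_cfg.get("outlet_pressure", 0.0))}
        else:
            if r.condition == "inlet":
                bc[r.label] = {"dirichlet": float(solver_cfg.get("inlet_value", 1.0))}
            elif r.condition == "outlet":
                bc[r.label] = {"dirichlet": float(solver_cfg.get("outlet_value", 0.0))}
    return bc


def _run_solver(cfg, mesh, state, out) -> dict:
    sc = cfg.solver
    manifest = state.get("manifest")
    if cfg.solve == "poisson":
        bc = _bc_from_manifest(manifest, sc, "scalar") if manifest else \
            {int(k): {"dirichlet": float(v)} for k, v in sc.get("dirichlet", {}).items()}
        f = fem.solve_poisson(mesh, float(sc.get("D", 1.0)),
                              float(sc.get("source", 0.0)), bc)
        meshing.write_vtk_fields(mesh, out / "solution_000.vtk",
                                 {"c": f.values})
        return {"model": "poisson", "min": float(f.values.min()),
                "max": float(f.values.max())}
    if cfg.solve == "ns":
        bc = _bc_from_manifest(manifest, sc, "ns")
        cfgs = fem.SolverConfig(dt=float(sc.get("dt", 0.01)),
                                T=float(sc.get("T", 1.0)),
                                element_order=sc.get("element_order", "p1-p1"),
                                bc_table=bc,
                                steady_tol=float(sc.get("steady_tol", 0.0)))
        props = fem.FluidProperties(float(sc.get("rho", 1.0)),
                                    float(sc.get("mu", 1.0)))
        states = fem.solve_ns_ipcs(mesh, props, cfgs,
                                   store_every=int(sc.get("store_every", 0)))
        for i, st in enumerate(states):
            meshing.write_vtk_fields(mesh, out / f"solution_{i:03d}.vtk",
                                     {"u": st.u.values[:mesh.n_nodes],
                                      "p": st.p.values[:mesh.n_nodes]})
        st = states[-1]
        fluxes = {}
        if manifest:
            for r in manifest.records:
                if r.kind == "cap":
                    fluxes[str(r.label)] = fem.boundary_flux(st, mesh, r.label)
        umax = float(np.linalg.norm(st.u.values, axis=1).max())
        return {"model": "navier-stokes", "n_steps": len(st.divergence_history),
                "u_max": umax,
                "flux_sum": float(sum(fluxes.values())) if fluxes else None,
                "cap_fluxes": {k: float(v) for k, v in fluxes.items()}}
    raise ValueError(f"unknown solver {cfg.solve!r}")


# ---------------------------------------------------------------------------
# Case fixtures
# ---------------------------------------------------------------------------

def make_case_fixture(name: str, seed: int = 0, outdir="fixture") -> dict:
    """Write the input files + reference config for a named synthetic case.

    ``cylinder`` — a 2-node straight vessel (smoke test);
    ``y_tree`` — one bifurcation, sliced/labelled and tet-meshed;
    ``tree_g3`` — a 3-generation tree with radius-driven graded meshing;
    ``vessel_in_box`` — an embedded straight vessel for the 3D-1D pattern.
    Returns {"config": path, "graph": path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gpath = outdir / "network.csv"
    cpath = outdir / "config.yaml"
    common = dict(graph_file=str(gpath), output_dir=str(outdir / "out"), seed=seed)
    if name == "cylinder":
        g = SpatialGraph(np.array([[0, 0, 0], [0, 0, 10.0]]),
                         np.array([1.5, 1.5]), np.array([[0, 1]]))
        cfgd = dict(common, spacing=0.3, remesh_edge_length=0.35, smooth_steps=8,
                    prune_length=2.0, sizing_k=0.5, h_min=0.25, h_max=0.8)
    elif name == "y_tree":
        g = make_synthetic_tree(1, root_radius=1.0, ratio=0.8,
                                branch_length=8.0, seed=seed)
        cfgd = dict(common, spacing=0.25, remesh_edge_length=0.3, smooth_steps=10,
                    prune_length=2.0, sizing_k=0.5, h_min=0.2, h_max=0.6)
    elif name == "tree_g3":
        g = make_synthetic_tree(3, root_radius=1.0, ratio=0.75,
                                branch_length=7.0, seed=seed)
        cfgd = dict(common, spacing=0.2, remesh_edge_length=0.25, smooth_steps=6,
                    prune_length=1.5, sizing_k=0.5, h_min=0.15, h_max=0.8)
    elif name == "vessel_in_box":
        g = SpatialGraph(np.array([[0, 0, -6], [0, 0, 6.0]]),
                         np.array([1.0, 1.0]), np.array([[0, 1]]))
        cfgd = dict(common, spacing=0.4,
                    stages=["reconstruct"])  # meshing handled by run_3d1d_case
        cfgd["solver"] = {"box_lo": [-6, -6, -9], "box_hi": [6, 6, 9]}
    else:
        raise ValueError(f"unknown fixture {name!r}")
    write_graph(g, gpath)
    with open(cpath, "w") as fh:
        yaml.safe_dump(cfgd, fh, sort_keys=True)
    return {"config": str(cpath), "graph": str(gpath)}
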