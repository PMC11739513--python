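"""End-to-end pipeline: generate -> calibrate/solve -> perfuse -> sweep.

A *bundle* is one run directory::

    manifest.json     provenance (config, seed, package version)
    geometry/         organ surface (ASCII STL) + super-lobule partition
    trees/            inlet/outlet trees (JSON + VTK legacy polylines)
    network/          element arrays of the flow network
    flow/             calibrated solution (CSV per element, JSON summary)
    perfusion/        loading curves (CSV) + threshold summary (JSON)
    sweep/            boundary-condition grid report (CSV)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import HepavascError
from .geometry import (
    SuperLobulePartition,
    VolumeBudget,
    VolumeModel,
    compute_volume_budget,
    load_stl,
    partition_super_lobules,
    sample_interior,
    synthetic_ellipsoid,
)
from .growth import (
    AttractorSet,
    ConnectedNetworkTopology,
    GrowthParams,
    VascularTree,
    connect_trees,
    grow_tree,
    initialize_major_branches,
    prune_tree,
)
from .hemodynamics import (
    ML_MIN_TO_MM3_S,
    MMHG_TO_DYN_MM2,
    SUPER_LOBULE,
    BoundaryConditions,
    Fluid,
    FlowNetwork,
    FlowSolution,
    RadiusPolicy,
    build_network,
    find_sl_resistance,
    solve_flow,
)
from .perfusion import LoadingResult, simulate_loading

__all__ = [
    "ModelBundle",
    "generate_model",
    "solve_bundle",
    "perfuse_bundle",
    "sweep_bundle",
    "save_bundle",
    "load_bundle",
    "write_flow_outputs",
    "write_perfusion_outputs",
    "export_tree_vtk",
]


@dataclass
class ModelBundle:
    """Everything produced by the generation stage."""

    config: RunConfig
    model: VolumeModel
    partition: SuperLobulePartition
    inlet_tree: VascularTree
    outlet_tree: VascularTree
    topology: ConnectedNetworkTopology
    network: FlowNetwork
    budget: VolumeBudget


def _stage(name):
    """Decorator: re-raise package errors with the failing stage named."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except HepavascError as err:
                raise type(err)(f"[stage: {name}] {err}") from err

        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner

    return wrap


def _resolve_primary(cfg, model: VolumeModel):
    """Primary roots/targets in mm, resolving relative coordinates."""
    p = cfg.primary
    if p.relative:
        c = model.centroid
        half = 0.5 * (model.bounds[1] - model.bounds[0])

        def to_mm(frac):
            return c + np.asarray(frac, dtype=float) * half

    else:

        def to_mm(frac):
            return np.asarray(frac, dtype=float)

    diag = float(np.linalg.norm(model.bounds[1] - model.bounds[0]))
    params = GrowthParams(
        D=p.D if p.D is not None else cfg.growth.D,
        d_k=p.d_k if p.d_k is not None else cfg.growth.d_k,
        d_i=p.d_i if p.d_i is not None else diag,
        max_iterations=cfg.growth.max_iterations,
    )
    return {
        "inlet": (to_mm(p.inlet_root), np.array([to_mm(t) for t in p.inlet_targets])),
        "outlet": (to_mm(p.outlet_root), np.array([to_mm(t) for t in p.outlet_targets])),
    }, params


@_stage("generate")
def generate_model(config: RunConfig) -> ModelBundle:
    """Run geometry, partition, two-stage growth, pruning and network build."""
    g = config.geometry
    if g.mesh_path:
        model = load_stl(g.mesh_path, target_volume=g.target_volume_ml * 1e3)
    else:
        model = synthetic_ellipsoid(
            target_volume=g.target_volume_ml * 1e3, ratios=tuple(g.ellipsoid_ratios)
        )

    cloud = sample_interior(model, g.cloud_size, seed=config.seed)
    partition = partition_super_lobules(
        cloud, g.n_super_lobules, seed=config.seed
    )

    primary, primary_params = _resolve_primary(config, model)
    growth_params = GrowthParams(**dataclasses.asdict(config.growth))
    trees = {}
    for label, seed_off in (("inlet", 1), ("outlet", 2)):
        root, targets = primary[label]
        tree = initialize_major_branches(
            model, label, root, targets, primary_params, seed=config.seed + seed_off
        )
        attr = AttractorSet.build(cloud.points, partition.centroids)
        tree = grow_tree(
            attr,
            growth_params,
            tree=tree,
            label=label,
            seed=config.seed + seed_off,
            cap_terminals=True,
        )
        trees[label] = prune_tree(tree)

    topology = connect_trees(trees["inlet"], trees["outlet"], partition.k)

    fluid = Fluid(mu_cP=config.flow.mu_cP)
    policy = RadiusPolicy(
        gamma=config.flow.gamma,
        r_root_inlet=config.flow.root_diameter_mm / 2.0,
        r_root_outlet=config.flow.root_diameter_mm / 2.0,
    )
    network = build_network(topology, policy, fluid)
    budget = compute_volume_budget(
        V_blood=g.blood_volume_fraction * model.volume,
        V_vessels=float(network.vessel_volumes[network.kind != SUPER_LOBULE].sum()),
        n_SL=partition.k,
    )
    network.sl_volume = budget.V_SL_individual
    partition.V_SL_individual = budget.V_SL_individual

    return ModelBundle(
        config=config,
        model=model,
        partition=partition,
        inlet_tree=trees["inlet"],
        outlet_tree=trees["outlet"],
        topology=topology,
        network=network,
        budget=budget,
    )


@_stage("solve")
def solve_bundle(
    bundle: ModelBundle, bc: BoundaryConditions | None = None
) -> FlowSolution:
    """Calibrate R_SL by bisection, then solve the pressure-driven system."""
    f = bundle.config.flow
    if bc is None:
        bc = BoundaryConditions.clinical(
            P_in_mmHg=f.P_in_mmHg,
            P_out_mmHg=f.P_out_mmHg,
            Q_target_ml_min=f.Q_target_ml_min,
        )
    fluid = Fluid(mu_cP=f.mu_cP)
    r_sl = find_sl_resistance(
        bundle.network,
        bc,
        tol=f.bisect_tol,
        bounds=(0.0, f.bisect_upper),
        fluid=fluid,
    )
    return solve_flow(bundle.network, bc, r_sl, drive="pressure", fluid=fluid)


@_stage("perfuse")
def perfuse_bundle(
    bundle: ModelBundle,
    solution: FlowSolution,
    dt: float | None = None,
) -> LoadingResult:
    p = bundle.config.perfusion
    return simulate_loading(
        bundle.network,
        solution,
        dt=p.dt_s if dt is None else dt,
        thresholds=tuple(p.thresholds),
        t_max=p.t_max_s,
        scheme=p.scheme,
        inlet_concentration=p.inlet_concentration,
    )


@_stage("sweep")
def sweep_bundle(
    bundle: ModelBundle,
    pressures_mmHg=None,
    flows_ml_min=None,
    with_loading: bool = True,
) -> pd.DataFrame:
    """Grid report over boundary conditions.

    One row per (dP, Q) cell with the calibrated R_SL (NaN + infeasible flag
    where no non-negative R_SL admits the flow), the maximum wall shear
    stress over vessel segments, and — when `with_loading` — the total and
    last-super-lobule times to 90% CPA concentration.
    """
    cfg = bundle.config
    pressures = pressures_mmHg or cfg.sweep.pressures_mmHg
    flows = flows_ml_min or cfg.sweep.flows_ml_min
    fluid = Fluid(mu_cP=cfg.flow.mu_cP)
    rows = []
    for dp in pressures:
        for q in flows:
            bc = BoundaryConditions.clinical(
                P_in_mmHg=dp, P_out_mmHg=0.0, Q_target_ml_min=q
            )
            row = {"dP_mmHg": dp, "Q_ml_min": q}
            try:
                r_sl = find_sl_resistance(
                    bundle.network,
                    bc,
                    tol=cfg.flow.bisect_tol,
                    bounds=(0.0, cfg.flow.bisect_upper),
                    fluid=fluid,
                )
            except HepavascError:
                row.update(
                    infeasible=True,
                    R_SL=np.nan,
                    max_wss_dyn_mm2=np.nan,
                    t90_total_s=np.nan,
                    t90_last_sl_s=np.nan,
                )
                rows.append(row)
                continue
            sol = solve_flow(bundle.network, bc, r_sl, fluid=fluid)
            row.update(
                infeasible=False,
                R_SL=r_sl,
                max_wss_dyn_mm2=float(np.nanmax(sol.wall_shear())),
            )
            if with_loading:
                res = perfuse_bundle(bundle, sol)
                row["t90_total_s"] = res.times_total.get(0.9, np.nan)
                row["t90_last_sl_s"] = res.times_last_sl.get(0.9, np.nan)
            else:
                row["t90_total_s"] = np.nan
                row["t90_last_sl_s"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle persistence


def _tree_to_dict(tree: VascularTree) -> dict:
    return {
        "label": tree.label,
        "positions": tree.positions.tolist(),
        "parents": tree.parents.tolist(),
        "terminal_map": {str(k): int(v) for k, v in tree.terminal_map.items()},
        "n_fixed": int(tree.n_fixed),
    }


def _tree_from_dict(d: dict) -> VascularTree:
    return VascularTree(
        positions=np.asarray(d["positions"], dtype=float),
        parents=np.asarray(d["parents"], dtype=np.int64),
        label=d["label"],
        terminal_map={int(k): int(v) for k, v in d["terminal_map"].items()},
        n_fixed=int(d["n_fixed"]),
    )


def export_tree_vtk(tree: VascularTree, path) -> None:
    """VTK legacy polyline export (one 2-point line per edge)."""
    edges = tree.edges
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"hepavasc {tree.label} tree\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {tree.n_nodes} float\n")
        for p in tree.positions:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"LINES {len(edges)} {3 * len(edges)}\n")
        for a, b in edges:
            fh.write(f"2 {a} {b}\n")


def save_bundle(bundle: ModelBundle, out_dir) -> Path:
    out = Path(out_dir)
    for sub in ("geometry", "trees", "network"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    manifest = {
        "package": "hepavasc",
        "version": __version__,
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "n_super_lobules": bundle.partition.k,
        "n_vessels": bundle.network.j,
        "matrix_size": bundle.network.n,
        "cluster_size_cv": bundle.partition.size_cv,
        "volume_budget": dataclasses.asdict(bundle.budget),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    from trimesh.exchange.stl import export_stl_ascii

    (out / "geometry" / "model.stl").write_text(
        export_stl_ascii(bundle.model.mesh)
    )
    (out / "geometry" / "partition.json").write_text(
        json.dumps(
            {
                "k": bundle.partition.k,
                "centroids": bundle.partition.centroids.tolist(),
                "assignment": bundle.partition.assignment.tolist(),
                "V_SL_individual": bundle.partition.V_SL_individual,
            }
        )
    )
    for tree in (bundle.inlet_tree, bundle.outlet_tree):
        (out / "trees" / f"{tree.label}.json").write_text(
            json.dumps(_tree_to_dict(tree))
        )
        export_tree_vtk(tree, out / "trees" / f"{tree.label}.vtk")

    net = bundle.network
    (out / "network" / "network.json").write_text(
        json.dumps(
            {
                "prox": net.prox.tolist(),
                "dist": net.dist.tolist(),
                "kind": net.kind.tolist(),
                "L": net.L.tolist(),
                "r": net.r.tolist(),
                "R": net.R.tolist(),
                "n_nodes": net.n_nodes,
                "inlet_node": net.inlet_node,
                "outlet_node": net.outlet_node,
                "sl_volume": net.sl_volume,
                "node_positions": net.node_positions.tolist(),
            }
        )
    )
    return out


def load_bundle(out_dir) -> ModelBundle:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    config = RunConfig.from_dict(manifest["config"])
    model = load_stl(out / "geometry" / "model.stl")
    part = json.loads((out / "geometry" / "partition.json").read_text())
    partition = SuperLobulePartition(
        k=part["k"],
        centroids=np.asarray(part["centroids"], dtype=float),
        assignment=np.asarray(part["assignment"], dtype=np.int64),
        V_SL_individual=part["V_SL_individual"],
    )
    inlet = _tree_from_dict(json.loads((out / "trees" / "inlet.json").read_text()))
    outlet = _tree_from_dict(json.loads((out / "trees" / "outlet.json").read_text()))
    nd = json.loads((out / "network" / "network.json").read_text())
    network = FlowNetwork(
        prox=np.asarray(nd["prox"], dtype=np.int64),
        dist=np.asarray(nd["dist"], dtype=np.int64),
        kind=np.asarray(nd["kind"], dtype=np.int64),
        L=np.asarray(nd["L"], dtype=float),
        r=np.asarray(nd["r"], dtype=float),
        R=np.asarray(nd["R"], dtype=float),
        n_nodes=nd["n_nodes"],
        inlet_node=nd["inlet_node"],
        outlet_node=nd["outlet_node"],
        sl_volume=nd["sl_volume"],
        node_positions=np.asarray(nd["node_positions"], dtype=float),
    )
    budget = VolumeBudget(**manifest["volume_budget"])
    topology = ConnectedNetworkTopology(
        inlet=inlet, outlet=outlet, n_sl=partition.k
    )
    return ModelBundle(
        config=config,
        model=model,
        partition=partition,
        inlet_tree=inlet,
        outlet_tree=outlet,
        topology=topology,
        network=network,
        budget=budget,
    )


def write_flow_outputs(solution: FlowSolution, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = solution.network
    tau = solution.wall_shear() if solution.fluid is not None else np.full(
        net.n_elements, np.nan
    )
    pd.DataFrame(
        {
            "element": np.arange(net.n_elements),
            "kind": np.where(net.kind == SUPER_LOBULE, "super_lobule", "vessel"),
            "prox_node": net.prox,
            "dist_node": net.dist,
            "L_mm": net.L,
            "r_mm": net.r,
            "R_dyn_s_mm5": np.where(
                net.kind == SUPER_LOBULE, solution.R_SL, net.R
            ),
            "Q_ml_min": solution.Q / ML_MIN_TO_MM3_S,
            "wss_dyn_mm2": tau,
        }
    ).to_csv(out / "elements.csv", index=False)
    pd.DataFrame(
        {
            "node": np.arange(net.n_nodes),
            "P_mmHg": solution.P / MMHG_TO_DYN_MM2,
        }
    ).to_csv(out / "nodes.csv", index=False)
    (out / "summary.json").write_text(json.dumps(solution.summary(), indent=1))


def write_perfusion_outputs(result: LoadingResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"t_s": result.t, "total_C": result.total_C}
    for i in range(result.sl_C.shape[1]):
        cols[f"SL{i}_C"] = result.sl_C[:, i]
    pd.DataFrame(cols).to_csv(out / "loading.csv", index=False)
    summary = {
        "dt_s": result.dt,
        "converged": bool(result.converged),
        "times_total_s": {f"{th:g}": result.times_total[th] for th in result.thresholds},
        "times_last_sl_s": {
            f"{th:g}": result.times_last_sl[th] for th in result.thresholds
        },
        "max_balance_error": float(np.nanmax(result.balance_error())),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
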