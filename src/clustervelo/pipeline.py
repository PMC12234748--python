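"""End-to-end pipeline: preprocessing through embedding velocities.

Stages run in the order the method is defined: preprocess and cluster,
build and prune the cluster graph, score terminal states and pick the
origin, select the main path, orient it with the gene-level orientation
scores (possibly resetting the origin), assign levels/children on the full
graph, build directed neighborhoods, estimate velocities, and project them
onto the embedding. Disconnected cluster graphs are processed per component
with independent origins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cluster_graph as cg
from . import main_path as mp
from . import orientation as ori
from . import velocity as vel
from .datamodel import PipelineConfig, cluster_cells, preprocess, validate_dataset

logger = logging.getLogger("clustervelo")


@dataclass
class ComponentResult:
    clusters: list[str]
    initial_origin: str
    origin_rule: int
    path: mp.MainPath
    report: ori.OrientationReport
    final_origin: str


@dataclass
class RunResult:
    adata: object
    graph: cg.ClusterGraph                 # full graph
    pruned: cg.ClusterGraph
    components: list[ComponentResult]
    dg: vel.DirectedClusterGraph
    dnn: vel.DirectedNeighborhood
    field: vel.VelocityField
    vgraph: vel.VelocityGraph
    v_embed: np.ndarray | None


def run_pipeline(adata, cfg: PipelineConfig | None = None, mode: str = "fit",
                 backend: str = "ratio") -> RunResult:
    """Run the whole method on a dataset; results are also written back into
    the AnnData (layers ``velocity``/``velocity_u``, obs ``level`` and
    ``pseudotime_global``, obsm ``velocity_embed``, uns run report).

    ``mode``: ``simple_fit`` | ``fit`` | ``kinetic``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    adata = preprocess(adata, cfg)
    adata = cluster_cells(adata, cfg)
    validate_dataset(adata, require_clusters=True)

    g_full = cg.build_cluster_graph(adata, cfg, backend=backend)
    pruned = cg.prune_graph(g_full, cfg)
    pruned = cg.score_terminal_states(adata, pruned, cfg)
    comps = pruned.components or [pruned.nodes]

    comp_results: list[ComponentResult] = []
    level: dict[str, int] = {}
    children: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    dti_edges: list[tuple[str, str]] = []
    assignment = _assign_all_clusters(g_full, comps)
    for ci, comp in enumerate(comps):
        sub = pruned.subgraph(comp)
        sub = cg.select_origin(sub, cfg)
        path = mp.select_main_path(sub)
        report = ori.orient_main_path(adata, sub, path, cfg)
        oriented = ori.infer_new_origin(adata, sub, path, report, cfg)
        comp_results.append(ComponentResult(
            clusters=list(comp), initial_origin=sub.origin,
            origin_rule=sub.origin_rule, path=path, report=report,
            final_origin=oriented.origin))
        # levels/children on the full graph restricted to this component's
        # clusters (pruned clusters re-attached by strongest weight)
        full_members = [c for c in g_full.nodes if assignment[c] == ci]
        gsub = g_full.subgraph(full_members)
        gsub.origin = oriented.origin
        lv = vel.assign_levels(gsub, cfg)
        dgc = vel.assign_children(gsub, lv, cfg)
        level.update(lv)
        children.update(dgc.children)
        parent.update(dgc.parent)
        dti_edges.extend(dgc.dti_edges)

    base = g_full.subgraph(g_full.nodes)
    base.origin = comp_results[0].final_origin
    dg = vel.DirectedClusterGraph(base=base, level=level, children=children,
                                  parent=parent, dti_edges=sorted(dti_edges))
    dnn = vel.build_dnn(adata, dg, cfg)
    if mode == "simple_fit":
        vf = vel.simple_fit(adata, dnn, cfg)
    elif mode == "fit":
        vf = vel.fit(adata, dnn, cfg)
    elif mode == "kinetic":
        vf = vel.fit_kinetic(adata, dnn, cfg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    vg = vel.velocity_graph(adata, vf, cfg)
    v_embed = None
    if "X_embed" in adata.obsm:
        v_embed = vel.embedding_velocity(adata, vg)

    adata.layers["velocity"] = vf.v_s
    adata.layers["velocity_u"] = vf.v_u
    if vf.rates is not None:
        for name, r in zip(("alpha", "beta", "gamma"), vf.rates):
            adata.layers[f"rate_{name}"] = r
    adata.obs["pseudotime_global"] = dnn.pseudotime
    adata.obs["level"] = [level[c] for c in adata.obs["cluster"].astype(str)]
    if v_embed is not None:
        adata.obsm["velocity_embed"] = v_embed
    adata.uns["run_report"] = {
        "dti_edges": [list(e) for e in dg.dti_edges],
        "components": {
            f"component_{i}": {
                "clusters": list(r.clusters),
                "initial_origin": r.initial_origin,
                "origin_rule": int(r.origin_rule),
                "main_path": list(r.path.nodes),
                "mean_score": float(r.report.mean_score),
                "decision": r.report.decision,
                "final_origin": r.final_origin,
            } for i, r in enumerate(comp_results)},
    }
    return RunResult(adata=adata, graph=g_full, pruned=pruned,
                     components=comp_results, dg=dg, dnn=dnn, field=vf,
                     vgraph=vg, v_embed=v_embed)


def infer_direction(adata, cfg: PipelineConfig | None = None,
                    backend: str = "ratio") -> list[ComponentResult]:
    """Run the pipeline only as far as the corrected origin (no velocities).

    Useful for direction-recovery experiments where the cluster-level
    decision is the quantity of interest.
    """
    if cfg is None:
        cfg = PipelineConfig()
    adata = preprocess(adata, cfg)
    adata = cluster_cells(adata, cfg)
    g_full = cg.build_cluster_graph(adata, cfg, backend=backend)
    pruned = cg.prune_graph(g_full, cfg)
    pruned = cg.score_terminal_states(adata, pruned, cfg)
    comps = pruned.components or [pruned.nodes]
    out = []
    for comp in comps:
        sub = pruned.subgraph(comp)
        sub = cg.select_origin(sub, cfg)
        path = mp.select_main_path(sub)
        report = ori.orient_main_path(adata, sub, path, cfg)
        oriented = ori.infer_new_origin(adata, sub, path, report, cfg)
        out.append(ComponentResult(
            clusters=list(comp), initial_origin=sub.origin,
            origin_rule=sub.origin_rule, path=path, report=report,
            final_origin=oriented.origin))
    return out


def _assign_all_clusters(g_full: cg.ClusterGraph,
                         comps: list[list[str]]) -> dict[str, int]:
    """Attach every full-graph cluster (including pruned ones) to the
    component it is most strongly connected to."""
    assignment = {}
    for ci, comp in enumerate(comps):
        for c in comp:
            assignment[c] = ci
    pending = [c for c in g_full.nodes if c not in assignment]
    while pending:
        progress = False
        for c in list(pending):
            i = g_full.index(c)
            best, best_w = None, 0.0
            for other, ci in assignment.items():
                wv = g_full.weights[i, g_full.index(other)]
                if wv > best_w:
                    best, best_w = ci, wv
            if best is not None:
                assignment[c] = best
                pending.remove(c)
                progress = True
        if not progress:
            for c in pending:        # fully isolated clusters
                assignment[c] = 0
            break
    return assignment
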