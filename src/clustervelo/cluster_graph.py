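"""Cluster graph construction, pruning, terminal-state scoring, origin choice.

The cluster graph has one node per cell cluster, with symmetric edge weights
in [0, 1] measuring inter-cluster connectivity (PAGA-style). Pruning keeps
the large, well-connected core of the graph; terminal-state scores rank
clusters as likely roots or ends; the origin node is the terminal state the
main path will start from (possibly corrected later by the orientation step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .datamodel import PipelineConfig, knn_indices_to_adjacency

logger = logging.getLogger("clustervelo")


@dataclass
class ClusterGraph:
    """Weighted undirected graph over clusters.

    ``weights`` is symmetric with zero diagonal and entries in [0, 1];
    ``sizes`` holds the per-node cell counts N_i. ``components`` is set when
    pruning could not reconnect the graph, in which case downstream stages
    run per component.
    """

    nodes: list[str]
    sizes: np.ndarray
    weights: np.ndarray
    root_score: np.ndarray | None = None
    end_score: np.ndarray | None = None
    origin: str | None = None
    origin_rule: int | None = None
    components: list[list[str]] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.diag(w).any():
            raise ValueError("weights must have zero diagonal")
        if w.min() < 0 or w.max() > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def neighbors(self, node: str) -> list[str]:
        i = self.index(node)
        return [self.nodes[j] for j in np.nonzero(self.weights[i] > 0)[0]]

    def subgraph(self, keep: list[str]) -> "ClusterGraph":
        idx = [self.index(n) for n in keep]
        return ClusterGraph(
            nodes=list(keep), sizes=self.sizes[idx],
            weights=self.weights[np.ix_(idx, idx)],
            root_score=None if self.root_score is None else self.root_score[idx],
            end_score=None if self.end_score is None else self.end_score[idx],
            origin=self.origin if self.origin in keep else None,
            origin_rule=self.origin_rule)


def _graph_components(weights: np.ndarray) -> list[list[int]]:
    n = len(weights)
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix(weights > 0), directed=False)
    return [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_cluster_graph(adata, cfg: PipelineConfig | None = None,
                        backend: str = "ratio") -> ClusterGraph:
    """Connectivity weights between clusters from the cell kNN graph.

    backend ``"ratio"`` (default, self-contained): the observed number of
    inter-cluster kNN edges divided by its expectation were edge endpoints
    placed at random proportional to cluster sizes, rescaled by the maximum
    and clipped to [0, 1]. backend ``"paga"`` delegates to scanpy's PAGA
    connectivities on the same neighbor graph.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if "cluster" not in adata.obs:
        raise ValueError("cluster labels required: run cluster_cells first")
    labels = adata.obs["cluster"].astype(str).to_numpy()
    nodes = sorted(set(labels))
    if len(nodes) < 2:
        raise ValueError("cluster graph requires >= 2 clusters")
    if "knn_indices" not in adata.obsm:
        raise ValueError("kNN graph required: run preprocess first")
    code = np.searchsorted(nodes, labels)
    sizes = np.bincount(code, minlength=len(nodes)).astype(float)

    if backend == "paga":
        w = _paga_weights(adata, nodes)
    elif backend == "ratio":
        adj = knn_indices_to_adjacency(
            np.asarray(adata.obsm["knn_indices"]), adata.n_obs)
        adj = sp.triu(adj, k=1).tocoo()
        C = len(nodes)
        counts = np.zeros((C, C))
        np.add.at(counts, (code[adj.row], code[adj.col]), 1.0)
        counts = counts + counts.T
        np.fill_diagonal(counts, 0.0)
        p = sizes / sizes.sum()
        n_edges = adj.nnz
        expected = 2.0 * n_edges * np.outer(p, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, counts / expected, 0.0)
        w = ratio / ratio.max() if ratio.max() > 0 else ratio
        w = np.clip(w, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return ClusterGraph(nodes=nodes, sizes=sizes, weights=w)


def _paga_weights(adata, nodes) -> np.ndarray:
    import scanpy as sc
    tmp = adata.copy()
    sc.pp.neighbors(tmp, use_rep="X_pca",
                    n_neighbors=np.asarray(adata.obsm["knn_indices"]).shape[1])
    tmp.obs["cluster"] = tmp.obs["cluster"].astype("category")
    sc.tl.paga(tmp, groups="cluster")
    conn = np.asarray(tmp.uns["paga"]["connectivities"].todense())
    order = [list(tmp.obs["cluster"].cat.categories).index(n) for n in nodes]
    w = conn[np.ix_(order, order)]
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_graph(g: ClusterGraph, cfg: PipelineConfig | None = None) -> ClusterGraph:
    """Drop small/isolated clusters, then reconnect disjoint sub-graphs.

    Step 1: clusters ordered by size are selected greedily until the selected
    mass exceeds ``pruning_mass_fraction`` of all cells, with at least
    ``pruning_min_clusters`` selected (all clusters when there are fewer);
    any dropped cluster whose weight to a selected one exceeds
    ``pruning_weight_factor`` times its maximum weight is added back.

    Step 2: if the retained graph is disconnected, for each pair of
    components the dropped cluster maximizing the product of its best weights
    into both sides is re-added. When no such cluster exists the components
    are reported separately (``components`` attribute) rather than merged.
    """
    if cfg is None:
        cfg = PipelineConfig()
    C = len(g.nodes)
    order = sorted(range(C), key=lambda i: (-g.sizes[i], g.nodes[i]))
    total = g.sizes.sum()
    n_min = min(cfg.pruning_min_clusters, C)
    selected: list[int] = []
    mass = 0.0
    for i in order:
        if mass > cfg.pruning_mass_fraction * total and len(selected) >= n_min:
            break
        selected.append(i)
        mass += g.sizes[i]
    sel = set(selected)
    # weight-based rescue of dropped clusters: one pass against the initial
    # selection (a cascading fixpoint would pull whole chains back in)
    rescued = set()
    for i2 in range(C):
        if i2 in sel:
            continue
        others = [j for j in range(C) if j != i2]
        w_max = g.weights[i2, others].max() if others else 0.0
        w_sel = max((g.weights[i2, j] for j in sel), default=0.0)
        if w_max > 0 and w_sel > cfg.pruning_weight_factor * w_max:
            rescued.add(i2)
    sel |= rescued

    # step 2: reconnect disjoint sub-graphs
    while True:
        keep = sorted(sel)
        sub_w = g.weights[np.ix_(keep, keep)]
        comps = _graph_components(sub_w)
        if len(comps) <= 1:
            break
        dropped = [i for i in range(C) if i not in sel]
        best, best_val = None, 0.0
        for i in dropped:
            # best weight from i into each of the two largest components
            c1, c2 = comps[0], comps[1]
            w1 = max(g.weights[i, keep[j]] for j in c1)
            w2 = max(g.weights[i, keep[j]] for j in c2)
            if w1 * w2 > best_val:
                best, best_val = i, w1 * w2
        if best is None:
            names = [[g.nodes[keep[j]] for j in comp] for comp in comps]
            logger.warning(
                "cluster graph has %d disjoint components that cannot be "
                "reconnected; run the remaining stages per component: %s",
                len(comps), names)
            out = g.subgraph([g.nodes[i] for i in keep])
            out.components = names
            return out
        sel.add(best)
        logger.info("reconnected components via cluster %s", g.nodes[best])
    return g.subgraph([g.nodes[i] for i in sorted(sel)])


# ---------------------------------------------------------------------------
# terminal-state scoring
# ---------------------------------------------------------------------------

def score_terminal_states(adata, g: ClusterGraph,
                          cfg: PipelineConfig | None = None) -> ClusterGraph:
    """Per-cluster root/end scores from a steady-state velocity transition chain.

    A preliminary velocity is taken from the steady-state residual
    u - gamma * s on the smoothed layers; a cosine transition matrix over the
    kNN support (same kernel as the final velocity graph) defines a Markov
    chain whose stationary distribution gives end scores; root scores come
    from the reversed chain. Both are min-max scaled to [0, 1] per cell and
    averaged within clusters.
    """
    from .velocity import cosine_velocity_graph

    if cfg is None:
        cfg = PipelineConfig()
    s = np.asarray(adata.layers["Ms"])
    u = np.asarray(adata.layers["Mu"])
    denom = (s * s).sum(axis=0)
    denom[denom == 0] = 1.0
    gamma = (u * s).sum(axis=0) / denom
    v = u - gamma[None, :] * s

    knn = np.asarray(adata.obsm["knn_indices"])
    pi, pi_tilde = cosine_velocity_graph(s, v, knn, cfg.velocity_graph_sigma)

    end_cell = _stationary_scores(pi_tilde, knn, adata.n_obs, reverse=False)
    root_cell = _stationary_scores(pi_tilde, knn, adata.n_obs, reverse=True)

    labels = adata.obs["cluster"].astype(str).to_numpy()
    R = np.zeros(len(g.nodes))
    E = np.zeros(len(g.nodes))
    for i, node in enumerate(g.nodes):
        m = labels == node
        if m.any():
            R[i] = root_cell[m].mean()
            E[i] = end_cell[m].mean()
    out = replace(g)
    out.root_score, out.end_score = R, E
    return out


def _stationary_scores(pi_tilde: np.ndarray, knn: np.ndarray, n: int,
                       reverse: bool, damping: float = 0.001,
                       n_iter: int = 5000) -> np.ndarray:
    """Min-max scaled stationary distribution of the (possibly reversed)
    transition chain, computed per connected component by damped power
    iteration."""
    k = knn.shape[1]
    rows = np.repeat(np.arange(n), k)
    P = sp.csr_matrix((pi_tilde.ravel(), (rows, knn.ravel())), shape=(n, n))
    if reverse:
        P = P.T.tocsr()
        rs = np.asarray(P.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        P = sp.diags(1.0 / rs) @ P
    comps_n, labels = sp.csgraph.connected_components(
        knn_indices_to_adjacency(knn, n), directed=False)
    scores = np.zeros(n)
    for c in range(comps_n):
        idx = np.nonzero(labels == c)[0]
        Pc = P[idx][:, idx].tocsr()
        rs = np.asarray(Pc.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        Pc = sp.diags(1.0 / rs) @ Pc
        m = len(idx)
        pi_v = np.full(m, 1.0 / m)
        for _ in range(n_iter):
            new = (1 - damping) * (pi_v @ Pc) + damping / m
            if np.abs(new - pi_v).sum() < 1e-13:
                pi_v = new
                break
            pi_v = new
        scores[idx] = pi_v
    lo, hi = scores.min(), scores.max()
    if hi > lo:
        scores = (scores - lo) / (hi - lo)
    return scores


# ---------------------------------------------------------------------------
# origin-node selection
# ---------------------------------------------------------------------------

def select_origin(g: ClusterGraph, cfg: PipelineConfig | None = None) -> ClusterGraph:
    """Pick the origin node from the root/end score rankings.

    Rule 1: the highest-root-score cluster with R > threshold and E < R.
    Rule 2: otherwise the highest-end-score cluster with E > threshold and
    R < E. Rule 3: otherwise the cluster with the highest root score.
    Rank ties break by ascending cluster id.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if g.root_score is None or g.end_score is None:
        raise ValueError("scores missing: run score_terminal_states first")
    R, E = g.root_score, g.end_score
    thr = cfg.score_threshold
    by_root = sorted(range(len(g.nodes)), key=lambda i: (-R[i], g.nodes[i]))
    by_end = sorted(range(len(g.nodes)), key=lambda i: (-E[i], g.nodes[i]))
    origin, rule = None, None
    for i in by_root:
        if R[i] > thr and E[i] < R[i]:
            origin, rule = g.nodes[i], 1
            break
    if origin is None:
        for i in by_end:
            if E[i] > thr and R[i] < E[i]:
                origin, rule = g.nodes[i], 2
                break
    if origin is None:
        origin, rule = g.nodes[by_root[0]], 3
    out = replace(g)
    out.origin, out.origin_rule = origin, rule
    logger.info("origin node %s selected by rule %d (R=%.3f, E=%.3f)",
                origin, rule, R[g.nodes.index(origin)],
                E[g.nodes.index(origin)])
    return out
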