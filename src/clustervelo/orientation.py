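"""Direction inference on the main path via the orientation score.

Cells on the main path are ordered by diffusion pseudotime from a root cell
in the origin cluster. For each gene the pseudotime-ordered unspliced and
spliced series are smoothed with a uniform 1-d kernel and normalized, a
piecewise-linear "linear tree" is fitted to each, and the orientation score

    S_g = sum over co-rising/co-falling sections tau of
          (+1 if rising, -1 if falling) * sum_{n in tau}(u_n - s_n) * len(tau)

rewards sections where unspliced RNA leads spliced RNA in the direction
implied by the current ordering. A negative mean score over the velocity
genes mandates reversing the path direction; branch paths sharing the
corrected source endpoint can relocate the origin further outward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import uniform_filter1d

from .cluster_graph import ClusterGraph
from .datamodel import PipelineConfig, knn_indices_to_adjacency
from .main_path import MainPath

logger = logging.getLogger("clustervelo")


# ---------------------------------------------------------------------------
# diffusion pseudotime (self-contained backend)
# ---------------------------------------------------------------------------

def diffusion_pseudotime(adjacency: sp.spmatrix, root: int,
                         n_comps: int = 10) -> np.ndarray:
    """Diffusion-map distance from a root cell on a symmetric kNN graph.

    Eigen-decomposes the symmetrized transition matrix
    D^{-1/2} A D^{-1/2}; pseudotime of a cell is its distance to the root in
    the diffusion space with components scaled by lambda/(1-lambda). Cells
    disconnected from the root's component are placed after the largest
    finite pseudotime. A tiny index-proportional jitter enforces strict
    ordering.
    """
    n = adjacency.shape[0]
    n_comp_graph, labels = sp.csgraph.connected_components(adjacency,
                                                           directed=False)
    t = np.full(n, np.nan)
    root_comp = labels[root]
    for c in range(n_comp_graph):
        idx = np.nonzero(labels == c)[0]
        if c != root_comp:
            continue
        sub = adjacency[idx][:, idx].astype(float)
        deg = np.asarray(sub.sum(axis=1)).ravel()
        deg[deg == 0] = 1.0
        d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        M = d_inv_sqrt @ sub @ d_inv_sqrt
        k = int(min(n_comps + 1, len(idx) - 1))
        if k < 2:
            t[idx] = np.arange(len(idx), dtype=float)
            continue
        if len(idx) <= 600:
            vals, vecs = np.linalg.eigh(M.toarray())
        else:
            from scipy.sparse.linalg import ArpackNoConvergence, eigsh
            try:
                vals, vecs = eigsh(
                    M.tocsc(), k=k, which="LA", tol=1e-9, maxiter=10000,
                    v0=np.full(len(idx), 1.0 / np.sqrt(len(idx))))
            except ArpackNoConvergence:
                vals, vecs = np.linalg.eigh(M.toarray())
        order = np.argsort(vals)[::-1][:k]
        vals, vecs = vals[order], vecs[:, order]
        # right eigenvectors of the row-stochastic chain; drop the trivial one
        psi = vecs / np.sqrt(deg)[:, None]
        lam = np.clip(vals[1:], -1.0, 1.0 - 1e-10)
        scale = lam / (1.0 - lam)
        comps = psi[:, 1:] * scale[None, :]
        root_pos = comps[np.nonzero(idx == root)[0][0]]
        t[idx] = np.sqrt(((comps - root_pos[None, :]) ** 2).sum(axis=1))
    finite_max = np.nanmax(t)
    t[np.isnan(t)] = finite_max + 1.0
    return t + 1e-12 * np.arange(n)


def path_pseudotime(adata, g: ClusterGraph, path: MainPath,
                    nodes: list[str] | None = None,
                    root_cell: int | None = None):
    """Pseudotime of the cells on a path (main path by default).

    Returns ``(cell_indices, t)``: positions of the path cells in the
    dataset and their pseudotime from the root cell, which defaults to the
    first stored cell of the path's first node (``root_cell`` overrides).
    """
    node_set = set(nodes if nodes is not None else path.nodes)
    first = (nodes if nodes is not None else path.nodes)[0]
    labels = adata.obs["cluster"].astype(str).to_numpy()
    mask = np.isin(labels, sorted(node_set))
    cell_idx = np.nonzero(mask)[0]
    if root_cell is not None:
        root_global = int(root_cell)
    else:
        root_candidates = np.nonzero(labels == first)[0]
        if len(root_candidates) == 0:
            raise RuntimeError(f"path root cluster {first!r} holds no cells")
        root_global = int(root_candidates[0])   # lowest stored index
    knn = np.asarray(adata.obsm["knn_indices"])
    adj = knn_indices_to_adjacency(knn, adata.n_obs)
    sub = adj[cell_idx][:, cell_idx]
    root_local = int(np.nonzero(cell_idx == root_global)[0][0])
    t = diffusion_pseudotime(sub.tocsr(), root_local)
    return cell_idx, t


# ---------------------------------------------------------------------------
# time series extraction
# ---------------------------------------------------------------------------

@dataclass
class GeneTimeSeries:
    gene: str
    u: np.ndarray
    s: np.ndarray
    normalization_mode: str = "sum"
    valid: bool = True


def smooth_and_normalize(series: np.ndarray, kernel: int,
                         mode: str = "sum") -> tuple[np.ndarray, np.ndarray]:
    """Uniform 1-d smoothing with edge replication, then per-gene rescaling.

    ``series`` is (n_path_cells x n_genes) ordered by pseudotime. The kernel
    length is clamped to the series length. Returns the rescaled matrix and a
    per-gene validity mask (all-zero genes cannot be normalized).
    """
    n = series.shape[0]
    k = int(min(kernel, n))
    sm = uniform_filter1d(series, size=k, axis=0, mode="nearest",
                          origin=0 if k % 2 else -1)
    if mode == "sum":
        denom = sm.sum(axis=0)
    elif mode == "max":
        denom = sm.max(axis=0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    return sm / safe[None, :], valid


def extract_series_matrix(adata, cell_idx: np.ndarray, t: np.ndarray,
                          cfg: PipelineConfig):
    """Pseudotime-ordered, smoothed, normalized u/s series for all genes.

    Returns ``(U, S, valid, order)`` with U, S of shape
    (n_path_cells x n_genes).
    """
    order = np.argsort(t, kind="stable")
    idx = cell_idx[order]
    u = np.asarray(adata.layers["Mu"])[idx]
    s = np.asarray(adata.layers["Ms"])[idx]
    U, ok_u = smooth_and_normalize(u, cfg.smoothing_kernel,
                                   cfg.normalization_mode)
    S, ok_s = smooth_and_normalize(s, cfg.smoothing_kernel,
                                   cfg.normalization_mode)
    return U, S, ok_u & ok_s, order


def extract_series(adata, cell_idx, t, gene: str,
                   cfg: PipelineConfig | None = None) -> GeneTimeSeries:
    """Single-gene convenience wrapper around :func:`extract_series_matrix`."""
    if cfg is None:
        cfg = PipelineConfig()
    j = list(adata.var_names).index(gene)
    U, S, valid, _ = extract_series_matrix(adata, cell_idx, t, cfg)
    return GeneTimeSeries(gene=gene, u=U[:, j], s=S[:, j],
                          normalization_mode=cfg.normalization_mode,
                          valid=bool(valid[j]))


# ---------------------------------------------------------------------------
# linear tree
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    start: int            # inclusive
    end: int              # exclusive
    slope: float
    intercept: float
    sse: float


@dataclass
class LinearTree:
    segments: list[Segment]
    split_points: list[int]
    mse_trace: list[float]

    def slopes_at(self, boundaries: np.ndarray) -> np.ndarray:
        """Slope of the covering segment for each interval [b_i, b_{i+1})."""
        starts = np.array([s.start for s in self.segments])
        slopes = np.array([s.slope for s in self.segments])
        pos = np.searchsorted(starts, boundaries[:-1], side="right") - 1
        return slopes[pos]

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([s.start for s in self.segments]
                        + [self.segments[-1].end])


class _PrefixLSQ:
    """Least-squares line fits on arbitrary index ranges via global prefix
    sums; all candidate splits of a range are evaluated vectorized."""

    def __init__(self, y: np.ndarray):
        x = np.arange(len(y), dtype=float)
        z = [0.0]
        self.cx = np.concatenate([z, np.cumsum(x)])
        self.cy = np.concatenate([z, np.cumsum(y)])
        self.cxx = np.concatenate([z, np.cumsum(x * x)])
        self.cxy = np.concatenate([z, np.cumsum(x * y)])
        self.cyy = np.concatenate([z, np.cumsum(y * y)])

    def _moments(self, a, b):
        m = (b - a).astype(float) if hasattr(b - a, "astype") else float(b - a)
        sx = self.cx[b] - self.cx[a]
        sy = self.cy[b] - self.cy[a]
        sxx = self.cxx[b] - self.cxx[a] - sx * sx / m
        sxy = self.cxy[b] - self.cxy[a] - sx * sy / m
        syy = self.cyy[b] - self.cyy[a] - sy * sy / m
        return m, sx, sy, sxx, sxy, syy

    def sse(self, a, b):
        _, _, _, sxx, sxy, syy = self._moments(a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(sxx > 1e-12, sxy / np.where(sxx > 1e-12, sxx, 1.0), 0.0)
        return np.maximum(syy - k * sxy, 0.0)

    def line(self, a: int, b: int) -> Segment:
        if b - a == 1:
            return Segment(a, b, 0.0, float(self.cy[b] - self.cy[a]), 0.0)
        m, sx, sy, sxx, sxy, syy = self._moments(a, b)
        slope = float(sxy / sxx) if sxx > 1e-12 else 0.0
        intercept = float(sy / m - slope * sx / m)
        return Segment(a, b, slope, intercept,
                       float(max(syy - slope * sxy, 0.0)))

    def best_split(self, a: int, b: int, min_len: int):
        n = b - a
        if n < 2 * min_len:
            return None
        splits = np.arange(a + min_len, b - min_len + 1)
        total = self.sse(np.full_like(splits, a), splits) + \
            self.sse(splits, np.full_like(splits, b))
        best = int(np.argmin(total))
        return int(splits[best]), float(total[best])


def fit_linear_tree(y: np.ndarray, cfg: PipelineConfig | None = None) -> LinearTree:
    """Recursive binary piecewise-linear fit of a series.

    Each round splits every splittable segment at its SSE-minimizing point;
    the round is accepted while the drop in total MSE stays above the
    convergence threshold (absolute, or relative to the current MSE) and
    every new interval keeps the minimum length.
    """
    if cfg is None:
        cfg = PipelineConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    min_len = cfg.tree_min_interval
    lsq = _PrefixLSQ(y)
    segments = [lsq.line(0, n)]
    mse_trace = [segments[0].sse / n]
    split_cache: dict[tuple[int, int], tuple[int, float] | None] = {}
    while True:
        proposals = []
        for seg in segments:
            key = (seg.start, seg.end)
            if key not in split_cache:
                split_cache[key] = lsq.best_split(seg.start, seg.end, min_len)
            res = split_cache[key]
            if res is not None and res[1] < seg.sse - 1e-15:
                proposals.append((seg, res[0]))
        if not proposals:
            break
        new_segments = []
        for seg in segments:
            match = [p for p in proposals if p[0] is seg]
            if match:
                split = match[0][1]
                new_segments.append(lsq.line(seg.start, split))
                new_segments.append(lsq.line(split, seg.end))
            else:
                new_segments.append(seg)
        new_mse = sum(s.sse for s in new_segments) / n
        drop = mse_trace[-1] - new_mse
        if cfg.tree_mse_drop_mode == "absolute":
            converged = drop < cfg.tree_mse_drop_threshold
        else:
            ref = mse_trace[-1] if mse_trace[-1] > 0 else 1.0
            converged = drop / ref < cfg.tree_relative_drop
        if converged:
            break
        segments = new_segments
        mse_trace.append(new_mse)
    segments.sort(key=lambda s: s.start)
    return LinearTree(segments=segments,
                      split_points=[s.start for s in segments[1:]],
                      mse_trace=mse_trace)


# ---------------------------------------------------------------------------
# orientation score
# ---------------------------------------------------------------------------

def orientation_score(tree_u: LinearTree, tree_s: LinearTree,
                      u: np.ndarray, s: np.ndarray) -> float:
    """Score of one gene from its two linear trees and normalized series.

    The two segmentations are intersected; each resulting interval is
    classified by the pair of local slopes (strictly positive pair: rising;
    strictly negative pair: falling; otherwise mixed, contributing zero).
    Adjacent intervals of the same class merge into maximal sections tau,
    each contributing sign(tau) * sum_{n in tau}(u_n - s_n) * len(tau).
    """
    bounds = np.union1d(tree_u.boundaries, tree_s.boundaries)
    ku = tree_u.slopes_at(bounds)
    ks = tree_s.slopes_at(bounds)
    cls = np.where((ku > 0) & (ks > 0), 1, np.where((ku < 0) & (ks < 0), -1, 0))
    d = u - s
    score = 0.0
    i = 0
    while i < len(cls):
        if cls[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(cls) and cls[j + 1] == cls[i]:
            j += 1
        a, b = int(bounds[i]), int(bounds[j + 1])
        score += cls[i] * d[a:b].sum() * (b - a)
        i = j + 1
    return float(score)


def score_genes(U: np.ndarray, S: np.ndarray, valid: np.ndarray,
                cfg: PipelineConfig) -> np.ndarray:
    """Orientation score per gene (NaN where the series is degenerate)."""
    G = U.shape[1]
    out = np.full(G, np.nan)
    for j in range(G):
        if not valid[j]:
            continue
        tu = fit_linear_tree(U[:, j], cfg)
        ts = fit_linear_tree(S[:, j], cfg)
        out[j] = orientation_score(tu, ts, U[:, j], S[:, j])
    return out


# ---------------------------------------------------------------------------
# velocity-gene filter
# ---------------------------------------------------------------------------

def velocity_gene_filter(adata, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Boolean mask of genes with reliable u-s signal.

    Keeps genes whose through-origin regression of u on s has slope
    gamma > ``velocity_gene_gamma_min`` and R^2 > ``velocity_gene_r2_min``,
    and whose u/s standard-deviation ratio is inside
    ``sigma_ratio_bounds``. Zero-variance genes are excluded. With
    ``velocity_gene_quantile`` set, the regression uses only the extreme
    quantiles of s (steady-state convention).
    """
    if cfg is None:
        cfg = PipelineConfig()
    u = np.asarray(adata.layers["Mu"])
    s = np.asarray(adata.layers["Ms"])
    n = u.shape[0]
    if cfg.velocity_gene_quantile:
        q = cfg.velocity_gene_quantile
        lo = np.quantile(s, q, axis=0)
        hi = np.quantile(s, 1 - q, axis=0)
        w = (s <= lo[None, :]) | (s >= hi[None, :])
    else:
        w = np.ones_like(s, dtype=bool)
    su = np.where(w, u, 0.0)
    ss = np.where(w, s, 0.0)
    denom = (ss * ss).sum(axis=0)
    gamma = np.where(denom > 0, (su * ss).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    resid = u - gamma[None, :] * s
    var_u = u.var(axis=0)
    var_s = s.var(axis=0)
    tss = ((u - u.mean(axis=0)[None, :]) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - (resid ** 2).sum(axis=0) / np.where(tss > 0, tss, 1.0), 0.0)
        ratio = np.sqrt(np.where(var_s > 0, var_u / np.where(var_s > 0, var_s, 1.0), np.inf))
    lo_b, hi_b = cfg.sigma_ratio_bounds
    mask = ((gamma > cfg.velocity_gene_gamma_min)
            & (r2 > cfg.velocity_gene_r2_min)
            & (var_u > 0) & (var_s > 0)
            & (ratio > lo_b) & (ratio < hi_b))
    return mask


# ---------------------------------------------------------------------------
# orientation report and origin correction
# ---------------------------------------------------------------------------

@dataclass
class OrientationReport:
    gene_names: list[str]
    scores: np.ndarray                   # per velocity gene
    mean_score: float
    decision: str                        # "keep" | "reverse"
    branch_scores: np.ndarray | None = None
    branch_mean: float | None = None
    branch_nodes: list[str] | None = None
    new_origin: str | None = None
    case: int | None = None


def orient_main_path(adata, g: ClusterGraph, path: MainPath,
                     cfg: PipelineConfig | None = None) -> OrientationReport:
    """Score the velocity genes on the main path and decide the direction."""
    if cfg is None:
        cfg = PipelineConfig()
    vel_mask = velocity_gene_filter(adata, cfg)
    if not vel_mask.any():
        raise ValueError(
            "no velocity gene passes the filter; relax the gamma/R^2/"
            "sigma-ratio thresholds in the configuration")
    cell_idx, t = path_pseudotime(adata, g, path)
    U, S, valid, _ = extract_series_matrix(adata, cell_idx, t, cfg)
    U, S = U[:, vel_mask], S[:, vel_mask]
    scores = score_genes(U, S, valid[vel_mask], cfg)
    mean_score = float(np.nanmean(scores))
    decision = "keep" if mean_score >= 0 else "reverse"
    logger.info("main-path mean orientation score %.4f over %d velocity "
                "genes: %s direction", mean_score, int(vel_mask.sum()),
                decision)
    return OrientationReport(
        gene_names=list(np.asarray(adata.var_names)[vel_mask]),
        scores=scores, mean_score=mean_score, decision=decision)


def infer_new_origin(adata, g: ClusterGraph, path: MainPath,
                     report: OrientationReport,
                     cfg: PipelineConfig | None = None) -> ClusterGraph:
    """Reset the origin from the orientation scores.

    Case 1 (no branch at the corrected source endpoint): a negative mean
    score moves the origin to the far end of the main path. Case 2 (a branch
    attaches at the corrected source endpoint i): the branch direction is
    scored the same way with branch pseudotime from i; if the branch flow
    runs into i (negative branch score, composing head-to-tail with the main
    flow) the origin moves to the branch's far endpoint j, otherwise it is i.
    """
    if cfg is None:
        cfg = PipelineConfig()
    source = path.nodes[0] if report.mean_score >= 0 else path.nodes[-1]
    branch = next((b for b in path.branches
                   if b.attachment == source and b.spine), None)
    if branch is None:
        report.case = 1
        report.new_origin = source
    else:
        report.case = 2
        vel_mask = velocity_gene_filter(adata, cfg)
        # branch series over the branch's own clusters, rooted at the spine
        # cell bordering the attachment: rooting inside the attachment
        # cluster folds its cells (which extend along the main path) into
        # the branch ordering and scrambles the series
        branch_nodes = list(branch.spine)
        labels = adata.obs["cluster"].astype(str).to_numpy()
        knn = np.asarray(adata.obsm["knn_indices"])
        first_cells = np.nonzero(labels == branch.spine[0])[0]
        att_hits = (labels[knn[first_cells]] == branch.attachment).sum(axis=1)
        root_cell = int(first_cells[int(np.argmax(att_hits))])
        cell_idx, t = path_pseudotime(adata, g, path, nodes=branch_nodes,
                                      root_cell=root_cell)
        U, S, valid, _ = extract_series_matrix(adata, cell_idx, t, cfg)
        U, S = U[:, vel_mask], S[:, vel_mask]
        b_scores = score_genes(U, S, valid[vel_mask], cfg)
        b_mean = float(np.nanmean(b_scores))
        report.branch_scores = b_scores
        report.branch_mean = b_mean
        report.branch_nodes = branch_nodes
        if b_mean < 0:                 # branch flows into i: aligned
            report.new_origin = branch.spine[-1]
        else:
            report.new_origin = source
        logger.info("branch %s mean score %.4f; origin set to %s",
                    "->".join(branch_nodes), b_mean, report.new_origin)
    out = g.subgraph(g.nodes)
    out.origin = report.new_origin
    out.origin_rule = g.origin_rule
    out.root_score, out.end_score = g.root_score, g.end_score
    return out
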