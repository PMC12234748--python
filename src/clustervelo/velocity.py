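"""Directed trajectory inference and per-cell velocity estimation.

With the corrected origin fixed, every cluster gets a level (BFS distance on
the full cluster graph with weak and shortcut edges suppressed) and at most
one parent, yielding directed cluster-level edges (DTI). Each cell's
directed nearest neighborhood (dNN) is the subset of its kNN that lies later
in global diffusion pseudotime and in the same or a child cluster — its
imputed future state. Velocities point from the cell toward the dNN mean
expression, either exactly (simple fit), with a neighbor-coherence
regularizer (fit), or through cell-specific kinetic rates predicted by a
small fully connected network (kinetic mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cluster_graph import ClusterGraph
from .datamodel import PipelineConfig, knn_indices_to_adjacency
from .orientation import diffusion_pseudotime

logger = logging.getLogger("clustervelo")


@dataclass
class DirectedClusterGraph:
    base: ClusterGraph
    level: dict[str, int]
    children: dict[str, list[str]]
    parent: dict[str, str]
    dti_edges: list[tuple[str, str]]

    @property
    def origin(self) -> str:
        return self.base.origin


@dataclass
class DirectedNeighborhood:
    knn: np.ndarray           # cells x k neighbor indices
    mask: np.ndarray          # cells x k bool: neighbor in dNN
    pseudotime: np.ndarray    # global pseudotime t'

    def members(self, n: int) -> np.ndarray:
        return self.knn[n][self.mask[n]]

    @property
    def sizes(self) -> np.ndarray:
        return self.mask.sum(axis=1)


@dataclass
class VelocityField:
    v_u: np.ndarray
    v_s: np.ndarray
    mode: str
    rates: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # alpha, beta, gamma


@dataclass
class VelocityGraph:
    knn: np.ndarray
    pi: np.ndarray            # cells x k cosine entries
    pi_tilde: np.ndarray      # cells x k row-stochastic (exp kernel)
    sigma: float


# ---------------------------------------------------------------------------
# level and child assignment
# ---------------------------------------------------------------------------

def assign_levels(g: ClusterGraph, cfg: PipelineConfig | None = None) -> dict[str, int]:
    """BFS levels from the origin on the full cluster graph.

    From a level-k node i, node i' gets level k+1 when w_{i,i'} > z1 and no
    third node j offers a stronger two-hop route (w_{i,i'} < z2 w_{i,j}
    w_{j,i'}). Nodes unreachable under these rules are attached at their
    strongest neighbor's level + 1 with a warning.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if g.origin is None:
        raise ValueError("origin not set")
    w = g.weights
    n = len(g.nodes)
    level = {g.origin: 0}
    frontier = [g.index(g.origin)]
    k = 0
    while frontier:
        nxt = []
        for i in frontier:
            for i2 in range(n):
                name2 = g.nodes[i2]
                if name2 in level or w[i, i2] <= cfg.z1:
                    continue
                shortcut = any(w[i, i2] < cfg.z2 * w[i, j] * w[j, i2]
                               for j in range(n) if j != i and j != i2)
                if shortcut:
                    continue
                level[name2] = k + 1
                nxt.append(i2)
        frontier = nxt
        k += 1
    for i2 in range(n):
        name2 = g.nodes[i2]
        if name2 in level:
            continue
        nb = int(np.argmax(np.where(
            [g.nodes[j] in level for j in range(n)], w[i2], -1.0)))
        attach = level.get(g.nodes[nb], 0) + 1
        logger.warning("node %s unreachable by the level rules; attached at "
                       "level %d via %s", name2, attach, g.nodes[nb])
        level[name2] = attach
    return level


def assign_children(g: ClusterGraph, level: dict[str, int],
                    cfg: PipelineConfig | None = None) -> DirectedClusterGraph:
    """Directed parent -> child edges consistent with the levels.

    i' is a child of i when w_{i,i'} > z1 and level(i') - level(i) = 1; a
    node that is nobody's child attaches to its strongest neighbor; a node
    with several parents keeps only the strongest one.
    """
    if cfg is None:
        cfg = PipelineConfig()
    w = g.weights
    parents: dict[str, list[str]] = {name: [] for name in g.nodes}
    for i, name_i in enumerate(g.nodes):
        for i2, name_i2 in enumerate(g.nodes):
            if i2 == i:
                continue
            if w[i, i2] > cfg.z1 and level[name_i2] - level[name_i] == 1:
                parents[name_i2].append(name_i)
    for name_j in g.nodes:
        if name_j == g.origin or parents[name_j]:
            continue
        j = g.index(name_j)
        strongest = int(np.argmax(np.where(
            np.arange(len(g.nodes)) == j, -1.0, w[j])))
        parents[name_j] = [g.nodes[strongest]]
    parent: dict[str, str] = {}
    for name_j, plist in parents.items():
        if not plist:
            continue
        j = g.index(name_j)
        parent[name_j] = max(plist, key=lambda p: (w[j, g.index(p)], p))
    children: dict[str, list[str]] = {name: [] for name in g.nodes}
    for child, par in parent.items():
        children[par].append(child)
    for v in children.values():
        v.sort()
    dti_edges = sorted((par, child) for child, par in parent.items())
    return DirectedClusterGraph(base=g, level=level, children=children,
                                parent=parent, dti_edges=dti_edges)


# ---------------------------------------------------------------------------
# directed nearest neighborhood
# ---------------------------------------------------------------------------

def _forest_roots(dg: DirectedClusterGraph) -> dict[str, str]:
    """Map each cluster to the root of its parent chain (cycle-guarded)."""
    out = {}
    for node in dg.base.nodes:
        seen = [node]
        cur = node
        while cur in dg.parent and dg.parent[cur] not in seen:
            cur = dg.parent[cur]
            seen.append(cur)
        out[node] = cur if cur not in dg.parent else min(seen)
    return out


def build_dnn(adata, dg: DirectedClusterGraph,
              cfg: PipelineConfig | None = None) -> DirectedNeighborhood:
    """dNN membership: kNN neighbors later in pseudotime, in self/child cluster.

    Global pseudotime starts at the first stored cell of the origin cluster;
    when the DTI forest has several roots (independent lineages), each
    lineage gets its own pseudotime from its own root.
    """
    if cfg is None:
        cfg = PipelineConfig()
    labels = adata.obs["cluster"].astype(str).to_numpy()
    knn = np.asarray(adata.obsm["knn_indices"])
    adj = knn_indices_to_adjacency(knn, adata.n_obs)
    roots = _forest_roots(dg)
    t = np.zeros(adata.n_obs)
    for root in sorted(set(roots.values())):
        members = [c for c, r in roots.items() if r == root]
        cells = np.nonzero(np.isin(labels, members))[0]
        root_candidates = np.nonzero(labels == root)[0]
        if len(root_candidates) == 0:
            raise ValueError(f"origin cluster {root!r} holds no cells")
        sub = adj[cells][:, cells]
        local_root = int(np.nonzero(cells == root_candidates[0])[0][0])
        t[cells] = diffusion_pseudotime(sub.tocsr(), local_root)
    allowed = {c: set(dg.children.get(c, [])) | {c} for c in dg.children}
    neighbor_cluster = labels[knn]
    later = t[knn] > t[:, None]
    ok_cluster = np.zeros_like(later)
    for i, c in enumerate(labels):
        ok_cluster[i] = np.isin(neighbor_cluster[i],
                                sorted(allowed.get(c, {c})))
    mask = later & ok_cluster
    return DirectedNeighborhood(knn=knn, mask=mask, pseudotime=t)


# ---------------------------------------------------------------------------
# velocity estimation
# ---------------------------------------------------------------------------

def _dnn_targets(x: np.ndarray, dnn: DirectedNeighborhood) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell dNN mean of x and the has-dNN mask."""
    sizes = dnn.sizes
    has = sizes > 0
    weights = dnn.mask / np.maximum(sizes, 1)[:, None]
    target = np.einsum("nk,nkg->ng", weights, x[dnn.knn])
    return target, has


def simple_fit(adata, dnn: DirectedNeighborhood,
               cfg: PipelineConfig | None = None) -> VelocityField:
    """Velocity = dNN mean expression minus own expression (zero without dNN).

    Plugging this into the squared-loss objective gives exactly zero.
    """
    u = np.asarray(adata.layers["Mu"])
    s = np.asarray(adata.layers["Ms"])
    tu, has = _dnn_targets(u, dnn)
    ts, _ = _dnn_targets(s, dnn)
    v_u = np.where(has[:, None], tu - u, 0.0)
    v_s = np.where(has[:, None], ts - s, 0.0)
    return VelocityField(v_u=v_u, v_s=v_s, mode="simple_fit")


def fit_objective(vf: VelocityField, adata, dnn: DirectedNeighborhood,
                  cfg: PipelineConfig) -> float:
    """Data term + signed consistency term actually being minimized."""
    u = np.asarray(adata.layers["Mu"])
    s = np.asarray(adata.layers["Ms"])
    tu, has = _dnn_targets(u, dnn)
    ts, _ = _dnn_targets(s, dnn)
    du = (u + vf.v_u - tu)[has]
    ds = (s + vf.v_s - ts)[has]
    data = (du ** 2).sum() + cfg.lam * (ds ** 2).sum()
    rows, cols = _same_cluster_pairs(adata, dnn.knn)
    import scipy.sparse as sp
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(vf.v_s),) * 2)
    cons = _consistency_sum(vf.v_s, A)
    return float(data + cfg.consistency_sign * cfg.lam_prime * cons)


def data_loss(vf: VelocityField, adata, dnn: DirectedNeighborhood,
              cfg: PipelineConfig | None = None) -> float:
    """The squared dNN loss alone, summed over genes."""
    if cfg is None:
        cfg = PipelineConfig()
    u = np.asarray(adata.layers["Mu"])
    s = np.asarray(adata.layers["Ms"])
    tu, has = _dnn_targets(u, dnn)
    ts, _ = _dnn_targets(s, dnn)
    du = (u + vf.v_u - tu)[has]
    ds = (s + vf.v_s - ts)[has]
    return float((du ** 2).sum() + cfg.lam * (ds ** 2).sum())


def _same_cluster_pairs(adata, knn):
    labels = adata.obs["cluster"].astype(str).to_numpy()
    n, k = knn.shape
    rows = np.repeat(np.arange(n), k)
    cols = knn.ravel()
    same = labels[rows] == labels[cols]
    return rows[same], cols[same]


def _unit_rows(v, eps=1e-12):
    norms = np.linalg.norm(v, axis=1)
    ok = norms > eps
    vh = np.zeros_like(v)
    vh[ok] = v[ok] / norms[ok, None]
    return vh, norms, ok


def _consistency_sum(v, pair_matrix):
    """Sum of pairwise cosines over the directed same-cluster pairs."""
    vh, _, _ = _unit_rows(v)
    return float((vh * (pair_matrix @ vh)).sum())


def fit(adata, dnn: DirectedNeighborhood,
        cfg: PipelineConfig | None = None) -> VelocityField:
    """Regularized velocity: data term plus a same-cluster coherence reward.

    Minimizes sum_g L_g - lambda' * L_c by plain gradient descent on the
    spliced velocity matrix, initialized at the simple fit (which zeroes the
    data term); the unspliced velocity keeps its closed-form optimum. Cells
    with empty dNN carry no data term and keep zero velocity. With
    lambda' = 0 the output equals the simple fit exactly. Deterministic.
    """
    if cfg is None:
        cfg = PipelineConfig()
    base = simple_fit(adata, dnn, cfg)
    if cfg.lam_prime == 0:
        return base
    v = base.v_s.copy()
    target = base.v_s            # data term pulls back to the simple solution
    has = dnn.sizes > 0
    rows, cols = _same_cluster_pairs(adata, dnn.knn)
    import scipy.sparse as sp
    n = len(v)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    B = (A + A.T).tocsr()        # a cell appears in pairs in both roles
    u_lay = np.asarray(adata.layers["Mu"])
    s_lay = np.asarray(adata.layers["Ms"])
    tu, _ = _dnn_targets(u_lay, dnn)
    ts, _ = _dnn_targets(s_lay, dnn)
    lr = cfg.fit_learning_rate
    sign = cfg.consistency_sign

    def objective(vv):
        du = (u_lay + base.v_u - tu)[has]
        ds = (s_lay + vv - ts)[has]
        data = (du ** 2).sum() + cfg.lam * (ds ** 2).sum()
        return float(data + sign * cfg.lam_prime * _consistency_sum(vv, A))

    best_v, best_obj = v.copy(), None
    prev_obj = None
    increased = False
    for it in range(cfg.fit_iterations):
        grad = np.zeros_like(v)
        dv = v - target
        grad[has] = 2.0 * cfg.lam * dv[has]   # the u term is fixed at its optimum
        vh, norms, ok = _unit_rows(v)
        S = B @ vh
        cos_sum = (vh * S).sum(axis=1)
        g_cons = np.zeros_like(v)
        g_cons[ok] = (S[ok] - cos_sum[ok, None] * vh[ok]) / norms[ok, None]
        grad += sign * cfg.lam_prime * g_cons
        v -= lr * grad
        if it % 20 == 0 or it == cfg.fit_iterations - 1:
            obj = objective(v)
            if best_obj is None or obj < best_obj:
                best_obj, best_v = obj, v.copy()
            if prev_obj is not None and obj > prev_obj + 1e-9:
                increased = True
            prev_obj = obj
    if increased:
        logger.warning("fit objective increased during descent; returning "
                       "the best iterate")
    return VelocityField(v_u=base.v_u, v_s=best_v, mode="fit")


# ---------------------------------------------------------------------------
# kinetic-rate mode: a small fully connected network maps (u, s) to rates
# ---------------------------------------------------------------------------

def _softplus(x):
    return np.logaddexp(0.0, x)


def fit_kinetic(adata, dnn: DirectedNeighborhood,
                cfg: PipelineConfig | None = None) -> VelocityField:
    """Cell-specific kinetic rates via a fully connected network.

    f_theta: concat(u_n, s_n) in R^{2G} (standardized) -> hidden
    (256, 64, ReLU) -> softplus rates (alpha_n, beta_n, gamma_n); velocities
    v_u = alpha - beta u, v_s = beta u - gamma s. Trained full-batch with
    Adam for ``kinetic_epochs`` epochs at ``kinetic_learning_rate`` to
    minimize the dNN squared loss; seeded and deterministic. Cells sharing
    an expression profile share rates by construction.
    """
    if cfg is None:
        cfg = PipelineConfig()
    u = np.asarray(adata.layers["Mu"])
    s = np.asarray(adata.layers["Ms"])
    n, G = u.shape
    tu, has = _dnn_targets(u, dnn)
    ts, _ = _dnn_targets(s, dnn)
    vu_target = tu - u           # desired velocities on dNN cells
    vs_target = ts - s
    X = np.concatenate([u, s], axis=1)
    # standardize the network input (rates are still applied to raw u, s)
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std[x_std == 0] = 1.0
    X = (X - x_mean) / x_std
    h1, h2 = cfg.kinetic_hidden
    rng = np.random.default_rng(cfg.random_seed)
    params = {
        "W1": rng.normal(0, np.sqrt(2.0 / (2 * G)), (2 * G, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0, np.sqrt(2.0 / h1), (h1, h2)),
        "b2": np.zeros(h2),
        "W3": rng.normal(0, np.sqrt(2.0 / h2), (h2, 3 * G)),
        "b3": np.zeros(3 * G),
    }
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    lr = cfg.kinetic_learning_rate
    w = has[:, None].astype(float)
    n_data = max(int(has.sum()) * G, 1)
    prev_loss = None
    for epoch in range(cfg.kinetic_epochs):
        Z1 = X @ params["W1"] + params["b1"]
        H1 = np.maximum(Z1, 0.0)
        Z2 = H1 @ params["W2"] + params["b2"]
        H2 = np.maximum(Z2, 0.0)
        Z3 = H2 @ params["W3"] + params["b3"]
        R = _softplus(Z3)
        alpha, beta, gamma = R[:, :G], R[:, G:2 * G], R[:, 2 * G:]
        v_u = alpha - beta * u
        v_s = beta * u - gamma * s
        du = w * (v_u - vu_target)
        ds = w * (v_s - vs_target)
        loss = ((du ** 2).sum() + cfg.lam * (ds ** 2).sum()) / n_data
        if not np.isfinite(loss) or (prev_loss is not None
                                     and loss > 1e3 * (prev_loss + 1.0)):
            raise RuntimeError(
                f"kinetic-rate training diverged at epoch {epoch}: "
                f"loss={loss:.3e} (previous {prev_loss:.3e}); lower the "
                "learning rate")
        prev_loss = loss
        g_vu = 2.0 * du / n_data
        g_vs = 2.0 * cfg.lam * ds / n_data
        g_alpha = g_vu
        g_beta = (-g_vu + g_vs) * u
        g_gamma = -g_vs * s
        gR = np.concatenate([g_alpha, g_beta, g_gamma], axis=1)
        gZ3 = gR * (1.0 / (1.0 + np.exp(-Z3)))       # softplus'
        grads = {
            "W3": H2.T @ gZ3, "b3": gZ3.sum(0),
        }
        gH2 = gZ3 @ params["W3"].T
        gZ2 = gH2 * (Z2 > 0)
        grads["W2"] = H1.T @ gZ2
        grads["b2"] = gZ2.sum(0)
        gH1 = gZ2 @ params["W2"].T
        gZ1 = gH1 * (Z1 > 0)
        grads["W1"] = X.T @ gZ1
        grads["b1"] = gZ1.sum(0)
        tstep = epoch + 1
        for k in params:
            m_adam[k] = b1m * m_adam[k] + (1 - b1m) * grads[k]
            v_adam[k] = b2m * v_adam[k] + (1 - b2m) * grads[k] ** 2
            mh = m_adam[k] / (1 - b1m ** tstep)
            vh = v_adam[k] / (1 - b2m ** tstep)
            params[k] -= lr * mh / (np.sqrt(vh) + eps)
    # final forward pass
    H1 = np.maximum(X @ params["W1"] + params["b1"], 0.0)
    H2 = np.maximum(H1 @ params["W2"] + params["b2"], 0.0)
    R = _softplus(H2 @ params["W3"] + params["b3"])
    alpha, beta, gamma = R[:, :G], R[:, G:2 * G], R[:, 2 * G:]
    return VelocityField(v_u=alpha - beta * u, v_s=beta * u - gamma * s,
                         mode="kinetic", rates=(alpha, beta, gamma))


# ---------------------------------------------------------------------------
# velocity graph and embedding projection
# ---------------------------------------------------------------------------

def cosine_velocity_graph(s: np.ndarray, v: np.ndarray, knn: np.ndarray,
                          sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Cosine graph pi and its exponential-kernel transition matrix pi_tilde
    over the kNN support. Zero-norm velocities give a zero pi row and a
    uniform pi_tilde row."""
    disp = s[knn] - s[:, None, :]            # cells x k x genes
    vn = np.linalg.norm(v, axis=1)
    dn = np.linalg.norm(disp, axis=2)
    num = np.einsum("nkg,ng->nk", disp, v)
    denom = dn * vn[:, None]
    pi = np.where(denom > 1e-12, num / np.where(denom > 1e-12, denom, 1.0), 0.0)
    zero_v = vn <= 1e-12
    pi[zero_v] = 0.0
    e = np.exp(pi / sigma ** 2)
    pi_tilde = e / e.sum(axis=1, keepdims=True)
    return pi, pi_tilde


def velocity_graph(adata, vf: VelocityField,
                   cfg: PipelineConfig | None = None) -> VelocityGraph:
    if cfg is None:
        cfg = PipelineConfig()
    s = np.asarray(adata.layers["Ms"])
    knn = np.asarray(adata.obsm["knn_indices"])
    pi, pi_tilde = cosine_velocity_graph(s, vf.v_s, knn,
                                         cfg.velocity_graph_sigma)
    return VelocityGraph(knn=knn, pi=pi, pi_tilde=pi_tilde,
                         sigma=cfg.velocity_graph_sigma)


def embedding_velocity(adata, vg: VelocityGraph,
                       chunk: int = 512) -> np.ndarray:
    """Project the transition matrix onto the 2-D embedding.

    v_e,n = sum_{n' != n} (pi_tilde_{n,n'} - 1/N) * unit(e_{n'} - e_n);
    unstored transition entries count as zero but still receive the -1/N
    background term. Coincident embedding positions contribute nothing.
    """
    e = np.asarray(adata.obsm["X_embed"], dtype=float)
    n = len(e)
    out = np.zeros((n, 2))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = e[None, :, :] - e[lo:hi, None, :]          # chunk x N x 2
        norm = np.linalg.norm(d, axis=2)
        ok = norm > 1e-12
        unit = np.where(ok[:, :, None], d / np.where(ok, norm, 1.0)[:, :, None], 0.0)
        out[lo:hi] = -unit.sum(axis=1) / n             # background -1/N term
        rows = np.arange(lo, hi)
        tgt = vg.knn[rows]                             # chunk x k
        pt = vg.pi_tilde[rows]
        local = unit[np.arange(hi - lo)[:, None], tgt]  # chunk x k x 2
        out[lo:hi] += np.einsum("ck,ckd->cd", pt, local)
    return out
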