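"""Data container conventions, I/O, preprocessing and clustering.

The pipeline operates on :class:`anndata.AnnData` objects with the following
conventions (the "expression dataset" contract):

===============  =============================================================
slot             meaning
===============  =============================================================
layers           ``spliced`` / ``unspliced`` raw counts (cells x genes);
                 ``Ms`` / ``Mu`` neighbor-smoothed log values; after velocity
                 estimation ``velocity`` / ``velocity_u``
obs              ``cluster`` categorical labels; ``pseudotime`` (main path),
                 ``pseudotime_global``, ``level``
obsm             ``X_pca``; ``X_embed`` 2-D embedding; ``knn_indices``
                 (cells x k int array, never containing the cell itself)
uns              run report entries written by later stages
===============  =============================================================

Cell and gene order is preserved end to end; all per-cell outputs are
positionally aligned with the input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("clustervelo")

#: layer-name aliases accepted on input, resolved in order
LAYER_ALIASES = {
    "spliced": ("spliced", "Ms", "S"),
    "unspliced": ("unspliced", "Mu", "U"),
}


def enable_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s [%(name)s] %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their defaults.

    Thresholds follow the method's published defaults; see the methods note
    for the rationale behind each one.
    """

    k_neighbors: int = 30
    n_top_genes: int = 2000
    min_shared_counts: int = 20
    leiden_resolution: float = 0.6
    smoothing_kernel: int = 100          # K, 1-d uniform kernel on path series
    pruning_mass_fraction: float = 0.5
    pruning_min_clusters: int = 5
    pruning_weight_factor: float = 0.6
    score_threshold: float = 0.1         # origin-node root/end score cut
    z1: float = 0.1                      # level assignment: minimum weight
    z2: float = 1.0                      # level assignment: shortcut factor
    lam: float = 1.0                     # weight of the spliced loss term
    lam_prime: float = 0.1               # weight of the consistency term
    tree_mse_drop_threshold: float = 100.0
    tree_mse_drop_mode: str = "relative"  # "absolute" | "relative"
    tree_relative_drop: float = 1e-3
    tree_min_interval: int = 10
    velocity_gene_gamma_min: float = 0.01
    velocity_gene_r2_min: float = 0.01
    velocity_gene_quantile: float | None = None  # e.g. 0.05: fit on extremes
    sigma_ratio_bounds: tuple[float, float] = (0.03, 3.0)
    normalization_mode: str = "sum"      # "sum" (sum-to-1) | "max"
    n_pcs: int = 30
    fit_iterations: int = 200
    fit_learning_rate: float = 0.01
    kinetic_epochs: int = 300
    kinetic_learning_rate: float = 0.001
    kinetic_hidden: tuple[int, int] = (256, 64)
    consistency_sign: float = -1.0       # -1: reward coherence (default)
    velocity_graph_sigma: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sigma_ratio_bounds
        if not lo < hi:
            raise ValueError("sigma_ratio_bounds must satisfy lower < upper")
        for name in ("k_neighbors", "n_top_genes", "min_shared_counts",
                     "smoothing_kernel", "tree_min_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.normalization_mode not in ("sum", "max"):
            raise ValueError("normalization_mode must be 'sum' or 'max'")

    def to_dict(self) -> dict:
        out = asdict(self)
        for k, v in out.items():         # tuples are not h5ad-serializable
            if isinstance(v, tuple):
                out[k] = list(v)
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def resolve_layer(adata: ad.AnnData, canonical: str) -> str:
    """Return the layer name in ``adata`` matching a canonical name."""
    for name in LAYER_ALIASES.get(canonical, (canonical,)):
        if name in adata.layers:
            return name
    raise KeyError(
        f"layer {canonical!r} not found; available layers: "
        f"{sorted(adata.layers.keys())}"
    )


def validate_dataset(adata: ad.AnnData, require_clusters: bool = False) -> None:
    """Check the expression-dataset contract; raise ``ValueError`` on breach."""
    s = adata.layers[resolve_layer(adata, "spliced")]
    u = adata.layers[resolve_layer(adata, "unspliced")]
    if s.shape != u.shape or s.shape != adata.shape:
        raise ValueError(
            f"spliced {s.shape} and unspliced {u.shape} layers must both match "
            f"the container shape {adata.shape}"
        )
    if _dense(s).min() < 0 or _dense(u).min() < 0:
        raise ValueError("counts must be non-negative")
    if "knn_indices" in adata.obsm:
        knn = np.asarray(adata.obsm["knn_indices"])
        if (knn == np.arange(adata.n_obs)[:, None]).any():
            raise ValueError("knn lists must not contain the cell itself")
    if require_clusters:
        if "cluster" not in adata.obs:
            raise ValueError("cluster labels required; run cluster_cells first")
        if adata.obs["cluster"].nunique() < 2:
            raise ValueError("pipeline stages beyond I/O require >= 2 clusters")


def make_dataset(spliced, unspliced, *, cluster=None, embedding=None,
                 gene_names=None, cell_names=None) -> ad.AnnData:
    """Assemble a dataset from matrices; a convenience for tests/simulation."""
    spliced = np.asarray(spliced, dtype=float)
    unspliced = np.asarray(unspliced, dtype=float)
    n, g = spliced.shape
    adata = ad.AnnData(
        X=spliced.copy(),
        obs=pd.DataFrame(index=cell_names if cell_names is not None
                         else [f"cell_{i}" for i in range(n)]),
        var=pd.DataFrame(index=gene_names if gene_names is not None
                         else [f"gene_{j}" for j in range(g)]),
    )
    adata.layers["spliced"] = spliced
    adata.layers["unspliced"] = unspliced
    if cluster is not None:
        adata.obs["cluster"] = pd.Categorical([str(c) for c in cluster])
    if embedding is not None:
        adata.obsm["X_embed"] = np.asarray(embedding, dtype=float)
    validate_dataset(adata)
    return adata


# ---------------------------------------------------------------------------
# I/O: h5ad, loom, mtx directory
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = Path(path)
    if p.suffix == ".h5ad":
        return "h5ad"
    if p.suffix == ".loom":
        return "loom"
    if p.is_dir():
        return "mtx_dir"
    raise ValueError(f"cannot infer format of {path}")


def read_dataset(path: str | Path, fmt: str | None = None) -> ad.AnnData:
    """Read an expression dataset from h5ad, loom, or an MTX directory."""
    fmt = _infer_format(path, fmt)
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
    elif fmt == "loom":
        adata = _read_loom(path)
    elif fmt == "mtx_dir":
        adata = _read_mtx_dir(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    resolve_layer(adata, "spliced")
    resolve_layer(adata, "unspliced")
    validate_dataset(adata)
    return adata


def write_dataset(adata: ad.AnnData, path: str | Path, fmt: str | None = None) -> None:
    """Write a dataset so that :func:`read_dataset` reproduces it exactly."""
    fmt = _infer_format(path, fmt)
    if fmt == "h5ad":
        adata.write_h5ad(path)
    elif fmt == "loom":
        _write_loom(adata, path)
    elif fmt == "mtx_dir":
        _write_mtx_dir(adata, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# loom is plain HDF5: genes x cells /matrix plus /layers, /row_attrs (genes)
# and /col_attrs (cells).

def _read_loom(path) -> ad.AnnData:
    with h5py.File(path, "r") as f:
        x = f["matrix"][:].T
        layers = {k: f["layers"][k][:].T for k in f.get("layers", {})}
        var_names = [v.decode() if isinstance(v, bytes) else str(v)
                     for v in f["row_attrs"]["Gene"][:]]
        obs_names = [v.decode() if isinstance(v, bytes) else str(v)
                     for v in f["col_attrs"]["CellID"][:]]
        obs = {}
        for k in f["col_attrs"]:
            if k == "CellID":
                continue
            vals = f["col_attrs"][k][:]
            if vals.dtype.kind in "SO":
                vals = [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
            obs[k] = vals
    adata = ad.AnnData(X=x, obs=pd.DataFrame(obs, index=obs_names),
                       var=pd.DataFrame(index=var_names))
    for k, v in layers.items():
        adata.layers[k] = v
    return adata


def _write_loom(adata, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=_dense(adata.X).T)
        g = f.create_group("layers")
        for k, v in adata.layers.items():
            g.create_dataset(k, data=_dense(v).T)
        ra = f.create_group("row_attrs")
        ra.create_dataset("Gene", data=np.asarray(adata.var_names, dtype="S"))
        ca = f.create_group("col_attrs")
        ca.create_dataset("CellID", data=np.asarray(adata.obs_names, dtype="S"))
        for k in adata.obs.columns:
            vals = adata.obs[k].to_numpy()
            if vals.dtype.kind in "OUb" or str(adata.obs[k].dtype) == "category":
                vals = np.asarray(vals, dtype="S")
            ca.create_dataset(k, data=vals)


def _read_mtx_dir(path) -> ad.AnnData:
    p = Path(path)
    s = sp.csr_matrix(mmread(p / "spliced.mtx"))
    u = sp.csr_matrix(mmread(p / "unspliced.mtx"))
    barcodes = pd.read_csv(p / "barcodes.csv", header=None)[0].astype(str)
    genes = pd.read_csv(p / "genes.csv", header=None)[0].astype(str)
    adata = ad.AnnData(X=s.copy(), obs=pd.DataFrame(index=barcodes),
                       var=pd.DataFrame(index=genes))
    adata.layers["spliced"] = s
    adata.layers["unspliced"] = u
    obs_path = p / "obs.csv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, index_col=0)
        for c in obs.columns:
            adata.obs[c] = obs[c].to_numpy()
    return adata


def _write_mtx_dir(adata, path) -> None:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    mmwrite(p / "spliced.mtx",
            sp.coo_matrix(adata.layers[resolve_layer(adata, "spliced")]))
    mmwrite(p / "unspliced.mtx",
            sp.coo_matrix(adata.layers[resolve_layer(adata, "unspliced")]))
    pd.Series(adata.obs_names).to_csv(p / "barcodes.csv", index=False, header=False)
    pd.Series(adata.var_names).to_csv(p / "genes.csv", index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(p / "obs.csv")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def knn_indices_to_adjacency(knn: np.ndarray, n_cells: int,
                             symmetric: bool = True) -> sp.csr_matrix:
    """Binary adjacency from a (cells x k) neighbor-index array."""
    n, k = knn.shape
    rows = np.repeat(np.arange(n), k)
    a = sp.csr_matrix((np.ones(n * k), (rows, knn.ravel())), shape=(n_cells, n_cells))
    if symmetric:
        a = a.maximum(a.T)
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def _build_knn(points: np.ndarray, k: int) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(k + 1, len(points)))
    nn.fit(points)
    idx = nn.kneighbors(points, return_distance=False)
    # drop self (first column when present; guard against exact duplicates)
    out = np.empty((len(points), min(k, len(points) - 1)), dtype=int)
    for i in range(len(points)):
        row = idx[i][idx[i] != i][: out.shape[1]]
        if len(row) < out.shape[1]:          # duplicate coordinates
            pad = [j for j in idx[i] if j != i][: out.shape[1]]
            row = np.asarray(pad)
        out[i] = row
    return out


def preprocess(adata: ad.AnnData, cfg: PipelineConfig | None = None) -> ad.AnnData:
    """Filter, normalize, log-transform, select HVGs, build kNN, smooth.

    Genes observed (u > 0 and s > 0 simultaneously) in fewer than
    ``min_shared_counts`` cells are removed; the top ``n_top_genes`` highly
    variable genes are retained; both layers are size-normalized and
    log1p-transformed; the kNN graph is built on the PCA of the log spliced
    counts; smoothed layers ``Ms``/``Mu`` are the mean over each cell's own
    value plus its k nearest neighbors (first-order moments convention).

    Idempotent: a second application returns the input unchanged.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if adata.uns.get("preprocessed", False):
        return adata
    s_name = resolve_layer(adata, "spliced")
    u_name = resolve_layer(adata, "unspliced")
    s = _dense(adata.layers[s_name]).astype(float)
    u = _dense(adata.layers[u_name]).astype(float)

    shared = ((s > 0) & (u > 0)).sum(axis=0)
    keep = shared >= cfg.min_shared_counts
    if not keep.any():
        raise ValueError("no gene passes the shared-counts filter")
    adata = adata[:, keep].copy()
    s, u = s[:, keep], u[:, keep]

    # per-cell size normalization (median total as target), then log1p
    for mat in (s, u):
        totals = mat.sum(axis=1)
        totals[totals == 0] = 1.0
        target = np.median(totals)
        mat *= (target / totals)[:, None]
    s = np.log1p(s)
    u = np.log1p(u)

    # highly variable genes on the log spliced layer
    n_top = cfg.n_top_genes
    if adata.n_vars <= n_top:
        logger.warning(
            "requested %d highly variable genes but only %d genes remain; "
            "keeping all", n_top, adata.n_vars)
        hvg_mask = np.ones(adata.n_vars, dtype=bool)
    else:
        import scanpy as sc
        tmp = ad.AnnData(X=s.copy())
        sc.pp.highly_variable_genes(tmp, n_top_genes=n_top, flavor="seurat")
        hvg_mask = tmp.var["highly_variable"].to_numpy()
    adata = adata[:, hvg_mask].copy()
    s, u = s[:, hvg_mask], u[:, hvg_mask]
    adata.layers["spliced_log"] = s
    adata.layers["unspliced_log"] = u

    from sklearn.decomposition import PCA

    n_pcs = int(min(cfg.n_pcs, adata.n_vars - 1, adata.n_obs - 1))
    pca = PCA(n_components=n_pcs, svd_solver="full",
              random_state=cfg.random_seed)
    adata.obsm["X_pca"] = pca.fit_transform(s - s.mean(axis=0))

    knn = _build_knn(adata.obsm["X_pca"], cfg.k_neighbors)
    adata.obsm["knn_indices"] = knn

    # smoothing: mean over self + k neighbors
    n = adata.n_obs
    smooth = sp.csr_matrix(
        (np.ones(knn.size), (np.repeat(np.arange(n), knn.shape[1]), knn.ravel())),
        shape=(n, n))
    smooth = smooth + sp.eye(n, format="csr")
    smooth = sp.diags(1.0 / np.asarray(smooth.sum(axis=1)).ravel()) @ smooth
    adata.layers["Ms"] = smooth @ s
    adata.layers["Mu"] = smooth @ u

    adata.uns["preprocessed"] = True
    adata.uns["config"] = cfg.to_dict()
    return adata


def cluster_cells(adata: ad.AnnData, cfg: PipelineConfig | None = None) -> ad.AnnData:
    """Leiden community detection on the kNN graph (no-op if labels exist).

    Deterministic given ``cfg.random_seed``; resolution from
    ``cfg.leiden_resolution``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if "cluster" in adata.obs:
        return adata
    if "knn_indices" not in adata.obsm:
        raise ValueError("kNN graph missing: run preprocess first")
    import igraph
    import leidenalg

    adj = knn_indices_to_adjacency(np.asarray(adata.obsm["knn_indices"]),
                                   adata.n_obs)
    sources, targets = adj.nonzero()
    mask = sources < targets
    graph = igraph.Graph(n=adata.n_obs,
                         edges=list(zip(sources[mask], targets[mask])))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=cfg.leiden_resolution, seed=cfg.random_seed)
    adata.obs["cluster"] = pd.Categorical([str(m) for m in part.membership])
    logger.info("leiden found %d clusters at resolution %.2f",
                adata.obs["cluster"].nunique(), cfg.leiden_resolution)
    return adata
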