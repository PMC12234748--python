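"""Evaluation metrics for inferred velocity fields.

Cross-boundary direction correctness (CBDir) scores whether velocities of
cells in cluster A point toward their neighbors in cluster B for each
expected developmental edge A -> B, either in the 2-D embedding or in gene
space. TransCosine averages the velocity-graph cosines over the same
cross-boundary pairs. VeloCoh compares each cell's velocity with the
displacement toward its transition-predicted future state. Sign accuracy
(cell-cycle benchmarks) compares the componentwise three-way signs of the
inferred and empirical velocities along an external position axis.

All scores over pairs/edges/cells are reported as means over the
contributing items; empty contributions are excluded as undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .velocity import VelocityField, VelocityGraph


@dataclass
class MetricsReport:
    cbdir_umap: dict[tuple[str, str], float] | None = None
    cbdir_gene: dict[tuple[str, str], float] | None = None
    trans_cosine: dict[tuple[str, str], float] | None = None
    velo_coh: np.ndarray | None = None
    sign_acc: np.ndarray | None = None

    def mean(self, name: str) -> float:
        val = getattr(self, name)
        if isinstance(val, dict):
            vals = [v for v in val.values() if np.isfinite(v)]
            return float(np.mean(vals)) if vals else float("nan")
        arr = np.asarray(val, dtype=float)
        arr = arr[np.isfinite(arr)]
        return float(arr.mean()) if len(arr) else float("nan")


def _check_edges(labels, edges):
    known = set(labels)
    for a, b in edges:
        if a == b:
            raise ValueError(f"cluster edge ({a}, {b}) must join two clusters")
        if a not in known or b not in known:
            raise ValueError(f"unknown cluster in edge ({a}, {b})")


def _cosine_rows(a: np.ndarray, b: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > eps) & (nb > eps)
    out = np.full(len(a), np.nan)
    out[ok] = (a[ok] * b[ok]).sum(axis=1) / (na[ok] * nb[ok])
    return out


def cbdir(adata, velocities: np.ndarray, edges, knn: np.ndarray | None = None,
          space: str = "gene") -> dict[tuple[str, str], float]:
    """Per-edge cross-boundary direction correctness.

    For each edge (A, B), the mean over pairs (n in A, n' in kNN(n) and B) of
    cos(v_n, x_{n'} - x_n) where x is the embedding position
    (``space="umap"``, with embedding velocities) or the smoothed spliced
    expression (``space="gene"``). Edges without contributing pairs map to
    NaN and are excluded from means.
    """
    labels = adata.obs["cluster"].astype(str).to_numpy()
    _check_edges(labels, edges)
    if knn is None:
        knn = np.asarray(adata.obsm["knn_indices"])
    if space == "umap":
        x = np.asarray(adata.obsm["X_embed"], dtype=float)
    elif space == "gene":
        x = np.asarray(adata.layers["Ms"])
    else:
        raise ValueError(f"unknown space {space!r}")
    v = np.asarray(velocities)
    out = {}
    for a, b in edges:
        rows, cols = _boundary_pairs(labels, knn, a, b)
        if len(rows) == 0:
            out[(a, b)] = float("nan")
            continue
        cos = _cosine_rows(v[rows], x[cols] - x[rows])
        cos = cos[np.isfinite(cos)]
        out[(a, b)] = float(cos.mean()) if len(cos) else float("nan")
    return out


def _boundary_pairs(labels, knn, a, b):
    in_a = np.nonzero(labels == a)[0]
    nb = knn[in_a]
    hit = labels[nb] == b
    rows = np.repeat(in_a, hit.sum(axis=1))
    cols = nb[hit]
    return rows, cols


def trans_cosine(adata, vg: VelocityGraph, edges) -> dict[tuple[str, str], float]:
    """Mean velocity-graph cosine pi over cross-boundary neighbor pairs."""
    labels = adata.obs["cluster"].astype(str).to_numpy()
    _check_edges(labels, edges)
    out = {}
    for a, b in edges:
        in_a = np.nonzero(labels == a)[0]
        hit = labels[vg.knn[in_a]] == b
        vals = vg.pi[in_a][hit]
        out[(a, b)] = float(vals.mean()) if vals.size else float("nan")
    return out


def velo_coh(adata, vf: VelocityField, vg: VelocityGraph) -> np.ndarray:
    """Per-cell coherence between velocity and predicted displacement.

    The transition matrix here is pi divided by its row sums (the stated
    simplification). Velocity-graph convention keeps only non-negative
    cosines, so pi is clipped at zero first — otherwise rows whose signed
    cosines sum to a negative number would have their predicted
    displacement inverted by the normalizer. Cells with no positive entry,
    zero displacement or zero velocity are undefined (NaN).
    """
    s = np.asarray(adata.layers["Ms"])
    pi_pos = np.clip(vg.pi, 0.0, None)
    row_sums = pi_pos.sum(axis=1)
    ok = row_sums > 1e-12
    pt = np.where(ok[:, None], pi_pos / np.where(ok, row_sums, 1.0)[:, None], 0.0)
    pred = np.einsum("nk,nkg->ng", pt, s[vg.knn])
    disp = pred - s
    out = _cosine_rows(disp, vf.v_s)
    out[~ok] = np.nan
    return out


def sign_accuracy(s: np.ndarray, velocities: np.ndarray,
                  positions: np.ndarray, eps: float = 1e-8,
                  difference_form: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-position sign agreement between empirical and inferred velocity.

    Cells are grouped by their (ordered) position values. The empirical
    velocity at position p_i is the difference of mean spliced expression
    toward p_{i+1}; the estimated velocity is the per-position mean of the
    inferred velocities (or, with ``difference_form``, the forward
    difference of those means). Vectors are rescaled by their largest
    absolute component before the three-way sign (+/0/-, |.| < eps is zero)
    is compared componentwise; the last position has no successor and is
    excluded. Returns (unique positions scored, accuracy per position).
    """
    positions = np.asarray(positions, dtype=float)
    uniq = np.unique(positions)
    if len(uniq) < 2:
        raise ValueError("sign accuracy requires at least two positions")
    s_bar = np.stack([s[positions == p].mean(axis=0) for p in uniq])
    v_bar = np.stack([velocities[positions == p].mean(axis=0) for p in uniq])
    emp = s_bar[1:] - s_bar[:-1]
    est = v_bar[1:] - v_bar[:-1] if difference_form else v_bar[:-1]

    def _sign(x):
        scale = np.abs(x).max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        xs = x / scale
        return np.where(xs > eps, 1, np.where(xs < -eps, -1, 0))

    acc = (_sign(emp) == _sign(est)).mean(axis=1)
    return uniq[:-1], acc
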