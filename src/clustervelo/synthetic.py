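"""Synthetic spliced/unspliced kinetics along branching lineages.

Generates datasets with known ground truth so every pipeline stage has a
parameter-recovery test. Each gene follows the standard splicing kinetics

    u'(t) = alpha(t) - beta * u(t)
    s'(t) = beta * u(t) - gamma * s(t)

with piecewise-constant transcription rate ``alpha`` (possibly branch- and
time-dependent), solved piecewise in closed form from (u, s) = (0, 0) at the
lineage root. Because ``u`` integrates ``alpha`` first and ``s`` integrates
``u``, unspliced RNA leads spliced RNA during both induction and repression —
the property the orientation score exploits. MURK genes receive a step
*increase* of ``alpha`` partway through development before the eventual
switch to repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import make_dataset

Schedule = tuple[tuple[float, float], ...]   # ((start_time, rate), ...)


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster (tree node): parent link, cell count and time interval."""

    name: str
    parent: str | None
    n_cells: int
    duration: float
    branch: str = "trunk"
    #: unobserved lead-in before the observed interval; dynamics keep running
    #: through it (root warm-up, or a fast fate-commitment transition)
    t0: float = 0.0

    def __post_init__(self):
        if self.n_cells <= 0 or self.duration <= 0:
            raise ValueError("cell counts and durations must be positive")
        if self.t0 < 0:
            raise ValueError("warm-up offset must be non-negative")


@dataclass(frozen=True)
class LineageSpec:
    """A forest of clusters; more than one root models weakly connected islands."""

    clusters: tuple[ClusterSpec, ...]

    def __post_init__(self):
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cluster names")
        for c in self.clusters:
            if c.parent is not None and c.parent not in names:
                raise ValueError(f"unknown parent {c.parent!r}")
        # acyclicity: walking parents must terminate
        by_name = {c.name: c for c in self.clusters}
        for c in self.clusters:
            seen, cur = set(), c
            while cur.parent is not None:
                if cur.name in seen:
                    raise ValueError("lineage tree contains a cycle")
                seen.add(cur.name)
                cur = by_name[cur.parent]

    @property
    def roots(self) -> list[str]:
        return [c.name for c in self.clusters if c.parent is None]

    def chain(self, name: str) -> list[ClusterSpec]:
        """Root-to-node chain of clusters."""
        by_name = {c.name: c for c in self.clusters}
        out = [by_name[name]]
        while out[0].parent is not None:
            out.insert(0, by_name[out[0].parent])
        return out

    def t_start(self, name: str) -> float:
        chain = self.chain(name)
        return sum(c.t0 for c in chain) + sum(c.duration for c in chain[:-1])

    def edges(self) -> list[tuple[str, str]]:
        return [(c.parent, c.name) for c in self.clusters if c.parent is not None]


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic rates of one gene.

    ``alpha`` is the default transcription schedule as (start_time, rate)
    breakpoints; ``branch_alpha`` overrides it on named branches (the override
    takes effect while the lineage runs through clusters of that branch).
    """

    alpha: Schedule
    beta: float = 2.0
    gamma: float = 1.0
    branch_alpha: tuple[tuple[str, Schedule], ...] = ()
    is_murk: bool = False
    switch_time: float | None = None

    def __post_init__(self):
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        for schedule in (self.alpha, *[s for _, s in self.branch_alpha]):
            for t0, rate in schedule:
                if not np.isfinite(rate) or rate < 0:
                    raise ValueError("alpha rates must be finite and >= 0")

    def schedule_for(self, branch: str) -> Schedule:
        return dict(self.branch_alpha).get(branch, self.alpha)


@dataclass
class GroundTruth:
    """Latent state recorded by the simulator for downstream tests."""

    latent_time: np.ndarray          # per cell
    cluster: np.ndarray              # per cell (str)
    branch: np.ndarray               # per cell (str)
    edges: list[tuple[str, str]]     # true parent -> child cluster edges
    root: str                        # root cluster of the primary tree
    u_true: np.ndarray               # noiseless u (cells x genes)
    s_true: np.ndarray               # noiseless s
    v_u: np.ndarray                  # alpha - beta u (noiseless)
    v_s: np.ndarray                  # beta u - gamma s (noiseless)
    murk_mask: np.ndarray            # per gene


# ---------------------------------------------------------------------------
# closed-form piecewise solution
# ---------------------------------------------------------------------------

def _advance(u0, s0, alpha, beta, gamma, dt):
    """State after time dt under constant alpha (closed form)."""
    a_b = alpha / beta
    d = u0 - a_b
    u = a_b + d * np.exp(-beta * dt)
    a_g = alpha / gamma
    if abs(beta - gamma) > 1e-10:
        e = beta * d / (gamma - beta)
        c = s0 - a_g - e
        s = a_g + e * np.exp(-beta * dt) + c * np.exp(-gamma * dt)
    else:                                   # resonant case beta == gamma
        c = s0 - a_g
        s = a_g + beta * d * dt * np.exp(-beta * dt) + c * np.exp(-gamma * dt)
    return u, s


def _alpha_pieces(spec: LineageSpec, gene: GeneKinetics, leaf_cluster: str):
    """Piecewise-constant alpha along the root-to-cluster chain.

    Returns a list of (t0, t1, alpha) covering [0, t_end of the cluster].
    """
    pieces = []
    t = 0.0
    for c in spec.chain(leaf_cluster):
        t_end = t + c.t0 + c.duration
        schedule = gene.schedule_for(c.branch)
        starts = [s for s, _ in schedule]
        # breakpoints of the schedule falling inside this cluster interval
        cuts = sorted({t, t_end, *[b for b in starts if t < b < t_end]})
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            rate = 0.0
            for b, r in schedule:
                if b <= lo + 1e-12:
                    rate = r
            pieces.append((lo, hi, rate))
        t = t_end
    return pieces


def evaluate_gene(spec: LineageSpec, gene: GeneKinetics, cluster: str,
                  times: np.ndarray):
    """Noiseless (u, s, alpha) of one gene at absolute latent times.

    ``times`` must lie within the time interval of ``cluster``; the state is
    propagated from (0, 0) at the root of the cluster's tree.
    """
    pieces = _alpha_pieces(spec, gene, cluster)
    u = np.empty_like(times, dtype=float)
    s = np.empty_like(times, dtype=float)
    a = np.empty_like(times, dtype=float)
    u0, s0 = 0.0, 0.0
    for t0, t1, alpha in pieces:
        inside = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        if inside.any():
            dt = times[inside] - t0
            u[inside], s[inside] = _advance(u0, s0, alpha, gene.beta,
                                            gene.gamma, dt)
            a[inside] = alpha
        u0, s0 = _advance(u0, s0, alpha, gene.beta, gene.gamma, t1 - t0)
    at_end = times >= pieces[-1][1] - 1e-12
    if at_end.any():
        u[at_end], s[at_end] = u0, s0
        a[at_end] = pieces[-1][2]
    return u, s, a


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(spec: LineageSpec, genes: list[GeneKinetics],
             noise: str | tuple = "none", seed: int = 0,
             latent_times: dict[str, np.ndarray] | None = None):
    """Simulate a dataset; returns ``(AnnData, GroundTruth)``.

    noise: ``"none"``, ``("poisson", scale)`` (counts drawn from
    Poisson(scale * value)), or ``("gaussian", sigma)`` (additive, clipped at
    zero). ``latent_times`` optionally fixes the per-cluster cell times.
    Bitwise reproducible given ``seed``.
    """
    if len(genes) == 0:
        raise ValueError("at least one gene required")
    span = {c.name: (LineageSpec.t_start(spec, c.name),
                     LineageSpec.t_start(spec, c.name) + c.duration)
            for c in spec.clusters}
    for g in genes:
        if g.switch_time is not None:
            total = max(hi for _, hi in span.values())
            if not 0 < g.switch_time < total:
                raise ValueError("switch_time outside the simulated span")

    rng = np.random.default_rng(seed)
    cells_t, cells_cluster, cells_branch = [], [], []
    for c in spec.clusters:
        lo, hi = span[c.name]
        if latent_times is not None and c.name in latent_times:
            t = np.asarray(latent_times[c.name], dtype=float)
        else:
            t = np.sort(rng.uniform(lo, hi, size=c.n_cells))
        cells_t.append(t)
        cells_cluster += [c.name] * len(t)
        cells_branch += [c.branch] * len(t)
    t_all = np.concatenate(cells_t)
    cluster_all = np.asarray(cells_cluster)
    branch_all = np.asarray(cells_branch)
    n, G = len(t_all), len(genes)

    u = np.zeros((n, G))
    s = np.zeros((n, G))
    alpha_at = np.zeros((n, G))
    for j, gene in enumerate(genes):
        for c in spec.clusters:
            mask = cluster_all == c.name
            u[mask, j], s[mask, j], alpha_at[mask, j] = evaluate_gene(
                spec, gene, c.name, t_all[mask])

    betas = np.array([g.beta for g in genes])
    gammas = np.array([g.gamma for g in genes])
    v_u = alpha_at - betas[None, :] * u
    v_s = betas[None, :] * u - gammas[None, :] * s

    u_obs, s_obs = u.copy(), s.copy()
    if noise != "none":
        kind, param = noise
        if kind == "poisson":
            u_obs = rng.poisson(param * u).astype(float)
            s_obs = rng.poisson(param * s).astype(float)
        elif kind == "gaussian":
            u_obs = np.clip(u + rng.normal(0, param, u.shape), 0, None)
            s_obs = np.clip(s + rng.normal(0, param, s.shape), 0, None)
        else:
            raise ValueError(f"unknown noise kind {kind!r}")

    adata = make_dataset(s_obs, u_obs, cluster=cluster_all)
    adata.obsm["X_embed"] = _pca2(np.log1p(s_obs))
    adata.obs["latent_time"] = t_all

    primary_root = spec.roots[0]
    truth = GroundTruth(
        latent_time=t_all, cluster=cluster_all, branch=branch_all,
        edges=spec.edges(), root=primary_root,
        u_true=u, s_true=s, v_u=v_u, v_s=v_s,
        murk_mask=np.array([g.is_murk for g in genes]))
    adata.uns["true_edges"] = [list(e) for e in spec.edges()]
    adata.uns["true_root"] = primary_root
    return adata, truth


def _pca2(x: np.ndarray) -> np.ndarray:
    from sklearn.decomposition import PCA
    k = int(min(2, x.shape[1], x.shape[0] - 1))
    out = np.zeros((x.shape[0], 2))
    centered = x - x.mean(0)
    if k > 0 and np.abs(centered).max() > 0:
        out[:, :k] = PCA(n_components=k,
                         svd_solver="full").fit_transform(centered)[:, :k]
    return out


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

#: Poisson capture scale for noisy fixtures: counts of order tens per gene,
#: i.e. moderate shot noise relative to the kinetic signal.
FIXTURE_POISSON_SCALE = 20.0


def _random_genes(rng, n_genes, total_span, murk_fraction=0.0, branches=()):
    """Gene panel with staggered onset/switch times; optional MURK subset."""
    genes = []
    n_murk = int(round(murk_fraction * n_genes))
    for j in range(n_genes):
        a0 = rng.uniform(2.0, 8.0)
        onset = rng.uniform(0.0, 0.55 * total_span)
        switch = onset + rng.uniform(0.25 * total_span, 0.45 * total_span)
        switch = min(switch, 0.95 * total_span)
        is_murk = j < n_murk
        if is_murk:
            t_step = onset + 0.4 * (switch - onset)
            sched = ((0.0, 0.0), (onset, a0), (t_step, 3.0 * a0), (switch, 0.0))
        else:
            sched = ((0.0, 0.0), (onset, a0), (switch, 0.0))
        branch_alpha = ()
        if branches:
            # assign the gene's program to one branch; silent elsewhere
            b = branches[j % len(branches)]
            if b is not None:
                branch_alpha = ((b, sched),)
                sched = ((0.0, 0.0),)
        genes.append(GeneKinetics(alpha=sched, beta=2.0, gamma=1.0,
                                  branch_alpha=branch_alpha,
                                  is_murk=is_murk, switch_time=switch))
    return genes


def make_fixture(name: str, seed: int = 0, n_cells: int = 2000,
                 n_genes: int = 200, noise: str | tuple | None = None):
    """Canned datasets with ground truth: ``linear``, ``bifurcation``,
    ``murk_mix``, ``cycle``, ``islands``.

    ``noise=None`` selects the fixture default (Poisson counts at
    ``FIXTURE_POISSON_SCALE`` except for ``cycle``, which is noiseless).
    """
    rng = np.random.default_rng(seed)
    if name == "linear":
        per = n_cells // 5
        spec = LineageSpec(tuple(
            ClusterSpec(f"c{i}", None if i == 0 else f"c{i-1}", per, 2.0)
            for i in range(5)))
        genes = _random_genes(rng, n_genes, total_span=10.0)
    elif name == "murk_mix":
        per = n_cells // 5
        spec = LineageSpec(tuple(
            ClusterSpec(f"c{i}", None if i == 0 else f"c{i-1}", per, 2.0)
            for i in range(5)))
        genes = _random_genes(rng, n_genes, total_span=10.0, murk_fraction=0.35)
    elif name == "bifurcation":
        # progenitor pool largest, secondary branch lightest: keeps subtree
        # masses distinct so the greedy path is non-degenerate
        f = [0.34, 0.20, 0.14, 0.12, 0.10, 0.10]
        counts = [max(1, int(round(x * n_cells))) for x in f]
        spec = LineageSpec((
            ClusterSpec("root", None, counts[0], 2.0),
            ClusterSpec("trunk", "root", counts[1], 2.0),
            ClusterSpec("a1", "trunk", counts[2], 2.0, branch="A"),
            ClusterSpec("a2", "a1", counts[3], 2.0, branch="A"),
            ClusterSpec("b1", "trunk", counts[4], 2.0, branch="B"),
            ClusterSpec("b2", "b1", counts[5], 2.0, branch="B"),
        ))
        # asynchronous branch programs: A ignites at the branch point, B
        # only midway through its first cluster, so the two branch-entry
        # populations are not transcriptionally coincident
        genes = []
        for j in range(n_genes):
            a0 = rng.uniform(2.0, 8.0)
            kind = ("shared", "A", "B")[j % 3]
            if kind == "shared":
                onset = rng.uniform(0.0, 3.5)
                switch = min(onset + rng.uniform(1.5, 3.0), 7.9)
            elif kind == "A":
                onset = rng.uniform(4.0, 4.4)
                switch = min(onset + rng.uniform(1.8, 2.8), 7.9)
            else:
                onset = rng.uniform(4.6, 7.0)
                switch = min(onset + rng.uniform(1.5, 2.5), 7.9)
            sched = ((0.0, 0.0), (onset, a0), (switch, 0.0))
            if kind == "shared":
                genes.append(GeneKinetics(alpha=sched, switch_time=switch))
            else:
                genes.append(GeneKinetics(alpha=((0.0, 0.0),),
                                          branch_alpha=((kind, sched),),
                                          switch_time=switch))
    elif name == "islands":
        main = n_cells * 4 // 5 // 4
        isl = n_cells // 5 // 2
        spec = LineageSpec((
            ClusterSpec("m0", None, main, 2.0, branch="main", t0=0.5),
            ClusterSpec("m1", "m0", main, 2.0, branch="main"),
            ClusterSpec("m2", "m1", main, 2.0, branch="main"),
            ClusterSpec("m3", "m2", main, 2.0, branch="main"),
            ClusterSpec("i0", None, isl, 2.0, branch="island", t0=2.0),
            ClusterSpec("i1", "i0", isl, 2.0, branch="island"),
        ))
        genes = _random_genes(rng, n_genes, total_span=8.0,
                              branches=("main", "main", "main", "island"))
    elif name == "cycle":
        return _make_cycle_fixture(seed, n_genes=min(n_genes, 30))
    else:
        raise ValueError(f"unknown fixture {name!r}")

    if noise is None:
        noise = ("poisson", FIXTURE_POISSON_SCALE)
    return simulate(spec, genes, noise=noise, seed=seed)


def make_rate_recovery_dataset(seed: int = 0, n_cells: int = 1000,
                               n_genes: int = 40):
    """Zero-noise dataset for kinetic-rate recovery experiments.

    Cell-uniform rates per gene with gamma log-uniform over [0.2, 5] and an
    early induction switch-off (switch in [2, 4] of a span of 10), so most
    of the trajectory samples the repression phase where the degradation
    rate governs the decay of s and is well identified. Returns
    ``(AnnData, GroundTruth, gamma_true)``.
    """
    rng = np.random.default_rng(seed)
    per = n_cells // 5
    spec = LineageSpec(tuple(
        ClusterSpec(f"c{i}", None if i == 0 else f"c{i-1}", per, 2.0)
        for i in range(5)))
    gamma_true = np.exp(rng.uniform(np.log(0.2), np.log(5.0), n_genes))
    genes = [GeneKinetics(alpha=((0.0, rng.uniform(2.0, 8.0)),
                                 (rng.uniform(2.0, 4.0), 0.0)),
                          beta=2.0, gamma=float(g))
             for g in gamma_true]
    adata, truth = simulate(spec, genes, noise="none", seed=seed)
    return adata, truth, gamma_true


def _make_cycle_fixture(seed: int, n_genes: int = 30, cells_per_pos: int = 5):
    """Cells on a circular (cell-cycle-like) position axis, noiseless.

    Discrete positions are chosen so that between consecutive positions every
    gene's spliced velocity keeps a constant sign: the base grid avoids a
    margin around each velocity zero-crossing, and one position is inserted
    just after each crossing. On such a grid the sign of the forward
    difference of mean spliced expression equals the sign of the velocity at
    the left position, so sign accuracy of the true velocities is exactly 1.
    """
    rng = np.random.default_rng(seed)
    total = 10.0
    spec = LineageSpec(tuple(
        ClusterSpec(f"q{i}", None if i == 0 else f"q{i-1}", 1, total / 4)
        for i in range(4)))
    # every gene is active from t = 0 so its velocity is never exactly zero
    # on the observed grid (a silent phase would break the sign guarantee)
    genes = [GeneKinetics(alpha=((0.0, rng.uniform(2.0, 8.0)),
                                 (rng.uniform(0.3, 0.8) * total, 0.0)),
                          beta=2.0, gamma=1.0)
             for _ in range(n_genes)]

    # dense scan of v_s(t) for zero crossings
    t_dense = np.linspace(1e-6, total - 1e-6, 20001)
    crossings = []
    for gene in genes:
        v = _velocity_on_grid(spec, gene, t_dense)
        sign = np.sign(v)
        idx = np.nonzero(np.diff(np.signbit(v)) & (np.abs(v[:-1]) > 1e-12))[0]
        for i in idx:
            # linear interpolation of the crossing time
            t0, t1 = t_dense[i], t_dense[i + 1]
            v0, v1 = v[i], v[i + 1]
            crossings.append(t0 - v0 * (t1 - t0) / (v1 - v0))
        del sign
    crossings = np.sort(np.asarray(crossings))
    # merge near-coincident crossings; one grid point just after the last
    merged = []
    for c in crossings:
        if merged and c - merged[-1][-1] < 0.02:
            merged[-1].append(c)
        else:
            merged.append([c])
    inserts = np.asarray([grp[-1] for grp in merged])

    base = np.linspace(0.2, total - 0.2, 41)
    margin, delta = 0.12, 1e-3
    keep = np.ones(len(base), bool)
    for c in crossings:
        keep &= ~((base > c - margin) & (base < c + margin))
    grid = np.sort(np.concatenate([base[keep], inserts + delta]))
    grid = grid[(grid > 0) & (grid < total)]

    per_cluster: dict[str, list[float]] = {c.name: [] for c in spec.clusters}
    for t in grid:
        i = min(int(t // (total / 4)), 3)
        per_cluster[f"q{i}"] += [t] * cells_per_pos
    latent = {k: np.asarray(v) for k, v in per_cluster.items() if v}
    spec = LineageSpec(tuple(
        ClusterSpec(c.name, c.parent, max(1, len(latent.get(c.name, [0]))),
                    c.duration) for c in spec.clusters))
    adata, truth = simulate(spec, genes, noise="none", seed=seed,
                            latent_times=latent)
    adata.obs["cycle_position"] = truth.latent_time
    return adata, truth


def _velocity_on_grid(spec, gene, times):
    out = np.empty_like(times)
    for c in spec.clusters:
        lo = spec.t_start(c.name)
        hi = lo + c.duration
        m = (times >= lo) & (times < hi) if c.name != spec.clusters[-1].name \
            else (times >= lo)
        u, s, _ = evaluate_gene(spec, gene, c.name, times[m])
        out[m] = gene.beta * u - gene.gamma * s
    return out
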