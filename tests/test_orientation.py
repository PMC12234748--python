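"""Pseudotime, series extraction, linear trees, and the orientation score."""

import numpy as np
import pytest

import clustervelo as cv
from clustervelo import orientation as ori
from clustervelo.datamodel import PipelineConfig


# ---------------------------------------------------------------------------
# diffusion pseudotime
# ---------------------------------------------------------------------------

def _chain_adjacency(n):
    import scipy.sparse as sp
    rows = np.arange(n - 1)
    a = sp.csr_matrix((np.ones(n - 1), (rows, rows + 1)), shape=(n, n))
    return (a + a.T).tocsr()


def test_pseudotime_root_is_origin_of_ordering():
    adj = _chain_adjacency(40)
    t = ori.diffusion_pseudotime(adj, root=0)
    assert np.argmin(t) == 0


def test_pseudotime_rank_matches_chain_position():
    adj = _chain_adjacency(40)
    t = ori.diffusion_pseudotime(adj, root=0)
    # oracle: shortest-path distance along the chain is simply the index
    assert np.array_equal(np.argsort(t), np.arange(40))


def test_pseudotime_reversed_root_reverses_ranks():
    adj = _chain_adjacency(40)
    t0 = ori.diffusion_pseudotime(adj, root=0)
    t1 = ori.diffusion_pseudotime(adj, root=39)
    assert np.array_equal(np.argsort(t1), np.argsort(t0)[::-1])


# ---------------------------------------------------------------------------
# series extraction
# ---------------------------------------------------------------------------

def test_smoothing_hand_convolution():
    y = np.array([[0.0], [0.0], [1.0], [0.0], [0.0]])
    sm, valid = ori.smooth_and_normalize(y, kernel=3, mode="max")
    # pre-normalization smoothing is [0, 1/3, 1/3, 1/3, 0]; max-scale by 1/3
    np.testing.assert_allclose(sm[:, 0], [0, 1, 1, 1, 0])
    assert valid[0]


def test_constant_series_uniform_after_sum_normalization():
    y = np.full((20, 1), 4.2)
    sm, valid = ori.smooth_and_normalize(y, kernel=100, mode="sum")
    np.testing.assert_allclose(sm[:, 0], 1.0 / 20)


def test_sum_normalization_sums_to_one():
    rng = np.random.default_rng(0)
    y = rng.uniform(0, 5, (37, 4))
    sm, valid = ori.smooth_and_normalize(y, kernel=10, mode="sum")
    np.testing.assert_allclose(sm.sum(axis=0), 1.0, atol=1e-9)


def test_all_zero_gene_flagged_invalid():
    y = np.zeros((15, 1))
    _, valid = ori.smooth_and_normalize(y, kernel=5)
    assert not valid[0]


# ---------------------------------------------------------------------------
# linear tree
# ---------------------------------------------------------------------------

def test_linear_tree_finds_single_kink():
    x = np.arange(100, dtype=float)
    y = np.where(x < 40, 2.0 * x, 80.0 - 1.5 * (x - 40))
    tree = ori.fit_linear_tree(y)
    assert len(tree.split_points) == 1
    assert abs(tree.split_points[0] - 40) <= 1
    assert sum(s.sse for s in tree.segments) < 1e-16
    # exhaustive oracle over all admissible splits
    best = min(range(10, 91),
               key=lambda c: np.polyfit(x[:c], y[:c], 1, full=True)[1][0]
               + np.polyfit(x[c:], y[c:], 1, full=True)[1][0])
    assert abs(best - tree.split_points[0]) <= 1


def test_linear_tree_straight_line_single_segment():
    x = np.arange(60, dtype=float)
    y = 3.0 * x + 1.0
    tree = ori.fit_linear_tree(y)
    assert len(tree.segments) == 1
    assert tree.segments[0].slope == pytest.approx(3.0, abs=1e-10)
    assert tree.segments[0].intercept == pytest.approx(1.0, abs=1e-8)


def test_linear_tree_too_short_to_split():
    y = np.sin(np.arange(15))
    tree = ori.fit_linear_tree(y)
    assert len(tree.segments) == 1


def test_linear_tree_mse_trace_non_increasing():
    rng = np.random.default_rng(1)
    y = np.cumsum(rng.normal(0, 1, 300))
    tree = ori.fit_linear_tree(y)
    assert all(b <= a + 1e-12 for a, b in zip(tree.mse_trace, tree.mse_trace[1:]))
    for seg in tree.segments:
        assert seg.end - seg.start >= 10


def test_linear_tree_absolute_mode_keeps_single_segment():
    # normalized series: an absolute MSE drop of 100 is unreachable
    rng = np.random.default_rng(2)
    y = rng.uniform(0, 1, 200)
    y = y / y.sum()
    cfg = PipelineConfig(tree_mse_drop_mode="absolute")
    tree = ori.fit_linear_tree(y, cfg)
    assert len(tree.segments) == 1


# ---------------------------------------------------------------------------
# orientation score
# ---------------------------------------------------------------------------

def _tree_from_slopes(slopes, seg_len):
    """LinearTree stub with given slopes on consecutive equal segments."""
    segs = [ori.Segment(i * seg_len, (i + 1) * seg_len, k, 0.0, 0.0)
            for i, k in enumerate(slopes)]
    return ori.LinearTree(segments=segs, split_points=[], mse_trace=[0.0])


def test_score_rising_section_arithmetic():
    # one rising section of length 4, sum of (u - s) = +0.02 -> +0.08
    tu = _tree_from_slopes([1.0], 4)
    ts = _tree_from_slopes([0.5], 4)
    u = np.array([0.05, 0.05, 0.05, 0.05])
    s = u - 0.005
    score = ori.orientation_score(tu, ts, u, s)
    assert score == pytest.approx(0.08, abs=1e-12)


def test_score_falling_section_arithmetic():
    # falling section, length 5, sum d = -0.03 -> (-1)(-0.03)(5) = +0.15
    tu = _tree_from_slopes([-1.0], 5)
    ts = _tree_from_slopes([-0.5], 5)
    u = np.full(5, 0.02)
    s = u + 0.006
    score = ori.orientation_score(tu, ts, u, s)
    assert score == pytest.approx(0.15, abs=1e-12)


def test_score_zero_when_series_identical():
    tu = _tree_from_slopes([1.0, -1.0], 5)
    ts = _tree_from_slopes([1.0, -1.0], 5)
    u = np.linspace(0, 1, 10)
    assert ori.orientation_score(tu, ts, u, u.copy()) == 0.0


def test_score_mixed_sign_sections_contribute_nothing():
    tu = _tree_from_slopes([1.0], 6)
    ts = _tree_from_slopes([-1.0], 6)
    u = np.full(6, 0.9)
    s = np.full(6, 0.1)
    assert ori.orientation_score(tu, ts, u, s) == 0.0


def test_score_zero_slope_counts_as_mixed():
    tu = _tree_from_slopes([0.0], 6)
    ts = _tree_from_slopes([1.0], 6)
    u = np.full(6, 0.9)
    s = np.full(6, 0.1)
    assert ori.orientation_score(tu, ts, u, s) == 0.0


def test_score_section_length_weighting():
    """Doubling a section's length doubles both l_tau and the d sum, so the
    contribution scales fourfold; per stated semantics the l_tau factor
    itself contributes linearly when d values are held fixed."""
    u1, s1 = np.full(4, 0.05), np.full(4, 0.04)
    u2, s2 = np.full(8, 0.05), np.full(8, 0.04)
    short = ori.orientation_score(_tree_from_slopes([1.0], 4),
                                  _tree_from_slopes([1.0], 4), u1, s1)
    long = ori.orientation_score(_tree_from_slopes([1.0], 8),
                                 _tree_from_slopes([1.0], 8), u2, s2)
    assert long == pytest.approx(4.0 * short, rel=1e-12)


def test_score_intersects_different_segmentations():
    # u-tree splits at 6, s-tree at 4: intervals [0,4),[4,6),[6,12)
    tu = _tree_from_slopes([1.0, -1.0], 6)
    ts = _tree_from_slopes([1.0, 1.0, -1.0], 4)
    u = np.full(12, 0.2)
    s = np.full(12, 0.1)
    # rising on [0,6) (merged), mixed on [6,8)? no: u falls on [6,12), s
    # falls on [8,12) -> falling overlap is [8,12)
    expected = (+1) * (0.1 * 6) * 6 + (-1) * (0.1 * 4) * 4
    assert ori.orientation_score(tu, ts, u, s) == pytest.approx(expected, abs=1e-12)


def test_simulated_induction_gene_scores_positive():
    gene = cv.GeneKinetics(alpha=((0.0, 6.0), (6.0, 0.0)), beta=2.0, gamma=1.0)
    spec = cv.LineageSpec((cv.ClusterSpec("c0", None, 300, 10.0),))
    adata, truth = cv.simulate(spec, [gene], noise="none", seed=0)
    order = np.argsort(truth.latent_time)
    cfg = PipelineConfig()
    U, oku = ori.smooth_and_normalize(truth.u_true[order], cfg.smoothing_kernel)
    S, oks = ori.smooth_and_normalize(truth.s_true[order], cfg.smoothing_kernel)
    tu = ori.fit_linear_tree(U[:, 0], cfg)
    ts = ori.fit_linear_tree(S[:, 0], cfg)
    assert ori.orientation_score(tu, ts, U[:, 0], S[:, 0]) > 0


# ---------------------------------------------------------------------------
# velocity-gene filter
# ---------------------------------------------------------------------------

def _filter_adata(u, s):
    adata = cv.make_dataset(s, u)
    adata.layers["Ms"] = np.asarray(s, float)
    adata.layers["Mu"] = np.asarray(u, float)
    return adata


def test_velocity_gene_proportional_kept():
    rng = np.random.default_rng(0)
    s = rng.uniform(0, 10, (100, 1))
    u = 0.5 * s
    assert cv.velocity_gene_filter(_filter_adata(u, s))[0]


def test_velocity_gene_uncorrelated_noise_dropped():
    rng = np.random.default_rng(1)
    s = rng.uniform(1, 10, (200, 1))
    u = np.abs(rng.normal(4, 0.7, (200, 1)))   # same scale, no correlation
    mask = cv.velocity_gene_filter(_filter_adata(u, s))
    assert not mask[0]


def test_velocity_gene_sigma_ratio_bound():
    rng = np.random.default_rng(2)
    s = rng.uniform(1, 2, (100, 1))
    u = 10.0 * (s - s.mean()) * 10 + 50.0      # sigma(u)/sigma(s) = 100
    mask = cv.velocity_gene_filter(_filter_adata(u, s))
    assert not mask[0]


def test_velocity_gene_zero_variance_dropped():
    s = np.full((50, 1), 3.0)
    u = np.full((50, 1), 1.5)
    assert not cv.velocity_gene_filter(_filter_adata(u, s))[0]


# ---------------------------------------------------------------------------
# origin correction
# ---------------------------------------------------------------------------

def _fake_path(nodes, branches=()):
    return cv.MainPath(nodes=list(nodes), branches=list(branches))


def _graph_with_origin(nodes, origin):
    C = len(nodes)
    w = np.zeros((C, C))
    for i in range(C - 1):
        w[i, i + 1] = w[i + 1, i] = 0.8
    g = cv.ClusterGraph(nodes=list(nodes), sizes=np.full(C, 10.0), weights=w)
    g.origin = origin
    return g


def test_positive_score_keeps_origin(linear_fixture):
    adata, _ = linear_fixture
    g = _graph_with_origin(["c0", "c1", "c2", "c3", "c4"], "c0")
    path = _fake_path(["c0", "c1", "c2", "c3", "c4"])
    report = cv.OrientationReport(gene_names=[], scores=np.array([1.0]),
                                  mean_score=1.138, decision="keep")
    out = cv.infer_new_origin(cv.preprocess(adata.copy()), g, path, report)
    assert out.origin == "c0"
    assert report.case == 1


def test_negative_score_flips_origin(linear_fixture):
    adata, _ = linear_fixture
    g = _graph_with_origin(["c0", "c1", "c2", "c3", "c4"], "c4")
    path = _fake_path(["c4", "c3", "c2", "c1", "c0"])
    report = cv.OrientationReport(gene_names=[], scores=np.array([-1.0]),
                                  mean_score=-0.650, decision="reverse")
    out = cv.infer_new_origin(cv.preprocess(adata.copy()), g, path, report)
    assert out.origin == "c0"
    assert report.case == 1


def test_branch_at_source_extends_origin_outward(linear_fixture):
    """Corrected source endpoint carries a branch whose flow runs into it:
    the origin moves to the branch's far endpoint."""
    adata, _ = linear_fixture
    # relabel: path covers c2..c4, branch c1-c0 attaches at the corrected
    # source c2; true development is c0 -> c4 so the branch flows into c2
    pre = cv.preprocess(adata.copy())
    g = _graph_with_origin(["c0", "c1", "c2", "c3", "c4"], "c2")
    branch = cv.Branch(attachment="c2", spine=["c1", "c0"],
                       members={"c0", "c1"})
    path = _fake_path(["c2", "c3", "c4"], branches=[branch])
    report = cv.orient_main_path(pre, g, path)
    assert report.mean_score > 0           # c2 -> c4 is the true direction
    out = cv.infer_new_origin(pre, g, path, report)
    assert report.case == 2
    assert report.branch_mean < 0          # branch flows c0 -> c2, into c2
    assert out.origin == "c0"


def test_branch_flowing_outward_keeps_attachment_origin(linear_fixture):
    """If the corrected branch direction leaves the shared endpoint, that
    endpoint itself is the origin."""
    adata, _ = linear_fixture
    pre = cv.preprocess(adata.copy())
    g = _graph_with_origin(["c0", "c1", "c2", "c3", "c4"], "c0")
    # pretend c3-c4 form a branch off the path c0..c2; it flows away from
    # its attachment c2... attach instead at source c0 to hit case 2:
    # development leaves c0, so branch c1..? -- use reversed fixture layout
    branch = cv.Branch(attachment="c0", spine=["c1"], members={"c1"})
    # path that excludes c1: c0 -> c2 is not adjacent in this graph, so we
    # build a custom graph where c0 connects to both c1 and c2
    C = 5
    w = np.zeros((C, C))
    for i, j in [(0, 1), (0, 2), (2, 3), (3, 4)]:
        w[i, j] = w[j, i] = 0.8
    g = cv.ClusterGraph(nodes=["c0", "c1", "c2", "c3", "c4"],
                        sizes=np.full(C, 10.0), weights=w)
    g.origin = "c0"
    path = _fake_path(["c0", "c2", "c3", "c4"], branches=[branch])
    report = cv.orient_main_path(pre, g, path)
    out = cv.infer_new_origin(pre, g, path, report)
    assert report.case == 2
    assert report.branch_mean > 0          # c0 -> c1 flows away from c0
    assert out.origin == "c0"


def test_no_velocity_genes_is_an_error():
    s = np.full((80, 3), 2.0)
    u = np.full((80, 3), 1.0)
    adata = cv.make_dataset(s, u, cluster=["a"] * 40 + ["b"] * 40)
    adata.layers["Ms"] = s.copy()
    adata.layers["Mu"] = u.copy()
    g = _graph_with_origin(["a", "b"], "a")
    path = _fake_path(["a", "b"])
    with pytest.raises(ValueError, match="velocity gene"):
        cv.orient_main_path(adata, g, path)


def test_reversal_antisymmetry(noiseless_linear):
    """Reversing pseudotime must flip the score sign for nearly all
    velocity genes on noiseless data."""
    adata, truth = noiseless_linear
    pre = cv.preprocess(adata.copy())
    cfg = PipelineConfig()
    mask = cv.velocity_gene_filter(pre, cfg)
    idx = np.arange(pre.n_obs)
    t = pre.obs["latent_time"].to_numpy()
    Uf, Sf, vf, _ = ori.extract_series_matrix(pre, idx, t, cfg)
    Ur, Sr, vr, _ = ori.extract_series_matrix(pre, idx, t.max() - t, cfg)
    f = ori.score_genes(Uf[:, mask], Sf[:, mask], vf[mask], cfg)
    r = ori.score_genes(Ur[:, mask], Sr[:, mask], vr[mask], cfg)
    ok = np.isfinite(f) & np.isfinite(r) & (np.abs(f) > 1e-12)
    assert (np.sign(f[ok]) != np.sign(r[ok])).mean() > 0.95
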