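# Methods

## Model and rationale

Splicing kinetics per gene follow u' = α(t) − βu, s' = βu − γs. The central
observation the package builds on is order-of-events, not rate values:
because u integrates α first and s integrates u, unspliced RNA rises before
spliced RNA during induction and falls before it during repression. This
holds for any non-negative α(t), including step changes (MURK genes), which
is why a direction decision based on u–s lead/lag is robust where
constant-rate ODE fits are not.

The pipeline therefore decides direction once, at the cluster level, and
only then estimates per-cell velocities constrained to that direction.
Stages and their contracts are documented in the module docstrings; this
note records parameter choices, numerical decisions, and what the synthetic
experiments do and do not establish.

## Parameters (defaults, units, why)

| parameter | default | meaning |
|---|---|---|
| `k_neighbors` | 30 | kNN size on PCA of log spliced counts; also the dNN candidate pool |
| `n_top_genes` | 2000 | highly variable genes kept (all kept, with a warning, when fewer exist) |
| `min_shared_counts` | 20 | minimum cells with joint u>0, s>0 per gene |
| `leiden_resolution` | 0.6 | community detection when no annotation is given |
| `smoothing_kernel` | 100 | uniform 1-d kernel along the pseudotime-ordered series (clamped to the series length) |
| `pruning_mass_fraction` / `pruning_min_clusters` | 0.5 / 5 | greedy size selection of graph nodes |
| `pruning_weight_factor` | 0.6 | rescue threshold relative to a dropped node's best weight |
| `score_threshold` | 0.1 | root/end score floor in the three-rule origin selection |
| `z1`, `z2` | 0.1, 1.0 | minimum weight and shortcut-suppression factor for level assignment |
| `lam`, `lam_prime` | 1.0, 0.1 | weight of the spliced data term; weight of the coherence term |
| `tree_min_interval` | 10 | smallest admissible linear-tree segment |
| `tree_mse_drop_threshold` | 100 (absolute mode) | published stopping rule; see below |
| `velocity_gene_gamma_min`, `velocity_gene_r2_min` | 0.01, 0.01 | u-on-s through-origin fit thresholds |
| `sigma_ratio_bounds` | (0.03, 3) | allowed σ(u)/σ(s) range for velocity genes |
| `kinetic_hidden`, `kinetic_epochs`, `kinetic_learning_rate` | (256, 64), 300, 0.001 | rate-network architecture and training protocol |
| `velocity_graph_sigma` | 1.0 | exponential kernel width of the transition matrix |

Velocity-gene regression uses all cells through the origin by default; an
extreme-quantile variant (steady-state convention) is available via
`velocity_gene_quantile`.

## Numerical decisions

**Linear-tree convergence.** The published absolute stopping rule
(`MSE drop < 100`) is defined on raw count scale; on series normalized to
sum to one, per-round MSE drops are of order 1e-4 and the absolute rule
stops before the first split. The default is therefore a relative rule
(drop/MSE < 1e-3); absolute mode is retained behind
`tree_mse_drop_mode="absolute"` for parity with raw-scale series. Split
scans use exact prefix-sum least squares, so each round is linear in the
series length. A round of splits is accepted only while the relative MSE
drop stays above threshold; every segment keeps at least
`tree_min_interval` points.

**Section extraction.** The u- and s-trees generally split at different
points; their segmentations are intersected and each interval classified by
the pair of local slopes. Strictly zero slopes classify an interval as
mixed (zero contribution). Adjacent intervals of the same class merge into
maximal sections before the length weighting — the l·Σd product is not
additive under fragmentation, so merging matters.

**Orientation score semantics.** The score is linear in d = ũ − s̃ and in
the section length; reversing the series flips its sign up to the
re-segmentation of the refitted trees (measured: >95% of velocity genes
flip on noiseless data).

**Terminal-state scoring.** Root/end scores come from damped power
iteration of the (reversed/forward) transition chain built from
steady-state residual velocities u − γ̂s on the smoothed layers. The
teleportation weight is 0.001: it is there only to guarantee convergence;
larger values visibly hold probability mass at graph bottlenecks (e.g.
branch points) instead of the true sources and sinks. Scores are computed
per connected component, min-max scaled per cell, and averaged within
clusters. Exact parity with external terminal-state routines is not
claimed; the three-rule origin selection is the tested contract.

**Main-path ties.** On graphs with shortcut cycles the subtree masses of
two candidates are often exactly equal (both reach the same remaining node
set). Ties break by the candidate's own cell count, then the connecting
edge weight, then node id. Rationale: a pure id tie-break can route the
path through a thin sibling shortcut at a branch point, producing a path
that runs half forward, half backward in real time — the direction score of
such a path is uninformative. The size/weight preference keeps the path on
the dominant lineage; the id rule remains the final deterministic fallback.

**Branch scoring (origin refinement).** When a branch hangs off the
corrected source endpoint i of the main path, its direction is scored like
the main path but over the branch's own clusters only, with the pseudotime
root at the spine cell most adjacent (by kNN) to the attachment cluster.
Rooting inside the attachment cluster folds that cluster's cells — which
extend along the main path — into the branch ordering and scrambles the
series. A negative branch score means the branch flows into i and moves
the origin to the branch's far endpoint; otherwise i itself is the origin.

**Eq.-5 sign.** The consistency term L_c (sum of same-cluster neighbor
velocity cosines) is a similarity to be encouraged, so the implemented
objective is Σ_g L_g − λ′L_c; `consistency_sign=+1` restores the literal
"+" formula. The descent is plain gradient descent from the simple-fit
solution (which zeroes the data term exactly); with λ′ = 0 the output
equals the simple fit bit-for-bit.

**Kinetic mode.** The rate network is a 2G→256→64→3G fully connected net
(ReLU hidden, softplus outputs for non-negativity) trained full-batch with
Adam for 300 epochs at learning rate 1e-3 on the dNN squared loss; inputs
are standardized per feature (the rate equations are applied to the raw
layers). Cells with identical expression receive identical rates by
construction.

**Diffusion pseudotime.** Self-contained diffusion-map implementation:
eigen-decomposition of D^{-1/2}AD^{-1/2} on the symmetrized kNN graph,
components scaled by λ/(1−λ), pseudotime = diffusion distance to the root
cell (the first stored cell of the origin cluster). Dense `eigh` is used
for graphs up to 600 nodes — ARPACK reliably fails to converge on small
path graphs with clustered eigenvalues — with a dense fallback for larger
graphs on non-convergence. A tiny index-proportional jitter enforces strict
ordering.

**Embedding projection.** The −1/N background term of the projection is
applied over all cells (unstored transition entries count as zero);
coincident embedding coordinates contribute nothing.

**Degenerate inputs.** All-zero genes are flagged and excluded from
scoring; zero-norm velocities give zero cosine rows and uniform transition
rows; empty directed neighborhoods give zero velocity (simple fit) or no
data term (fit); an empty velocity-gene set raises with advice to relax
thresholds; unreconnectable graph components are reported and processed
independently, each with its own origin and pseudotime root.

## The synthetic generator

The simulator solves the kinetics in closed form piecewise (the numerical
integrator lives only in tests as an oracle) along a forest of clusters
with per-cluster time intervals; transcription schedules may differ by
branch, and a cluster may carry an unobserved lead-in (`t0`) during which
dynamics keep running — used for island populations that are already mature
when first observed and for fast fate-commitment transitions. Defaults:
β = 2, γ = 1 per unit pseudotime so the u-lead is visible; fixture counts
are Poisson at scale 20 (counts of order tens — moderate shot noise);
gene programs have staggered onsets and switch-offs so no time point is
transcriptionally empty.

Fixtures: `linear` (5-cluster chain), `bifurcation` (trunk plus two
branches; the progenitor pool is the largest population and the two branch
programs ignite asynchronously — simultaneous ignition makes the two
branch-entry populations transcriptionally identical, which no clustering
or graph statistic can separate), `murk_mix` (35% MURK genes),
`islands` (a main chain plus a weakly connected mature island), and
`cycle` (noiseless cell-cycle-like positions chosen so that every gene's
spliced velocity keeps one sign between consecutive positions, making the
sign accuracy of the true velocities exactly 1 by construction).

What passing these tests shows: the direction logic, the estimators and the
metrics behave as specified under the kinetic model with Poisson noise.
What they do not show: robustness to doublets, ambient RNA, batch effects,
dropout beyond Poisson thinning, cluster misannotation, or topologies with
many interleaved lineages — real-data behavior on such inputs is untested
here.

## Problem sizes used by the shipped experiments

Direction recovery runs the three noisy fixtures at 2000 cells × 200 genes
across 20 seeds in the test suite (8 seeds per fixture in the acceptance
script); invariant and end-to-end checks run at 800 × 60; reversal
antisymmetry at 1000 × 100 noiseless; kinetic-rate recovery at 1000 × 40
with γ log-uniform on [0.2, 5] and early switch-off (repression-rich
sampling, where the degradation rate governs the observable decay and is
well identified).

## Known limitations

- The greedy main path is a heuristic; it reproduces the stated rule, not a
  global optimum, and on densely connected cluster graphs the direction
  decision degrades when the initially selected origin is an interior
  cluster (the three-rule selection makes this rare but not impossible).
- Orientation relies on enough velocity genes with genuine u–s lead; data
  with very shallow unspliced coverage will trip the velocity-gene filter.
- The kinetic mode recovers rate *ranks*, not absolute rates: dNN
  displacement targets fix velocity only up to a local time scale.
- Terminal-state scores are an operational stand-in for the external
  routine the selection rules were designed around; only rule behavior, not
  numeric parity, is guaranteed.
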