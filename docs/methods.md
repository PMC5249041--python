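# Methods

## Model and workflow

`mirdirect` treats the integrated miRNA+mRNA expression matrix as draws
from a multivariate distribution in which *direct* association between two
features means dependence that persists after conditioning on all other
features — in the Gaussian case, a nonzero entry of the precision
(inverse covariance) matrix. Marginal correlation additionally contains
every transitive path through other features, which is what the three
estimators suppress in different ways.

The pipeline is: load the two TSV matrices → integrate over the shared
samples (columns aligned by sample id, miRNA rows first) → z-score each
feature (mean 0, sd 1, n−1 denominator) → estimate a direct-association
score matrix per method, under bootstrap resampling → rank the bipartite
miRNA×mRNA block of each network and fuse by the inverse rank product →
extract top-N edges and per-miRNA top-k targets → score against a
validated pair list. Integration precedes standardization so the z-scores
are exact on the final sample set.

## Estimators

**Shrinkage partial correlation.** The empirical correlation matrix R is
shrunk off-diagonally toward zero, R\* = (1−λ)R with unit diagonal, and
λ chosen analytically as min(1, Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²) with
Var̂(r_ij) = n/(n−1)³ · Σ_k (z_ik z_jk − mean)², the unbiased variance of
the per-sample products of the standardized data. Partial correlations
follow from the inverse, p_ij = −Ω_ij/√(Ω_ii Ω_jj). Any λ > 0 makes R\*
positive definite, so the estimator is defined for n ≤ p; λ = 0 with a
singular R raises an error advising auto shrinkage. Diagonal fixed to 1;
entries clipped to [−1, 1].

**Sparse partial correlation.** The symmetric joint-regression objective
½ Σ_i w_i‖X_i − Σ_{j≠i} ρ_ij √(d_j/d_i) X_j‖² + λ Σ_{i<j}|ρ_ij| is
minimized by cyclic coordinate descent over pairs: each ρ_ij has the
closed-form soft-threshold update ρ_ij ← S(b, λ)/a with
a = w_i(d_j/d_i)G_jj + w_j(d_i/d_j)G_ii and b the combined partial-residual
inner products, maintained via the Gram matrix G = XXᵀ so each update is
O(p). Outer iterations (default 3) alternate the sweep with residual-
precision updates d_i = n/RSS_i; residual weights w_i default to uniform,
with an option to set w_i = d_i. The default penalty is
λ = √n · Φ⁻¹(1 − α/(2p²)), α = 0.1, the rate used for consistent
neighborhood selection in the sparse-regression literature. With λ = 0
and enough outer iterations the solution converges to the plain
partial-correlation matrix (tested to 1e-4); λ above
2·max_{i<j}|G_ij| yields the exactly zero matrix. Non-convergence within
the sweep budget warns and returns the last iterate, flagged in metadata.
If numba is importable the sweep kernel is JIT-compiled; otherwise the
identical code runs as pure Python.

**Mutual information + network deconvolution.** Each feature is
discretized into B equal-frequency bins by rank, and pairwise MI (nats)
is the plug-in estimate from the joint histogram. The auto bin count is
the nearest integer to n^(1/3) (minimum 2): the plug-in estimator's
upward bias is ≈(B−1)²/(2n), so a cube-root rule keeps the bias O(n^(-1/3))
and the MI of independent features near zero, whereas √n bins would leave
a bias of ~0.45 nats at n = 1000, swamping weak associations. The
deconvolution step maps each eigenvalue of the observed matrix through
λ → λ/(1+λ) in its eigenbasis, the closed-form inverse of the transitive
series G_obs = G_dir + G_dir² + … . Because the series inverse requires
all eigenvalues > −1, the input is linearly scaled to spectral radius
≤ 0.9 by default (factor recorded in metadata); rescaling can be disabled
when the input is known to be in the convergent range, in which case the
inversion is exact. The *input* diagonal is kept as given — it carries
the closed-cycle terms of the series, and zeroing it would shift the
spectrum and break exact inversion; for the MI pipeline it is already
zero. The *output* diagonal is forced to 0 (self-association is
meaningless downstream).

All estimators reject degenerate inputs: fewer than 3 samples, constant
feature rows, bin counts exceeding n.

## Bootstrap and ensemble aggregation

Each replicate draws ⌈rate·n⌉ sample columns uniformly with replacement
(defaults: 100 iterations, rate 0.95 — an m-out-of-n bootstrap read of
"95% with replacement"; an n-out-of-n variant is available via
`sampling_rate=1.0`, and replacement can be disabled). Replicate t's RNG
stream is seeded by (seed, t), so replicates are independently
reproducible and order-free. A replicate with a constant feature row is
redrawn (bounded retries); a replicate whose fit fails is skipped with a
warning.

Replicates — and, at the next level, the per-estimator aggregates — are
combined on ranks, not raw weights, because weight scales differ across
estimators (correlations vs nats) and across replicates. Ranks are taken
over the bipartite miRNA×mRNA block only (within-kind pairs would dilute
the ranking; the outputs and the evaluation are bipartite), by descending
|weight| with average-rank ties, so that exact zeros share the worst
rank. Ranking by |weight| keeps strongly *negative* (repressive)
associations on top; a `signed` option ranks most-negative first. The
consensus weight is r'_ij = 1/log Π_m (r_ij^m + 1) with the natural log
(the base only rescales weights, never reorders them); computed as
1/Σ log(r+1) to avoid overflow. Bootstrap aggregates are re-ranked before
the cross-method ensemble, since the fusion rule consumes ranks.

## Outputs and evaluation

Global top-N edges and per-miRNA top-k targets are extracted with ties
broken lexicographically by (miRNA id, mRNA id) and logged, making output
prefixes stable and runs byte-reproducible. Exports are TSV
(`mirna, mrna, weight, rank`) and Cytoscape SIF (`mirna associates mrna`).
Precision is the count of predicted pairs present in the ground-truth
list, per miRNA and in total; identifiers match exactly after
case-folding, with optional stripping of -3p/-5p arm suffixes (off by
default — silent fuzzy matching inflates scores). miRNAs absent from the
truth count zero and are flagged so either evaluation convention
(count-as-zero or exclude) can be derived from the report.

## Synthetic benchmark

The generator builds a precision matrix with unit diagonal and −v at each
chosen bipartite edge, v drawn from the configured magnitude interval
with random signs (or all negative under `repressive`, mimicking
repression). If the smallest eigenvalue falls below 0.05 the matrix is
diagonally loaded and renormalized, shrinking all realized partial
correlations by a common factor (logged); if that would more than halve
them, generation fails with advice to lower the weights. Samples are
drawn from N(0, Ω⁻¹) via Cholesky, plus optional white noise.

Because edges are bipartite, a non-adjacent miRNA–mRNA pair can never
share a neighbor; the shortest purely transitive route between sides has
length 3. `indirect_pairs` therefore returns non-edge bipartite pairs
connected through at most two intermediate features, found by powering
the adjacency matrix.

What the generator emulates: the large-p-small-n shape of matched
expression studies, sparse direct structure, transitive marginal
correlation, repressive sign structure, observation noise. What it does
not: microarray platform effects, probe-level noise models,
non-Gaussian marginals, differential-expression feature selection, and
the incompleteness/bias of real target databases. Passing benchmarks
therefore demonstrate correct recovery of GGM structure under the model's
own assumptions, not field performance on microarray cohorts.

## Default study sizes

The test suite and `scripts/acceptance.py` use 10 miRNAs × 40 mRNAs, 30
direct edges with |partial correlation| in [0.25, 0.4], 500 samples, and
5 dataset seeds; bootstrap aggregation uses 30 iterations in the tests
and the full 100 in the acceptance script, both at rate 0.95. These sizes
keep a full study to seconds while leaving dozens of transitive pairs per
dataset to separate from the 30 direct edges.

## Known limitations

- SPACE's coordinate descent solves a convex problem per (d, w), but the
  alternation with d-updates is a heuristic fixed-point; pathological
  penalties near the shrinkage threshold may need more outer iterations.
- Network deconvolution's rescaling changes the estimand (weights are
  shrunk nonlinearly); only the ordering should be interpreted.
- The plug-in MI estimator is biased upward at small n; the cube-root bin
  rule controls but does not remove this.
- Partial-correlation estimates assume approximately linear, Gaussian-like
  dependencies; MIND captures monotone nonlinear association but loses
  sign information.
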