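# Methods

## Model and estimand

Let `X_V^(1)`, `X_V^(2)` be the expression levels of the genes `V` of one
pathway in two conditions, modelled as Gaussian vectors Markov with respect
to a shared decomposable graph `G`. A set `D ⊆ V` is a *source set* if the
marginal law of `X_D` differs between conditions while the conditional law
of `X_{V∖D}` given `X_D` coincides; the minimal such `D` is the primary
dysregulation. Exhaustive search over subsets is infeasible, but on a
decomposable graph the two-sample problem decomposes over (clique,
separator) components, and the *graphical source set* — the smallest source
set expressible through cliques and separators — can be estimated as the
intersection over root cliques of the unions of significantly dysregulated
cliques. The graphical source set can strictly contain the minimal one:
perturbing a single node that is not itself a separator returns its whole
enclosing clique (the package's clique-perturbation tests exercise exactly
this behaviour).

## Graph preparation

Directed pathway graphs are moralized (parents of a common child are
joined, directions dropped) and triangulated by **greedy min-fill** with a
deterministic tie-break: fewest fill edges, then lexicographically smallest
sorted fill-edge set, then smallest node label. Any fill-in heuristic
yields a valid chordal cover; determinism is required because different
fill-ins change the clique structure and hence the estimate. Graph nodes
without expression data are removed *before* moralization (the likelihood
needs data for every clique member), with a logged warning. Disconnected
graphs are handled per connected component; a junction forest is built by
maximum-intersection Kruskal with index tie-breaks, and each of the `k`
perfect orderings is a BFS of that forest from one root clique.

## Test statistic and estimators

For a node set `A`, `λ(A) = Σ_l n_l log(|Σ̂_A|/|Σ̂_A^(l)|)` with
maximum-likelihood covariances (denominator `n_l`, per-condition centering)
and a pooled estimate centered at the grand mean with denominator
`n_1+n_2`. Grand-mean centering makes `λ` the classical likelihood ratio
for joint equality of means and covariances, so both kinds of dysregulation
register. The component statistic is `λ(C) − λ(S)`; log-determinants go
through Cholesky, and a non-positive-definite MLE is an error, never a
silent regularization.

The MLE exists when `min(n1, n2) > p*` (largest clique size). Below that,
the **ridge** estimator adds `ε` to every diagonal with
`ε = c · mean(diag(pooled covariance of the full gene set))`, `c` the
smallest of {1e-4, 1e-3, 1e-2, 1e-1} for which every component-sized
submatrix in both conditions has condition number ≤ 1e6 (largest grid value
as fallback). One `ε` per run, frozen across permutations, keeping the
permutation ensemble exchangeable. The `auto` estimator selects MLE exactly
when it exists. The asymptotic reference for a component is χ² with
`df = [p + p(p+1)/2] − [s + s(s+1)/2]` (Gaussian parameter counting); it is
accurate for components up to dimension 3 at n = 25 per group and for the
4-node clique from n ≈ 100 — below that the uncorrected likelihood ratio is
slightly inflated, which is why permutation p-values (valid at any n) are
the default inferential route and the asymptotic route is offered for MLE
only.

## Multiple-testing control

The `m = k + Σ v(C_i)` distinct components are controlled at FWER α by
single-step Westfall–Young procedures on one shared set of `B` label
permutations (duplicate components are tested once; verdicts are broadcast
to every ordering containing them). For **minP**, every column of the
p-value matrix — observed statistics included — is ranked against the other
`B` columns of the pooled (B+1)-column ensemble with add-one counting; under
the null all columns are exchangeable, making the min-p reference exact.
(Ranking permutations only within their own pool leaves their p-values one
grid step above the observed ones and measurably inflates the FWER.) The
cutoff is the largest achievable p-level whose add-one exceedance estimate
of the min-p distribution stays ≤ α; rejection uses non-strict `p ≤ cutoff`,
the conservative-but-nonempty choice on a discrete grid, and for a single
component the procedure reduces to an exact-level permutation test.
**maxT** (MLE only, since it needs the asymptotic reference) compares
components on `−log` asymptotic χ² p-values, with the analogous cutoff on
per-permutation maxima; with equal degrees of freedom it rejects exactly the
same set as minP applied to the asymptotic p-values. Recommended permutation
counts are `⌈m/α⌉` (minP) and `⌈1/α⌉` (maxT), capped at 10000; when a run
resolves `permutations="auto"` a floor of 100 is applied as well. Single-step
rather than step-down was chosen because the estimator consumes one global
cutoff; step-down is a possible extension.

An ordering with zero rejections forces an empty source set (an empty union
enters the intersection). This literal reading is kept deliberately: under
the global null at least two coordinated false rejections are needed for a
non-empty estimate, which is what makes the null behaviour of the estimator
conservative (measured non-empty rate ~0.02 at α = 0.05).

## Synthetic data

`random_ggm` draws a concentration matrix supported exactly on the graph
edges — off-diagonal magnitudes uniform on (0.15, 0.45) with random signs,
diagonal set above the absolute row sum (diagonal dominance ⇒ positive
definite) — optionally rescaled to unit variances, with means uniform on
(5, 10) (a log-expression-like scale) or zero. Real pathway parameters are
not shipped; the reference model is a seeded draw, and every experiment
states its seed.

Perturbations:

* **marginal** — `μ_D` and `Σ_DD` scaled by `1+δ` (variances up by δ,
  within-`D` correlations preserved), and the joint reassembled from the
  *original* regression matrix, intercept and conditional covariance of the
  complement, so `D` is a source set by construction. Intensities 0.2 / 0.6
  / 1.0 are labelled mild / moderate / strong. For multi-node `D` spanning
  several cliques the reassembly can introduce concentration fill within
  `D`, so the Markov check is waived there.
* **structural** — selected concentration entries set to zero (positive
  definiteness verified, error otherwise), optionally after strengthening
  those entries so the removal is a non-trivial perturbation (the
  strengthening factor backs off along 3, 2, 1.5, 1.2, 1 to preserve
  positive definiteness).
* **mean shift** — condition-2 mean `μ + Σ e_t μ_t`, covariance unchanged;
  the displacement is the covariance operator applied to a sparse target,
  so conditionals given the target are identical across conditions and the
  minimal source set is {target}. Intensities 1 / 5 / 10 / 50 = weak /
  mild / moderate / strong.

**Skewed margins.** The sensitivity sampler matches the mean, the full
covariance matrix and the requested marginal skewness exactly, using an
additive half-normal construction with an independent skewing source per
node (`X_i = μ_i − b·d_i + d_i|U_i| + Z_i`, `d_i` by third-moment
matching). The exact multivariate skew-normal family was rejected: with the
covariance matched, its PSD constraint `Σ − (1−2/π)dd' ⪰ 0` subtracts a
rank-one multiple of the joint skew direction and caps the achievable
marginal skewness near 0.1 when several weakly correlated nodes are skewed.
The cost is that margins are skew-normal-*type* (half-normal-plus-Gaussian
convolutions) rather than exactly skew-normal, and the conditional
independence structure holds only approximately under skewing. Default:
skewness 0.3 on 4 of the 10 nodes.

**The benchmark graph** has 10 nodes and maximal cliques {1,2,3}, {3,4,5},
{5,6}, {6,7}, {5,8,9,10} (`k = 5`, `p* = 4`, `m = 12` distinct components);
node 5 is a singleton separator cutting {1,2,3,4} off from the rest. It
reproduces the structural constraints of the published simulation graph
except the exact component count (13 there), whose edge list is available
only graphically.

What the generator does *not* emulate: count noise (negative-binomial
RNA-seq), batch effects, missingness, model misspecification of the graph
itself. Passing tests therefore demonstrate correctness of the estimator
under its own model (plus moderate skewness), not robustness to arbitrary
real-data violations.

## Problem sizes and numerical choices

The validation experiments use 100–500 Monte-Carlo replicates per cell at
n ∈ {5, 10, 25} per condition with the recommended permutation counts
(B = 240 for m = 12 at α = 0.05): large enough that binomial Monte-Carlo
error (≤ 2.2% at 500 runs, ≤ 5% at 100) is small against the effects being
measured, and small enough that the whole suite runs in minutes on one CPU.
Permutation statistics are computed vectorized across permutations per node
set; the pooled grand-mean covariance is permutation-invariant and computed
once. All randomness flows through explicit integer seeds; identical
configuration and seed give bit-identical results, including the exported
JSON (floats serialized at 10 significant digits, no timestamps). Condition
labels are ordered lexicographically (smaller label = condition 1); λ is
label-symmetric, so this matters only for reporting.

## Known limitations

* The estimate is the *graphical* source set; no second-stage drill-down
  inside it is attempted.
* Ridge p-values are valid but conservative; the ridge tuning rule is a
  deterministic stand-in isolated behind one function
  (`llr_testing.choose_ridge_eps`) for easy recalibration.
* The `score` index combines per-hypothesis permutation p-values by
  Fisher's method over the distinct components containing a gene; p-values
  of overlapping components are dependent, so `score` is a ranking device,
  not a calibrated p-value (also isolated for recalibration).
* Asymptotic (maxT) inference should not be trusted for cliques whose size
  approaches `min(n1, n2)`; use minP.
* FWER is the only error rate controlled; no FDR variants.
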