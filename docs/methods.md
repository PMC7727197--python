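# Methods

This note records the statistical and numerical choices behind `censelect`.
Notation: n observations, p variables, 10 true variables with common
coefficient β, outcomes either continuous (unit-variance Gaussian errors) or
binary (logistic, baseline prevalence 0.5).

## 1. Synthetic covariates (`simdata`)

**Copula construction.** Covariates are drawn from a Gaussian copula: a latent
multivariate normal with block-constant correlation, pushed through monotone
marginal transforms. Because the target dependence is specified on the
Spearman scale, the latent Pearson correlation is set to
`2·sin(π·ρ_S/6)`, which is exact for the Gaussian copula; monotone marginal
transforms then leave Spearman correlations untouched. The default design
places collinear blocks of five variables at |ρ_S| = 0.97 on the first
indices; among the remaining variables 30% are lognormal and 20%
zero-inflated (40% zeros), echoing skewed and zero-heavy census tabulations.

**PSD repair.** Block-plus-background correlation matrices can drift slightly
indefinite after the Spearman→Pearson map; eigenvalues are floored at zero and
the matrix rescaled to unit diagonal.

**Missingness and preprocessing.** Entries are masked completely at random
(default 2%), then median-imputed and standardized (mean 0, SD 1 with
ddof = 1), mirroring the common practical pipeline. `impute_and_standardize`
is idempotent and errors on constant columns.

**Truth selection.** Five true variables are sampled from the
high-collinearity pool (maximum absolute correlation with any other variable
above 0.95 in the realized matrix) and five from the low pool (below 0.6), so
every benchmark pits each method against both regimes at once.

**Effect-size calibration.** β is the smallest two-decimal value whose
two-sided univariable Wald test reaches the requested power (default 0.80) at
α = 5×10⁻⁵, using SE = 1/√n (continuous) or 1/√(n·π(1−π)) at π = 0.5
(binary). At n = 2000 this yields 0.11 and 0.22. Rounding is upward, so the
power target is met, and a grid walk guards against boundary artifacts. At
reduced scales the same rule re-calibrates automatically (e.g. 0.20 continuous
at n = 600), keeping difficulty comparable across scales.

**Splits.** Each replicate splits rows 2/3 discovery (⌊2n/3 + 0.5⌋) and 1/3
validation, uniformly at random.

## 2. Clustering (`cluster`)

Distance is `1 − |ρ_Spearman|`; linkage is complete, via
`scipy.cluster.hierarchy.linkage`. Cutting the dendrogram at height h keeps
only merges strictly below h, which guarantees the interpretable bound: every
pair inside a cluster has |ρ_S| > 1 − h (the default cut 0.2 means pairwise
|ρ_S| > 0.8). The bound is asserted on every clustering output.

The bootstrap variant scores each dendrogram node (below the cut) by the
fraction of B resampled-row dendrograms in which its exact member set
reappears, then keeps the maximal non-overlapping nodes with stability ≥ 0.95.
This is an intentionally simple stability filter — it asks for exact member-set
recurrence rather than approximate cluster similarity — chosen because it is
transparent and deterministic.

## 3. Penalized selection (`sparse_select`, `sgl`)

**Lasso / elastic net.** The objective is the scikit-learn parameterization
(1/2n squared error, or mean logistic deviance, plus
λ·[(1−α)/2·‖β‖₂² + α·‖β‖₁]). λ runs over a 100-point geometric grid from the
data-derived λ_max down to 10⁻³·λ_max; the elastic-net mixing α runs over
0.05–0.95 in steps of 0.05, with the K-fold assignment shared across the
whole (α, λ) grid so the comparison is paired. Continuous fits use
`enet_path` coordinate descent per fold; binary fits use saga with warm
starts along the path. Two λ rules are exposed: the CV minimum and the
one-standard-error rule (largest λ with mean CV error ≤ min + SE — the first
index on the decreasing grid inside the band).

**Sparse group lasso.** The native solver minimizes

    loss(β₀, β) + λ·[(1 − mix)·Σ_g √p_g·‖β_g‖₂ + mix·‖β‖₁]

with loss the 1/n-scaled squared error or logistic negative log-likelihood and
an unpenalized intercept. For singleton groups the penalty collapses to
λ|β_j| for any mix, so all-singleton problems reproduce the plain lasso — a
property the tests verify against scikit-learn to < 10⁻⁵.

The solver is blockwise proximal coordinate descent: singleton groups take
exact coordinate updates (continuous) or proximal gradient steps (binary);
multi-member groups take proximal gradient steps — elementwise soft-threshold
by t·λ·mix, then group soft-scaling by t·λ·(1−mix)·√p_g — with step size
t = 1/L_g from the exact per-group Lipschitz constant (‖X_g‖₂²/n, divided by
4 for logistic loss), which makes the objective monotonically non-increasing.
λ_max is found per group by bisection on the KKT zero-group condition
‖S(∇_g, λ·mix)‖₂ ≤ λ·(1−mix)·√p_g. Hot loops are numba-compiled; paths are
warm-started. CV chooses λ at the minimum error (no 1SE rule for SGL).

The clustered pipeline (`HierarchicalSGL`) clusters the discovery matrix
(threshold or bootstrap), then runs SGL with mix = 0.95 on those groups, so a
selected group can still be sparse inside.

## 4. Tree ensembles (`tree_select`, `bart`)

**RF / bagging VIMP.** Ensembles are bootstrap aggregations of scikit-learn
decision trees; random forests consider p/3 (regression) or √p
(classification) candidate features per split, bagging considers all p.
Importance is out-of-bag permutation degradation (MSE or misclassification).
Standard errors use the delete-d jackknife: the ensemble is refit on
subsamples of size m = ⌈n^0.75⌉ drawn without replacement, and
SE² = (m/(n−m)) · var over subsamples. Selection requires the
100·(1 − α/p)% normal CI to lie strictly above zero — at α = 0.05, p = 1000
that is a 99.995% interval (z ≈ 4.056), a deliberately severe familywise
criterion.

**BART.** A compact Bayesian additive regression trees sampler: a sum of 20
trees, grow/prune Metropolis–Hastings with the integrated leaf marginal
likelihood, depth prior 0.95·(1+d)⁻², leaf-scale prior σ_μ = 0.5/(k√m)
(continuous, outcomes rescaled to [−0.5, 0.5]) or 3/(k√m) (probit binary),
inverse-χ² prior on σ² (ν = 3, q = 0.9), probit data augmentation by
inverse-CDF truncated normal draws. A variable's inclusion proportion is its
share of all split rules, averaged over kept posterior draws.

Selection thresholds come from a permutation null: P refits on
outcome-permuted data give a (P × p) null matrix, and three criteria of
increasing severity are applied to the observed proportions — the local
per-variable 1−α quantile, the global SE multiplier m_j + C*·s_j (C* the
smallest multiplier covering 1−α of permutation rows simultaneously), and the
global 1−α quantile of row-wise maxima. Quantiles use the `higher` method, so
with P = 50 permutations the local criterion's null exceedance rate is
3/51 ≈ 5.9%, not exactly 5%.

## 5. Evaluation (`evalbench`)

Each replicate: simulate the outcome on the fixed covariate matrix, split,
select on discovery, validate selections on the held-out third (univariable
Wald p < 0.05 by default; a lasso mode exists for heavily correlated
selections), then score:

* **strict** — TP are exactly selected-and-validated truths; every other
  validated variable is an FP.
* **relaxed** — a truth counts as identified if it or any surrogate
  (|Pearson| > 0.8 with it, boundary excluded) is validated; surrogates leave
  the FP pool; the TP ceiling stays at 10.

F2 = 5·TP/(5·TP + 4·FN + FP) up-weights sensitivity, matching a screening use
case where misses are worse than extra follow-ups.

Under the global null the expected validated-FP count per replicate for the
univariable screen is p·(0.05/p)·0.05 = 0.0025 — independent of p — which the
acceptance suite checks by simulation.

**Determinism.** Replicate streams are spawned from a single
`numpy.random.SeedSequence`, covariates and truth are fixed across replicates,
and CSVs are written with a fixed float format, so a fixed master seed
reproduces results byte-for-byte.

## 6. Reduced problem sizes

The full-scale configuration (p = 1000, n = 2000, 500 replicates, all 12
methods) is hours of compute. The shipped acceptance suite instead runs the
property checks at p = 200, n = 600 with 50 replicates, where the qualitative
behavior (elastic-net sensitivity ≥ lasso-1SE, lasso-1SE specificity ≥
elastic-net, clustered SGL's relaxed-F2 advantage, confounded truths invisible
to univariable screening) is already stable. BART null-calibration checks are
further reduced (p = 50, n = 300, 50 permutations, short chains) because each
threshold evaluation costs P + 1 full sampler runs. These sizes are a time
budget decision, not a statistical one; all methods accept full-scale inputs.

## 7. Limitations

* The BART sampler is minimal (no sparse Dirichlet splitting prior, single
  chain, fixed 100-cutpoint grids); it targets inclusion-proportion ranking,
  not posterior predictive quality.
* The univariable logistic screen falls back to a score test under complete
  separation (with a warning) rather than implementing Firth correction.
* Bootstrap cluster stability requires exact member-set recurrence, which is
  conservative for large, loosely bound clusters.
* Binary penalized paths rely on saga convergence at small λ; extremely
  separable data may need more iterations.
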