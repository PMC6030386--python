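# Methods

## Model

For sample i with OTU relative abundances **z**_i (counts divided by
library size), covariates **x**_i and outcome y_i, the package fits

* continuous: y_i = β₀ + **x**_iᵀβ₁ + f(**z**_i; γ)ᵀ**b** + ε_i,
  ε_i ~ N(0, σ_ε²)
* binary: logit E(y_i) = β₀ + **x**_iᵀβ₁ + f(**z**_i; γ)ᵀ**b**

with random OTU effects **b** ~ N(0, σ_b² C(ρ)). The correlation
C_ij(ρ) = exp(−2ρ d_ij²) derives from a trait-evolution view of the
phylogeny: d_ij is the patristic distance, and ρ acts as an evolutionary
rate. ρ = 0 gives the all-ones matrix (all effects identical); ρ → ∞
gives the identity (tree uninformative). The squared-distance exponent is
the default because it separates clades more sharply; the plain distance
is available via `squared_distance=False`. Marginally the model is a
kernel machine: the aggregate OTU effect has covariance
σ_b² K(γ, ρ) with K = f(Z; γ) C(ρ) f(Z; γ)ᵀ.

Assumptions worth keeping in mind: effects are additive in transformed
abundances; the correlation of effects decays isotropically with
patristic distance (no lineage-specific rates); samples are independent
(no longitudinal or family structure).

## Estimation

**Continuous (REML).** With Σ = σ_b² K + σ_ε² I the restricted
likelihood is profiled down to δ = σ_ε²/σ_b². One symmetric
eigendecomposition of the projected kernel S(K+I)S (S the annihilator of
the fixed-effect design) reduces every likelihood evaluation to O(n).
δ is located on a 61-point log₁₀ grid over [10⁻⁶, 10⁶] and refined by
bounded scalar minimization in the winning bracket; the boundary
σ_b² = 0 (ordinary least squares) is always evaluated and preferred when
it is at least as likely, so variance estimates can sit exactly on the
boundary. β̂ is generalized least squares at the optimum. The spectral
path is verified in the tests against a dense evaluation of the
restricted likelihood to 10⁻⁶.

**Binary (PQL).** Penalized quasi-likelihood iterates weighted working
LMMs: μ = logistic(η), w = μ(1−μ) floored at 10⁻⁶ (quasi-separation
protection), working response η + (y−μ)/w, working covariance
σ_b² K + σ_ε² W⁻¹. Iteration stops when max|Δη| < 10⁻⁶ or after 50
passes; non-convergence is flagged on the result, not raised. The
working-model dispersion σ_ε² is estimated by REML rather than pinned at
the quasi-likelihood scale of 1; `fix_dispersion=1.0` restores the
classical behaviour. With a zero kernel the whole procedure collapses to
IRLS logistic regression (checked against statsmodels).

**Prediction.** New samples get the conditional Gaussian mean
X_te β̂ + σ̂_b² K_te,tr Σ̂_tr⁻¹ (y_tr − X_tr β̂) (for PQL, applied to the
converged working model and mapped through the inverse logit). Solves
use a Cholesky factorization with one retry after adding a
10⁻⁸·tr(Σ)/n diagonal jitter — Σ can be near-singular when ρ = 0 makes
C rank one. The equivalent BLUP form (per-OTU effect estimates pushed
through the test abundances) is exercised in the tests to 10⁻⁸.

## Tuning

(γ, ρ) are treated as tuning parameters, not estimated. Defaults: ρ on
{0} ∪ {2⁻⁵, …, 2⁵} with 10⁴ appended as the tree-agnostic fallback, γ on
{0, 0.01, 0.1, 0.3, 0.5, …, 1.9}. Five-fold CV (stratified for binary
outcomes) scores each cell by held-out PMSE (minimized) or AUC
(maximized); ties break to the first optimum in row-major order
(γ ascending, then ρ ascending), the winning cell is refit on all
training data. Because the kernel contains no fitted quantities, the
full-sample kernel is computed once per cell and sliced into
train/held-out blocks — numerically identical to per-fold recomputation,
with no possibility of leakage. Fixing the ρ grid to {10⁴} yields the
linear-kernel baseline used in the comparisons. Prediction quality is
summarized by R², the squared sample correlation between observed and
predicted values (predicted probabilities for binary outcomes); zero
variance in either vector defines R² = 0 with a warning.

## Positive definiteness

With the squared-distance exponent C(ρ) is not guaranteed PSD. The
constructor checks the spectrum and, only when the smallest eigenvalue
falls below −10⁻¹⁰·λ_max, clips eigenvalues below 10⁻¹⁰·λ_max to that
floor, reconstructs, and re-normalizes the diagonal to 1 (flagged via
`pd_corrected`). Rank-deficient but PSD cases — notably the all-ones
matrix at ρ = 0 — are deliberately left untouched so the exact limiting
values survive; downstream solves carry their own jitter fallback.

## Synthetic-data generator

The generator emulates a 16S study end to end and defines the conditions
under which the package is benchmarked:

* **Tree**: pure-birth (Yule) tree, unit birth rate, deterministic per
  seed. Being ultrametric it can carry zero-length terminal cherries —
  two effectively identical OTUs — which real trees also have at 97%
  clustering.
* **Counts**: Dirichlet-multinomial with concentration
  π·(1−ϕ)/ϕ; library sizes ~ NegBin(mean 5000, size 25), the "size"
  reading of the dispersion (variance μ + μ²/25). Default mean
  proportions are ranked log-normal (σ = 2) with ϕ = 0.02 — heavy-tailed,
  a few dominant taxa and a long rare tail, self-contained rather than
  estimated from any external dataset. `estimate_dm` provides
  method-of-moments estimation from a user table when a real template is
  available.
* **Signal**: the tree is cut into m clusters by PAM (hand-implemented
  BUILD+SWAP on the patristic distance matrix, deterministic);
  m_c = ⌊m·s%⌋ outcome-associated clusters are chosen at a
  low/median/high cumulative-abundance level out of 1000 random draws.
  Every OTU in a cluster shares one coefficient b_l ~ N(0, σ_b²)
  (σ_b² = 2 continuous, 4 binary), so signals are clustered by
  construction; m = p makes them phylogenetically unrelated.
* **Outcome**: η_i = β₀ + Σ_l b_l Σ_{k∈C_l} f(z_ik) with f identity,
  square root, or presence indicator. Continuous outcomes add Gaussian
  noise with σ_ε² = var(signal)·(1−v)/v so the OTU signal explains
  exactly v of the outcome variance (default v = 0.8; 0.5 and 0.33 cover
  lower signal-to-noise settings). The variance is computed on the
  generated sample (population convention, ddof = 0). Binary outcomes are
  Bernoulli(logistic(η)); balanced case-control counts, when needed, are
  obtained by oversampling and truncation at the caller.
* **Noisy trees**: `permute_tree` symmetrically permutes the rows and
  columns of the distance matrix for a chosen percentage of tips,
  degrading the tree toward non-informativeness at 100%.

What the generator does **not** emulate: taxon-taxon ecological
correlations beyond the Dirichlet's negative covariance, batch or
sequencing-depth artefacts, non-ultrametric branch-length noise, and
covariate-microbiome confounding. Benchmarks on these data therefore
establish internal correctness and the direction of the tuning behaviour
(tree helps when signal is clustered; small γ captures presence/absence
signal), not field performance on any particular real cohort.

## Benchmark scales

The directional benchmarks in `tests/test_acceptance.py` use
n_train = 100, n_test = 200, p = 200, 10 replicates per condition — the
package's chosen problem size for routine verification; larger
replicate counts sharpen the same comparisons. The variance-ratio
recovery check uses n = 300 with 50 replicates.

## Preprocessing pipeline

Fixed stage order: (1) sample outlier filter — Bray-Curtis distances on
proportions (library-size effects removed before distance computation),
outlier index o_j = m_j / median(m) with m_j the median distance of
sample j to the rest, drop o_j > 2; identical samples give an undefined
index, treated as 1 (kept). (2) OTU filters — prevalence ≥ 10% of
samples and median nonzero count ≥ 10. (3) GMPR size factors — geometric
mean over samples of pairwise median count ratios over co-detected taxa,
self-ratio included so that a pure per-sample scaling is recovered
exactly; factors rescaled to geometric mean 1. (4) per-taxon 97%-quantile
winsorization using the lower order-statistic convention, which makes the
cap an observed value and the operation exactly idempotent. (5) optional
square-root transform. Each stage logs input/output dimensions. Outcome
transformations (e.g. square-root of age) are left to the user.

## Known limitations

* PQL is a first-order approximation; with few samples or extreme class
  imbalance the variance components are biased toward zero (no Laplace
  or quadrature alternative is provided).
* A single kernel variance component: no multi-kernel composition, no
  sample-level random effects for repeated measures.
* Patristic distances are used as-is by default; trees with wildly
  different branch-length scales shift the meaningful ρ range
  (`rescale_distances=True` divides by the median off-diagonal distance
  to make the grid transferable).
* PAM BUILD+SWAP is exact but O(m·p²) per sweep; for p in the thousands
  with many clusters, expect clustering to dominate generator runtime.
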