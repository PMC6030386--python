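# phyloglmm

Phylogeny-regularized kernel mixed models for predicting host outcomes
from microbiome composition.

## The problem

16S rRNA studies summarize a microbial community as a table of OTU
(operational taxonomic unit) counts together with a phylogenetic tree
relating the OTUs. Outcome-associated taxa are often *clustered* on that
tree — related species share function — and often *dense*: many species
shift together when the community changes state. Sparse regression
methods (lasso-type) underperform in exactly those regimes. This package
predicts a continuous or binary outcome y from relative abundances
**z** = (z₁,…,z_p) by treating the per-OTU effects as random with a
tree-induced correlation, so that phylogenetic neighbors are encouraged
to act alike and the effective dimension collapses to two variance
components.

## The model

Per-OTU effects **b** are random with

&nbsp;&nbsp;&nbsp;&nbsp;**b** ~ N(0, σ_b² C(ρ)),&nbsp;&nbsp;
C_ij(ρ) = exp(−2ρ d_ij²)

where d_ij is the patristic distance between tips i and j (the plain
exponent exp(−2ρ d_ij) is available by flag). ρ ≥ 0 sets the
phylogenetic depth of signal grouping: ρ = 0 makes all effects identical,
ρ → ∞ removes the tree entirely. Abundances enter through the power
transform f(z; γ) = z^γ (zeros stay zero); small γ up-weights rare taxa
and γ = 0 reduces the data to presence/absence.

* Continuous outcome (LMM): y_i = β₀ + **x**_iᵀβ₁ + f(**z**_i; γ)ᵀ**b** + ε_i,
  fitted by REML after one spectral decomposition of the sample kernel
  K(γ, ρ) = f(Z; γ) C(ρ) f(Z; γ)ᵀ.
* Binary outcome (GLMM): logit E(y_i) = β₀ + **x**_iᵀβ₁ + f(**z**_i; γ)ᵀ**b**,
  fitted by penalized quasi-likelihood (iterated weighted working LMMs).

Prediction for new samples is the conditional Gaussian mean

&nbsp;&nbsp;&nbsp;&nbsp;ŷ_te = X_te β̂ + Σ̂_te,tr Σ̂_tr⁻¹ (y_tr − X_tr β̂),

equivalently the BLUP of **b** pushed through the test abundances.
(γ, ρ) are tuned by k-fold cross-validation (PMSE for continuous
outcomes, AUC for binary); fixing ρ = 10⁴ recovers a tree-agnostic
linear-kernel baseline.

The package also ships the full synthetic-data generator used in its
tests (Dirichlet-multinomial counts, PAM clustering of the tree into
outcome-associated OTU clusters, continuous/binary outcomes at a fixed
signal-to-noise ratio) and the standard preprocessing pipeline for raw
count tables (Bray-Curtis outlier filter, prevalence and median-count
OTU filters, GMPR size-factor normalization, 97%-quantile winsorization,
square-root transform).

## Worked example

```python
import phyloglmm as pg
from phyloglmm.estimators import PhyloKernelRegressorCV

design = pg.SimulationDesign(
    m=10, signal_density_pct=10, abundance_level="high",
    outcome_type="continuous", seed=7,
)
data = pg.simulate_dataset(design, n=150, p=100)
Z, y = data.proportions, data.outcome

cv = PhyloKernelRegressorCV(distances=data.dist, random_state=0)
cv.fit(Z[:100], y[:100])
print(f"selected gamma = {cv.best_gamma_}, rho = {cv.best_rho_}")
fit = cv.best_estimator_
print(f"sigma_b2 = {fit.sigma_b2_:.3f}, sigma_e2 = {fit.sigma_e2_:.3f}")
r2 = pg.r_squared(y[100:], cv.predict(Z[100:]))
print(f"test R^2 = {r2:.3f}")
```

prints

```
selected gamma = 1.1, rho = 0.03125
sigma_b2 = 0.524, sigma_e2 = 0.004
test R^2 = 0.786
```

The CV selected a small ρ — the outcome was generated from one deep
clade-level cluster, so deep phylogenetic grouping pays off — and the
tuned model explains ~79% of the held-out outcome variance (the
generator caps the explainable share at 80%). The same data through the
tree-agnostic baseline (`rho_grid=[1e4]`) gives test R² = 0.777 here; the
gap widens with stronger clustering and more replicates.

The estimators follow scikit-learn conventions (`get_params`/`set_params`,
`fit`/`predict`/`predict_proba`, trailing-underscore fitted attributes)
and accept pandas DataFrames whose columns are matched to the tree tips
by label. Everything is also scriptable from the shell:

```sh
phyloglmm simulate --p 100 --n 60 --seed 3 --outdir data/
phyloglmm tune --counts data/counts.tsv --tree data/tree.nwk \
    --outcome data/outcome.tsv --outdir tuned/
phyloglmm predict --model tuned/model.json --counts data/counts.tsv \
    --out predictions.tsv
```

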