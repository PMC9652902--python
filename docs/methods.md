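# Methods

## Model

All fits assume the kinship linear mixed model

```
Y = X β + Z u + ε,   u ~ N(0, σ² τ K),   ε ~ N(0, σ² I),
```

so marginally `Y ~ N(X β, σ² (I + τ Z K Z'))`. `K` is treated as known
and positive semi-definite (validated at load time with a tolerance of
−1e−8 times the largest eigenvalue); `Z` is a 0/1 incidence matrix with
one strain per observation, the identity for panels of unreplicated
individuals. One eigendecomposition `Z K Z' = U Λ U'` (eigenvalues
clipped at zero) is shared by every fit: in the rotated coordinates
`U'Y`, the covariance is diagonal with weights `1 + τ λ_i`, so for any
`τ` the estimates of `β` and `σ²` are closed-form weighted least squares
and the exact Gaussian log-likelihood is cheap.

**Estimation of τ.** The profile log-likelihood is evaluated on a
100-point log-spaced grid over `[1e−6, 1e6]` and refined by bounded
scalar minimization between the best grid point's neighbors. Ties within
optimizer tolerance (1e−9 relative) break toward smaller `τ`: with
`K = I` the profile is exactly flat in `τ` (the weights are constant), and
the parsimonious end of the grid is reported. ML is used throughout, not
REML, so that BIC differences approximate Bayes factors coherently; a
REML profile is available as an off-by-default option for
variance-component diagnostics. The BIC parameter count `d` includes all
design columns plus `σ²` and `τ`; because only BIC differences enter
Bayes factors, constant conventions cancel and `d` is not configurable.

## Bayesian scoring

Bayes factors against the base model use the BIC approximation
`BF ≈ exp{−½ (BIC_i − BIC_b)}` (unit-information prior; no explicit
parameter priors needed). All arithmetic is in log space with `|log BF|`
clamped at 700. The model space carries an independent-Bernoulli prior
`P(M) = π₀^{s−p} (1−π₀)^p` over the `s` eligible SNPs.

`π₀` is estimated from the screening-step Wald p-values by Storey's
smoother: `π̂₀(λ) = #{p > λ}/(L(1−λ))` on `λ = 0.05, 0.10, …, 0.95`,
smoothed by a natural cubic spline and evaluated at `λ = 0.95`. When the
estimate is conservative (≥ 1, common under a global null), the fallback
`π₀ = 1 − 100/L` is used — a prior expectation of 100 causal SNPs
genome-wide. That formula presumes genome-scale `L`; for panels of ≤ 100
SNPs it is clamped into `[0.5, 1)`. `π₀` is re-estimated at every
screening step, but all model-selection steps reuse the first iteration's
estimate so SNPs found early and late compete under the same prior.

## Screening

The base-model GLS residuals `Ŷ = Y − X β̂` have covariance
`σ² Σ(τ̂)` with `Σ = A − X (X'A⁻¹X)⁻¹ X'` and `A = I + τ̂ Z K Z'`. This
matrix is singular by construction — its null space is spanned by
`A⁻¹ X`, so `Σ A⁻¹ X = 0` and `rank(Σ) = n − rank(X)`; at `τ̂ = 0` with
an intercept-only design it reduces to the centering matrix
`I − 11'/n`. The per-SNP regressions `Ŷ = X_l β_l + ε*`,
`ε* ~ N(0, σ² Σ)`, are fit on the retained eigenbasis of `Σ`
(eigenvalues above 1e−10 of the largest), scaled to unit variance; this
equals brute-force GLS with the pseudo-inverted dense `Σ` (tested to
1e−6). No intercept is re-included: the residuals are already adjusted
for `X`. The BIC comparison of the one-SNP model against the empty model
uses the retained rank as the sample size, keeping the density proper on
the column space.

Candidates are selected by Bayesian FDR control: rank SNPs by decreasing
posterior probability (ties by ascending index, making output
deterministic), form the running mean of `1 − p_(l)`, and flag the
largest prefix with estimated FDR strictly below `q₀` (default 0.05).
SNPs already in the base model are skipped (`p_l = NaN`) and cannot
re-enter as candidates within the same iteration; SNPs whose projection
onto the residual space is numerically zero (e.g. perfect copies of base
SNPs) get `p_l = 0` with a logged warning.

## Model selection

The search space is every subset of base ∪ candidate SNPs — base SNPs
are droppable. Perfectly correlated SNPs within the union are first
collapsed to the lowest index of each group; the dropped indices are
reported as aliases of the kept one in all outputs. `τ` is estimated
once from the full model containing the whole union (P3D) and held fixed
for every candidate model, so each model's score is a solve against a
submatrix of one precomputed Gram matrix; if the full model would exceed
`n − 2` columns or is otherwise unfittable, the base model's `τ̂` is used
instead (logged).

Spaces of up to 15 SNPs are enumerated completely (≤ 32,768 models).
Larger spaces use a genetic algorithm on binary inclusion chromosomes:
population 100, initialized with the intercept-only model, single-SNP
models for up to 99 SNPs ranked by screening posterior, and random
chromosomes; fitness-proportional selection with weights
`exp(−½ score)` computed via log-sum-exp; single-point crossover with
probability 0.8; one random bit flipped per child with probability 0.1;
one-elite preservation; stop after 400 generations or 40 consecutive
generations with an unchanged best model (a 4000/400 pair is available
through `GAConfig`). Crossover and mutation rates are the conventional
GA-library defaults; they are configurable. The default GA score is the
prior-adjusted `BIC − 2 log P(M)`, so the GA optimizes exactly the
posterior that enumeration ranks by; a plain-BIC fitness mode is
provided for comparison. Every evaluated model is cached by its sorted
index tuple, so no model's likelihood is computed twice. Ties in the
best model break toward fewer SNPs, then lexicographic order.

## Outer iteration

Iteration 0 starts from the covariate-only base model. Each iteration
runs screening, then selection; the best model becomes the next base
model. Convergence is set-equality of the best model with its base model.
Two safeguards (the underlying procedure assumes convergence and has
none): revisiting a previously seen base model stops with
`stop_reason="cycle"` and returns the best visited model by
prior-adjusted ML score (each refit with its own `τ̂`); a hard cap
(`max_outer = 50`) stops with `stop_reason="max_iter"`. Cycles have not
been observed in the test suite; the handling is defensive.

## Single-marker baselines

`sma_exact` re-maximizes `τ` per SNP on a 50-point log grid with grouped
local refinement (25 points), vectorized across SNPs by sweeping the
covariates out of the rotated design; `sma_approx` fixes `τ̂` from the
no-SNP model; `sma_ols` is simple linear regression. All report
two-sided Wald p-values (t distribution, residual degrees of freedom)
and a Bonferroni-significant set at `p < 0.05/L`. With `K = I` or
`K = 0` the weights are constant in `τ` and all mixed-model variants
coincide exactly with OLS — a useful identity the tests exploit.
Monomorphic or degenerate SNPs report `p = 1`.

## Synthetic data

The generator emulates a dense inbred panel: per LD block a latent
Gaussian AR(1) process (adjacent correlation `rho`, default 0.9 for
strong within-block LD; 0 for independence) is thresholded at
Hardy–Weinberg quantiles for a per-SNP MAF drawn uniformly from
`[maf_min, 0.5]`; realized MAFs below the floor are re-thresholded with
a larger draw, so no constant columns survive. Defaults are 328
individuals, 10 blocks of 6000 SNPs, MAF ≥ 0.01, ten causal SNPs at the
block centers (positions 3000, 9000, …, 57000 1-based at L = 60000,
scaled proportionally for smaller L), effects
`(β₁, .4, .4, .4, β₁, .4, .4, .4, β₁, .4)` with β₁ ∈ {0.05, …, 1.6},
intercept α = 1, τ = 0.1, σ² = 0.2 — values representative of salt-stress
root phenotypes in *A. thaliana*. Phenotypes come from the mixed model,
its no-signal variant (for null robustness), or its no-random-effect
variant (for misspecification checks); kinship is the VanRaden
realized-relationship matrix `W W' / (2 Σ p_j(1−p_j))` built from the
simulated genotypes themselves.

What the generator does not emulate: coalescent-realistic LD decay,
allele-frequency spectra from real demography, population stratification
beyond the kinship random effect, genotyping error, or kinship estimated
from a larger marker set than the analyzed SNPs. Passing tests therefore
demonstrate correctness of the machinery and the qualitative orderings
(conditioning rescues small effects; model selection controls FDR under
LD), not calibrated performance on any real organism.

## Problem sizes in the test suite

Unit tests run at `n ≤ 300`. The end-to-end checks use scaled study
conditions chosen once: the signal and null benchmarks at `n = 300`,
`L = 2000` (10 blocks) with 20 replicates; the two-SNP conditioning
design and variance-component recovery at `n = 500`, `L = 1000` with 50
replicates. The acceptance script reruns the same configurations. At this
scale the measured orderings are stable across seeds: the iterative
method's FDR is several-fold below SMA's under LD while its recall is
higher, SMA recovers the β = 0.2 SNP about an order of magnitude less
often, and variance-component medians land within 5% of the truth.

## Known limitations

- The screening covariance is written here as
  `Σ = A − X(X'A⁻¹X)⁻¹X'`, the exact covariance of the GLS residuals; it
  annihilates `A⁻¹X` rather than `X`. Formulations that sandwich `A`
  between ordinary projections differ and are not equivalent.
- BIC-approximate Bayes factors carry `O(n^{-1/2})` error; at very small
  `n` the model posteriors inherit it.
- The GA is stochastic; only seeded runs are reproducible. On multimodal
  spaces it can return a local optimum, though the enumeration
  cross-check shows agreement on spaces up to 15 SNPs.
- No support for multi-trait models, interaction terms, non-Gaussian
  phenotypes, or automatic covariate selection.
- `sma_ols` ignores user covariates by design (it is the classic simple
  regression baseline).
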