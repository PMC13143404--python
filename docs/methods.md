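# Methods

## Model

`gmfact` fits generalized matrix factorization (GMF) models to an
n × m response matrix Y whose entries follow an exponential-dispersion
family EF(θ_ij, φ) with mean μ_ij = E(y_ij), variance
(φ/w_ij) ν(μ_ij) and linear predictor

    g(μ_ij) = η_ij = (X Bᵀ + Γ Zᵀ + U Vᵀ)_ij (+ offset_ij)

where X (n × p) holds row covariates (batch indicators, cell-level
attributes; by default a single intercept), Z (m × q) column covariates
(by default a single intercept), B and Γ the corresponding regression
coefficients, and U (n × d), V (m × d) the latent factors and loadings.
In single-cell RNA-seq terms: the gene intercept β₀j is a baseline
expression level, the cell intercept γ₀i an estimated scale factor that
replaces fixed library-size normalization, U holds "meta-gene" scores
per cell and V gene weights.

Estimation is penalized quasi-likelihood: the latent factors are treated
as fixed parameters and the penalized negative log-likelihood

    ℓ_λ = − Σ_{(i,j)∈Ω} log f(y_ij; θ_ij, φ) + (λ/2)(‖U‖²_F + ‖V‖²_F)

is minimized over the observed set Ω. The y-only constant c(y, φ) is
included so that AIC/BIC sit on the standard likelihood scale. The
objective is bi-convex in (U, V), not jointly convex; all three fitters
find local stationary points, which is why the structured initialization
matters.

Families shipped: gaussian, poisson, binomial, gamma, negbin (NB2,
fixed or moment-estimated size), quasipoisson. Links: identity, log,
logit, inverse. Canonical pairs are the defaults. The quasipoisson
"log-density" is the Poisson kernel scaled by 1/φ (a quasi-likelihood;
no exact c(y, φ) exists), so its information criteria are
quasi-criteria.

### Sign convention

All stored derivative kernels are derivatives of the penalized
**negative** log-likelihood with respect to η:

    Ḋ = −w (y − μ) / (φ ν(μ) ġ(μ)),
    D̈ =  w α(μ) / (φ ν(μ) ġ(μ)²),  α(μ) = 1 + (y − μ)(ν̇/ν + g̈/ġ),

with α ≡ 1 under expected (Fisher) information, which keeps D̈ > 0.
Descent steps are Δ = −G/H throughout, and every gradient in the package
is verified against central finite differences of the objective; the
test suite enforces ≤ 1e−6 relative agreement for all family/link pairs.

## Algorithms

**AIRWLS** alternates one penalized Fisher-scoring step for every column
pair [β_j, v_j] against the design [X, U], then for every row pair
[γ_i, u_i] against [Z, V]; the ridge λ applies to the latent
coefficients only. Because the designs are shared across the m column
fits (and across the n row fits), the normal matrices for all fits are
formed in a single einsum and solved by one batched `np.linalg.solve` —
the same batched IRLS that drives the initialization. Steps are damped
by halving (at most 10 times) whenever the objective would increase, so
the trace is non-increasing over accepted cycles.

**Diagonal quasi-Newton** updates all blocks at once with
Δ = −G/H elementwise, H the diagonal expected information plus λ, a
fixed starting step ρ (default 0.1) and the same halving rule.

**Adaptive SGD** partitions rows into R chunks and columns into S chunks
(default target chunk size min(n, 1000) × min(m, 250)). One epoch sweeps
the S column chunks; for each, a row chunk is drawn by cycling a
reshuffled order, giving the block B = I × J. From the block derivatives
the rescaled stochastic gradients

    Ĝ_U = (m/m*_J) Ḋ_B V_J + λU_I,  Ĥ_U = (m/m*_J) D̈_B (V_J∗V_J) + λ

(and symmetrically for V, plus the unpenalized B_J and Γ_I blocks, which
mirror the latent-block treatment) are exponentially averaged,

    Ḡ ← (1−α₁)Ḡ + α₁Ĝ,  H̄ ← (1−α₂)H̄ + α₂Ĥ,   α₁=0.1, α₂=0.01,

and only rows I of (U, Γ) and rows J of (V, B) move:

    θ ← θ + ρ_t Δ,  Δ = −α_t Ḡ / max(H̄, 1e−8),
    α_t = (1−α₂ᵗ)/(1−α₁ᵗ),  ρ_t = k0/(1 + k0 k1 t)^τ.

The averaged chunk gradients are exactly unbiased for the full-batch
blocks under equal chunk sizes (tested by exhaustive enumeration). The
bias factor α_t is the printed formula of the adaptive scheme; combined
with zero-initialized accumulators it over-scales the first ~1/α₂ steps
by about α₁/α₂ = 10, which is why the default initial step k0 = 0.01 is
small (effective early step ≈ 0.1 of a quasi-Newton step) and why large
k0 can diverge on count data through the exp link. Runs that want faster
convergence should raise k0 toward 0.02–0.05 and lower k1 rather than
touch the smoothing coefficients. The global iteration counter t feeds
both ρ_t and α_t.

### Missing values

Ω is a boolean mask; masked cells of Y may hold any placeholder
(including NaN) and are never read. The SGD and quasi-Newton fitters
impute y ← μ at masked entries before evaluating the derivative kernels
— the score contribution vanishes and the Fisher weight remains in the
diagonal curvature (a preconditioner, not the objective). AIRWLS gives
masked entries zero weight in its least-squares solves. Both routes
leave the gradient over Ω identical and are covered by a poisoning test
(NaN vs. absurd placeholders, bitwise-equal fits). Completion sets
ŷ_ij = μ̂_ij on Ωᶜ and leaves observed entries untouched.

### Dispersion and the negative binomial size

φ is profiled, not jointly optimized: the search direction −G/H is
invariant to φ, so the stationary point in (B, Γ, U, V) does not depend
on it. For the deterministic fitters φ is estimated by the Pearson
method of moments (denominator N_obs − k, k = pm + qn + d(n+m) + 1,
floor 1e−8) at initialization and re-estimated once at convergence,
keeping the line-search objective on a single scale. The stochastic
fitter refreshes φ once per epoch from the monitoring subsample — the
mean Pearson statistic with the full-data degrees-of-freedom correction
— blended by an exponential average with weight α₂. An unknown NB size
is re-estimated once per epoch by moments on Pearson residuals and
frozen within the epoch.

### Convergence and divergence

SGD convergence is declared when the relative change of the objective on
a fixed seeded 10% subsample of Ω stays below `tol` (default 1e−5) for 3
consecutive epochs; the deterministic fitters apply the same rule to the
full objective they already evaluate for line search. A monitored
objective exceeding ~50× its initial absolute value (or turning
non-finite) aborts with the trace attached. Means from g⁻¹(η) are
clipped to [1e−10, 1e10] (or [1e−10, 1−1e−10]); clip events are counted
in the result.

## Identifiability

The decomposition is made unique without changing η by (1) absorbing the
X-column-space components of Γ and U into B (and the Z-components of V
into Γ) by least squares, (2) an SVD of the residual UVᵀ via the thin-QR
trick, (3) one of three normalizations: B1 (PCA convention, default:
UᵀU = Σ diagonal decreasing, VᵀV = I, first non-zero entry of each V
column positive, detection threshold 1e−12, ties broken by lowest row
index), B2 (orthonormal U), or B3 (factor-model convention:
unit-variance centered U columns, lower-triangular V with positive
diagonal; requires an intercept in X so constraint (A) centers U). The
projection is idempotent and preserves the singular values of UVᵀ. Note
that with λ > 0 the projection redistributes ‖U‖²_F + ‖V‖²_F, so
objective values comparable across algorithms are taken at the
pre-projection optimum (`manifest["final_objective"]`).

## Initialization

The null-residual strategy: m column GLMs for B, then n row GLMs for Γ
given the offsets X b̃_j, then the rank-d SVD of the deviance (or
Pearson) residual matrix of this regression-only fit — masked residuals
are set to 0, i.e. "as predicted by the null model" — with U scaled by
the singular values so it carries the magnitude (B1-style), and finally
m column GLMs with U as design and the regression offset for V. The OLS
fast path replaces each GLM by weighted least squares on a
link-transformed response; counts use the started log log(y + 1/2)
(the offset 1/2 is a convention; any constant in [0.25, 1] behaves
similarly). Row/column GLMs run at most 50 IRLS iterations at tolerance
1e−8 and fall back to the OLS path when unconverged (counted and
logged). All fits sharing a design are solved batched, so results are
independent of execution order.

## Model selection

* **Information criteria**: AIC = 2·negloglik + 2k and
  BIC = 2·negloglik + k log|Ω| with the full parameter count
  k = pm + qn + d(n+m) + 1 (not constraint-adjusted; noted in the
  manifest).
* **Cross-validation**: `folds` independent uniform entrywise holdouts
  (default fraction 0.3) — repeated holdout, not a disjoint K-fold.
  Test entries are masked before initialization and fitting. Ranks are
  processed ascending with warm starts; because a zero (u, v) column
  pair is an exact stationary point of ℓ_λ (both gradients vanish and no
  fitter can leave it), new columns are padded with small seeded
  Gaussian entries (sd 1e−2) instead of zeros. The score is the relative
  deviance on the held-out entries, averaged per entry across folds
  (scale-free across folds).
* **Spectral rules** on the singular values of the deviance-residual
  matrix at the OLS null fit: the eigengap rule returns
  argmax_k (σ_k − σ_{k+1}); the elbow rule finds the knee (the point of
  maximum distance below the chord joining the profile's endpoints) and
  returns the component just before it.

## Synthetic data

`simulate_gmf` draws data exactly from the model: standard-normal U, V
scaled so the latent term has link-scale sd `snr`, Gaussian intercepts,
responses from the requested family; the returned truth is projected to
B1. It is the well-specified case for recovery and agreement checks.

`simulate_scrna` emulates a single-cell count matrix and is deliberately
*not* the factor model, so every fitted model is misspecified, as in
real benchmarking. Counts are negative binomial (size 2) with log-mean

    log μ_ij = log L_i + b_j + batch_{b(i),j} + type_{c(i),j},

five evenly allocated cell types, three batches (effects N(0, 0.3²) on
all genes), log-normal(0, 0.4²) library sizes L_i, and baseline
log-expression b_j ~ N(2, 0.5²), mimicking a most-variable-genes
selection of moderately expressed genes. Each type up-regulates a random
10% of genes with effects N(1, 1²). The up-regulation location is a
deliberate design choice: with zero-mean effects the five centered type
profiles sum to zero and span only four dimensions, whereas real marker
signatures are predominantly over-expressed (differential-expression
factors in standard single-cell simulators are multiplicative
log-normal, hence nonzero-mean on the log scale), and the resulting signal is genuinely five-dimensional.
Batch labels are exported as dummy covariates in X.

What the generator does **not** emulate: zero inflation, lineage or
branching trajectories, gene–gene correlation beyond the type/batch
structure, ambient RNA and doublets. Tests passing on these data
therefore demonstrate correctness of the estimation machinery and
qualitative robustness to NB overdispersion under a Poisson working
model — not performance on any real dataset.

## Problem sizes used in the automated checks

The acceptance checks run at n×m up to 2000×200 (rank selection), with
1000×100 Poisson instances for cross-algorithm agreement and the batch
probe, and 5 seeds where a majority criterion applies. These sizes are
chosen so the full pipeline (initialization, three fitters, repeated
holdout over a rank grid) runs comfortably on one CPU core while keeping
the signal-to-noise regime of the larger simulated designs. The CV grid
{2,…,7} with 2 repeated holdouts and a 100-epoch quasi-Newton fitter
per cell reproduces the rank-selection behaviour at a fraction of the
cost of a full 5-fold scan.

## Known limitations

* The sqrt link is not offered: it is non-bijective over the real line,
  which breaks the finite-difference gradient contract on half the
  predictor domain.
* Heterogeneous per-column families, zero-inflated models and tensor
  factorization are out of scope.
* The elbow rule assumes a convex decreasing scree profile; on profiles
  with heterogeneous signal strengths the eigengap rule can lock onto a
  gap inside the signal block (largest-single-gap behaviour), which is
  inherent to the argmax-difference definition.
* AIC/BIC use the unadjusted parameter count; with strong penalization
  the effective dimension is smaller, so the criteria are conservative.
* The stochastic fitter's early iterations are over-scaled by the
  printed bias factor (see above); k0 well above ~0.05 can diverge on
  count data.
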