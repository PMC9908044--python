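# Methods

## Estimands

For a trial with clusters i = 1..G of sizes nᵢ and cluster-level true
effects δᵢ on a collapsible scale, the package computes

- participant-average effect: Δ_P = Σ nᵢδᵢ / Σ nᵢ;
- cluster-average effect: Δ_C = Σ δᵢ / G.

Both are weighted averages of the same cluster effects and therefore lie
between min δᵢ and max δᵢ; they coincide whenever the δᵢ are constant
(whatever the sizes) or the nᵢ are constant (whatever the effects).

For binary outcomes the generative model is a random-intercept logistic
model: the cluster-conditional log-odds is η = μ(n) + δ(n)·arm + b,
b ~ N(0, σ_b²). Marginal event probabilities are obtained by integrating
the intercept out, p = ∫ expit(η + σ_b z) φ(z) dz, with 64-node
Gauss–Hermite quadrature in the probabilist convention (nodes/weights from
`numpy.polynomial.hermite_e.hermegauss`, weights divided by √(2π)), so
results are bit-reproducible; quadrature agrees with 10⁷-draw Monte Carlo
integration to better than 10⁻³. Δ_P applies the summary measure (risk
difference, risk ratio or odds ratio) to probabilities averaged with
participant weights (stratum count × size); Δ_C uses cluster weights
(stratum count).

**Design choice — cluster-average odds ratio.** For non-collapsible
measures there is no single canonical cluster-average definition. We
define Δ_C as the summary measure applied to equally-cluster-weighted
marginal probabilities, so both estimands are "summary measure of weighted
average potential outcomes" and differ only in the weights — exactly
parallel to the collapsible case. The alternative (exponentiated average
of cluster log odds ratios) is available via
`marginal_estimands_binary(..., cluster_average_of_log_or=True)`.

## Estimators

All fits use the design (1, arm) on participant-level data or cluster
means. Point-estimate identities that hold on every dataset, exactly:

- size-weighted cluster-level WLS ≡ unweighted IEE (both are the
  participant-level difference in arm means);
- unweighted cluster-level OLS ≡ inverse-size-weighted IEE (both are the
  difference of arm-wise unweighted means of cluster means).

**Sandwich variance.** `cluster_robust_covariance` computes
B⁻¹(Σᵢ sᵢsᵢᵀ)B⁻¹ with scores summed within cluster. CR0 is the default;
CR1 multiplies by G/(G−1). Confidence intervals use t with G−2 degrees of
freedom by default (`df_method="normal"` switches to normal quantiles);
with a small-to-moderate number of clusters the plain sandwich is
anti-conservative, and CR0 + t(G−2) is a conventional, conservative
default. At least 3 clusters are required (the sandwich is degenerate
below that). Weighted cluster-level analyses always use HC0
heteroskedasticity-robust errors — the size weights make the cluster-mean
regression heteroskedastic; unweighted cluster-level analysis uses
classical errors by default with an HC0 option.

**Binary-outcome IEE.** Logit, log and identity links deliver odds-ratio,
risk-ratio and risk-difference summaries. Fisher scoring with
step-halving keeps fitted probabilities inside (0, 1) for the log and
identity links; a fit that cannot stay in range raises a convergence error
carrying the last iterate.

**Mixed model.** y_ij = β₀ + β₁·armᵢ + bᵢ + e_ij with compound-symmetric
cluster covariance. The (restricted) likelihood is profiled over
ρ = σ_b²/(σ_b²+σ_e²) ∈ [0, 0.999] with bounded scalar minimization
(xatol 10⁻⁸); for each ρ the fixed effects are GLS, which for a
cluster-constant design reduces to a cluster-level regression with weights
w(n) = n/(1 + (n−1)ρ), and σ² is profiled in closed form. REML is the
default (ML available); an estimate pinned at either bound is flagged
`icc_at_boundary`. `fixed_rho` skips estimation and fits GLS at a known
ICC — used for limit checks (ρ→0 recovers the IEE estimate, ρ→0.999 the
unweighted cluster-level estimate) and for isolating the weighting
mechanism from ICC-estimation error (below). Cross-checked against an
independent REML implementation to ~10⁻⁴ on the coefficient.

**Exchangeable GEE.** Alternates Fisher-scoring coefficient updates under
the working correlation with the moment estimator of α: the Pearson
dispersion is φ = Σe²/(N−p) and α = Σ within-cluster pairwise residual
products / ((N_pairs − p)·φ), clamped to [0, 0.999] (a negative moment
estimate is clamped to 0 and flagged). Convergence is max |Δβ| below
`tol`; non-convergence raises with the last iterate. The working-block
inverse uses the closed form R⁻¹ = [I − α/(1+(n−1)α)·J]/(1−α), so no
matrix is ever formed. Cross-checked against an independent GEE
implementation to ~10⁻⁶.

## Simulator

Gaussian outcomes: y_ij = μ(nᵢ) + δ(nᵢ)·armᵢ + bᵢ + e_ij with
bᵢ ~ N(0, σ_b²), e_ij ~ N(0, σ_e²); binomial outcomes put the same linear
predictor on the log-odds scale. σ_b may be given directly or via the ICC
(σ_b = σ_e·√(ρ/(1−ρ))); for binomial scenarios an ICC is interpreted on
the latent logistic scale with residual SD π/√3, which differs from the
observed-scale ICC — scenarios in this package specify σ_b directly.

Replicate streams use a counter-based Philox generator keyed by
(base seed << 32) + replicate, so any replicate regenerates bit-identically
and independently of execution order.

**Allocation** defaults to stratification by size stratum (even split per
stratum, odd cluster randomized), which fixes the number of clusters per
(arm × stratum) and hence makes the expected estimate of every estimator
available in closed form; `simple` gives complete randomization with equal
arm totals. A stratum with a single cluster cannot be split and triggers
a pooled-allocation fallback with a warning.

**Presets.** `figure1`: 30 clusters of size 10 (effect 5) and 30 of size
100 (effect 1), σ_e = 5, baseline 0 (any constant baseline shifts all
estimators equally, so zero is the natural choice). `type1-binary`:
baselines logit(0.10)/logit(0.20) with a common conditional log-OR
log(0.75) — outcomes depend on size, effects do not. `type2-binary`:
common baseline logit(0.10) with conditional ORs 0.75 (small) and 0.50
(large) — a pure effect-by-size interaction; the common 10% baseline is
this package's choice, made so the scenario isolates type-2
informativeness.

What the generator does *not* emulate: covariates, missing outcomes,
intercurrent events, continuous cluster-size distributions, unequal
allocation, longitudinal structure. Passing tests therefore demonstrate
estimator properties under clean informative-cluster-size mechanisms, not
robustness to those real-data features.

## Bias study

For each grid ICC and replicate, a dataset is generated and each requested
estimator fitted; cells report mean estimate, bias (mean − truth),
empirical SD, Monte Carlo SE (SD/√R), mean model SE and CI coverage.
Coverage is evaluated against each estimator's own targeted estimand
(participant- or cluster-average); the model-based comparators are
assessed against the configured study truth. Replicates whose fit fails
are excluded and counted; more than 5% failures in any cell aborts the
study. Replicate r uses the same random stream at every grid ICC (common
random numbers), which sharpens bias comparisons along the grid.

The default is R = 500 replicates on the grid {0, 0.05, 0.1, 0.2}
(configurable; the package's own checks use 500, which keeps 3·MC-SE
bounds discriminating at desk-scale runtime), ICC grid default
{0, 0.01, 0.02, 0.05, 0.1, 0.15, 0.2} for exploratory runs.

**Analytic oracle.** `expected_mixed_estimate(ρ, spec)` returns
Σ_s c_s·w(n_s)·δ(n_s) / Σ_s c_s·w(n_s) with w(n) = n/(1+(n−1)ρ) — the
expectation of the compound-symmetry GLS arm contrast at known ρ under
stratified allocation. At ρ = 0 it equals Δ_P, as ρ → 1 it tends to Δ_C,
and it is monotone between them.

Two distinct agreement checks are run, and the distinction matters:

1. *GLS at the known ICC* matches the oracle evaluated at the nominal ICC
   (within 3 MC-SE at every grid point). This validates the weight
   formula itself.
2. *The fitted (REML) mixed model* matches the oracle evaluated at each
   replicate's **estimated** ICC. Under type-2 informative cluster size
   the mean model is misspecified — the effect differs by stratum — and
   that heterogeneity inflates the REML variance-component estimate, so
   ρ̂ systematically exceeds the generative ICC (e.g. mean ρ̂ ≈ 0.04 when
   the true ICC is 0). The model weights clusters by w(n, ρ̂), not
   w(n, ρ_true); comparing against the oracle at the nominal ICC would
   conflate the weighting mechanism with ICC-estimation bias. One
   consequence worth noting: the mixed model and GEE are biased for Δ_P
   even at ICC = 0 in this scenario, both because ρ̂ ≥ 0 by construction
   and because of the misspecification-driven inflation.

## Known limitations

- Generalized linear *mixed* models for binary outcomes are not
  implemented; the bias experiment is linear, and binary outcomes are
  supported for IEE/GEE only.
- No covariate adjustment, survival outcomes, stepped-wedge or
  cluster-crossover designs.
- Small-sample corrections are limited to CR1 and t(G−2) intervals; CR2
  and related corrections are out of scope.
- The moment estimator of the GEE working correlation uses the
  (N_pairs − p) denominator; other software may use N_pairs, giving
  slightly different α̂ (point estimates are insensitive in practice).
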