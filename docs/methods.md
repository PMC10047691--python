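# Methods

## Model

The observed response vector y (length n) follows

    y = X δ + Z u + e,    u ~ N(0, G~),    e ~ N(0, σe² I_n),

with two crossed grouping factors: participants (S levels) and items (I
levels).  X contains an intercept, the p base covariates and a chosen subset
of their product interactions; with every product of order ≥ 2 included there
are k = 2^p − p − 1 interaction columns.  The random part carries, for each
factor, a random intercept and optional random slopes on fixed-effect columns.
Within a factor the coefficient vector of one level has covariance Σ_S (or
Σ_I) built from per-term SDs and a common correlation ρ; across factors and
across levels coefficients are independent, so G~ is block diagonal
(kron(I_S, Σ_S) ⊕ kron(I_I, Σ_I)).  Residuals are homoscedastic: R = σe² I_n.
The canonical report ordering for the standard two-covariate model is
(b0, b1, b2, b3, sig1, sig2, sig3, sig4) = (fixed effects; participant
intercept SD, item intercept SD, participant slope SD, residual SD).

A compact term-level view V = Z G Zᵀ + R with G_jl = σ²_{j,S} + σ²_{j,I} on
the diagonal and ρ_S σ_{j,S} σ_{l,S} + ρ_I σ_{j,I} σ_{l,I} off it is exposed
as `assemble_G` / `assemble_V` for single-observation-structure reasoning; all
estimation uses the expanded per-level covariance, which is the correct
marginal covariance of crossed designs.

Complete-data machinery:

* `solve_henderson` solves the mixed-model equations
  [[XᵀX, XᵀZ~], [Z~ᵀX, Z~ᵀZ~ + σe² G~⁻¹]] (δ, u) = (Xᵀy, Z~ᵀy),
  equivalent to GLS fixed effects and BLUP random effects.  Cross-products are
  cached per design; each solve is O(q³) with q = S·t_S + I·t_I (214 for the
  default scenario), independent of n after the one-time O(n) pass.
* `marginal_loglik` evaluates log N(y; Xδ, V) by the Woodbury identity:
  log|V| = n log σe² + log|G~| + log|G~⁻¹ + Z~ᵀZ~/σe²|, so no n × n matrix is
  formed.
* `ml_fit` maximizes the profile likelihood over log-SD parameters (optionally
  a Fisher-z correlation) with L-BFGS-B, fixed effects profiled through the
  MME.  It is cross-checked against lme4 (ML) in the test suite.

## Incomplete data

A response vector is partitioned row-wise into observed, missing, left- and
right-censored.  Censoring flags the extreme round(rate·n) rows at the
empirical quantile threshold t (ties broken by row order, so the achieved
count is exact); flagged values are replaced by t and the true values are only
known to lie beyond it.  `side="both"` splits the rate equally between tails,
and an alternative trimming rule (`trim_sd`) censors beyond a multiple of the
SD, mirroring the field's 2.5-SD practice.  Missingness is MCAR (iid
Bernoulli), MAR (masking probability logistic in an observed covariate,
default AoA, slope 1 per covariate SD, intercept calibrated by bisection to
hit the target rate within 1e-4), or MNAR (the same logistic driven by the
response itself).  Corruption order is fixed: censoring first, then
missingness among the remaining observed rows, so achieved combined rates
match the requested ones.  The 4 × 4 benchmark grid crosses MAR rates
{0, 5, 10, 20}% with right-censoring rates {0, 5, 10, 20}%, each condition
carrying a deterministically derived child seed.

## The SEM estimator

Iteration j (of N = 50 by default, burn-in M = 10):

1. **S-step.**  G (= 100) sweeps of a systematic-scan Gibbs sampler targeting
   P(u, y_unobs | y_obs, Θ_j), from a cold start (u = 0).  Each sweep draws,
   in order: the residuals of the unobserved rows from N(0, σe²) truncated —
   at censored rows by the censoring threshold (so right-censored imputations
   stay ≥ t), at missing rows by the observed response range; then the
   participant block and the item block coordinate-wise from their Gaussian
   full conditionals given the completed response, vectorized across levels.
   The literal scalar-extreme bound recipe for the intercept coordinates
   (per-level observed range around the previous value) is kept as a
   truncation of those conditionals; it is isolated in `_intercept_bounds` so
   alternative readings are one-line swaps, and it almost never binds.
   Unobserved rows are completed as Xδ + Zu + e.
2. **M-step.**  Θ_{j+1} = argmax of the completed-data likelihood.  The
   default maximizes the marginal mixed-model likelihood of the completed
   response (profile ML, warm-started at Θ_j, ~tens of O(q³) evaluations).
   `mstep="moments"` instead applies the closed-form complete-data maximizer
   given the sampled (u, e): σ̂²_{j,S} = S⁻¹ Σ_s u²_{j,s}, σ̂²_e = n⁻¹ Σ e²,
   correlations as sample correlations of the paired draws, then δ from
   Henderson's system.  The moment form is cheaper but adds Monte-Carlo
   noise of order (2S)^{-1/2} per iteration to the weakly identified SDs.

The estimator is the arithmetic per-component mean of Θ_{M+1..N}.  On fully
observed data the S-step consumes no randomness and the default SEM fit
coincides with the direct ML fit.

**Initialization** ("random"): OLS fixed effects on the observed rows,
variance components from residual moment heuristics (group-mean SDs for the
intercepts), all with seeded multiplicative log-normal jitter.

**SAEM** damps the update: Θ_{j+1} = Θ_j + γ_j (M(Y_j) − Θ_j), componentwise
on (δ, variances, Fisher-z correlations).  Step schedules: slow cosine
γ_j = cos(jπ/2N); hybrid cos(j·arccos(0.3)/20) for j ≤ 20 then 6/j (continuous,
γ_20 = 0.3); linear 1 − (j+1)/N clipped to [0,1] (the literal printed form
−(j+1)/N is selectable as `linear_literal`); constant 1.  γ ≡ 1 reproduces SEM
bit for bit.  **MCEM** keeps γ = 1 and averages the complete-data objective
over m(k) independent imputations; m ≡ 1 again reproduces SEM exactly.

## The MCMC comparator

A Metropolis-within-Gibbs sampler over (δ, SDs, latent unobserved responses,
u): latent responses are redrawn exactly as in the S-step; item blocks and
participant intercepts use conjugate Gaussian conditionals; the participant
random-slope block — the fixed-random interaction, where plain Monte-Carlo
updates mix poorly — moves by Hamiltonian Monte Carlo (leapfrog integrator,
L = 10 steps, step size 0.6 with one automatic halving if acceptance hits
zero over a 50-proposal window, diagonal mass set to the block's current
conditional precision); δ has a conjugate update under a wide normal prior
(SD = 1e3 × sd(y)); SDs move by random-walk MH on the log scale under
half-Cauchy(scale = sd(y)) priors.  The point estimate is the post-burn-in
posterior mean (800 draws, 200 burn-in by default).  The priors are the
package's own weakly-informative choices; the comparator is interpretable but
not claimed identical to any external implementation.

## Synthetic scenario

The generator emulates a handwriting-latency experiment: S = 30 participants
write the names of I = 150 drawings (4500 RTs).  Per item, AoA ~ uniform(1, 15)
years and a letter count ~ 2 + Poisson(5); the word-length category is a
balanced median split (ranked by letter count, ties by item index, upper half
"long").  AoA is centered at the item-sample mean by default: the intercepts
then describe behavior at the mean acquisition age, keeping the participant
intercept SD and slope SD separately identifiable while preserving the year
scale of b1 and sig3 (options: "zscore", "raw").  The generating truth
defaults to the reference vector (1045, 93.16, −52.28, 2.80, 14.57, 230.8,
9.79, 282.0); responses are the linear predictor plus participant intercepts,
item intercepts, participant AoA slopes and residuals, all Gaussian and
mutually independent (no intercept-slope correlation).  The generating draws
are retained in a test-only `truth` attribute.

What the generator does *not* emulate: right-skewed RT distributions,
trial-order and fatigue effects, heteroscedastic residuals, correlated
random effects, or covariate measurement error.  Passing tests therefore show
the estimators are correct under the stated Gaussian LMEM, not that real RT
data satisfy it.

Identification note: with 30 participants the participant-level SDs (sig1,
sig3) carry little information (posterior/likelihood spread of order 25-50% of
their values), and the item-level fixed effects (b2, b3) have sampling SDs of
tens of ms at 150 items.  Single-dataset benchmark columns therefore agree
closely between estimators fit to the same data while individual components
can sit far from the generating values; comparisons in the evaluation harness
can be scored against either the generating truth or the complete-data
reference fit (`run_grid(reference=...)`).

## Evaluation harness

Estimates are compared as canonical 8-vectors by MAE, Pearson correlation
(LCor) and Spearman rank correlation (RCor).  `run_grid` corrupts a fresh copy
of the scenario per grid condition, fits any subset of {SEM, SAEM, MCMC, KE}
(KE = ML on the observed rows only, the field's status-quo), and is
deterministic given one master seed; failed fits are recorded as failed rows
without stopping the grid.  QQ diagnostics return centered residuals against
normal quantiles (slope ≈ residual SD; `standardize=True` for the normalized
plot).

## Numerical choices and degenerate inputs

* SD floor 1e-10 inside factor covariances keeps G~ invertible as SDs → 0, so
  the zero-variance limit of Henderson's system reproduces OLS; σe is floored
  at 1e-8 with a warning.
* Truncated-normal draws use the inverse-CDF construction through scipy's
  truncnorm, which evaluates standardized CDF differences in log space and is
  safe far into the tails (draws at 8-9 SDs remain inside their bounds).
* Incompatible Gibbs bounds (empty intervals) are widened to the unconstrained
  conditional with a logged warning; group levels with fewer than two observed
  rows contribute no range bound.
* Censoring ties at the threshold are broken by row order (stable sort), making
  the flagged count exact and corruption bit-reproducible.
* The M-step optimizer is bounded to ±12 log units around its warm start;
  non-finite parameter vectors abort a fit with the partial trace returned for
  diagnosis.
* All randomness flows through numpy Generators seeded from the configs; equal
  seeds give bit-identical traces, reports and posterior draws.

## Problem sizes used in the checks

The test suite exercises the full 30 × 150 design where the claims are about
it (the low-censoring recovery correlations, with N=50/M=10/G=100; parameter
recovery over 10 seeds at 5% MAR + 5% censoring with N=25/G=25) and documented
reduced scales elsewhere: the SEM-versus-MCMC grid ordering runs 10 × 30
datasets over 5 master seeds with N=12/G=10 against 400-draw MCMC chains, and
the distributional sampler checks use dedicated toys sized for their
Monte-Carlo tolerances.  The grid-ordering check scores both methods against
the complete-data reference fit of each dataset, which isolates method error
from the common dataset sampling noise that dominates at reduced item counts.

## Known limitations

* One common within-factor correlation per factor (not a free correlation
  matrix); correlations are fixed at zero in the standard presets.
* Exactly two grouping factors; no REML variants; Gaussian responses only;
  no interval censoring; covariates and grouping labels must be complete.
* SEM/SAEM traces are averaged after a fixed burn-in (no adaptive stopping),
  matching the fixed-N design of the estimator.
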