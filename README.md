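# semlmm

Stochastic-EM estimation of linear mixed-effects models with crossed random
effects when the response is partly censored and partly missing.

## The problem

Reaction-time experiments in psycholinguistics have every participant respond
to every item, so the natural analysis is a linear mixed-effects model (LMEM)
with two crossed random factors — participants and items — plus whatever
fixed-by-fixed interactions the hypotheses require and, ideally, the
fixed-by-random interactions (random slopes) the design supports.  In
practice a sizable share of the responses never reaches the model: trials are
lost to equipment or task errors (missing at random given the covariates), and
extreme latencies are routinely right-censored by trimming rules.  The common
practice of "keeping the case empty" — fitting the model on the observed rows
only — biases the estimates.

`semlmm` implements a stochastic expectation-maximization (SEM) estimator that
treats the censored and missing responses as latent data.  For the standard
picture-naming design the model is

```
RT_si = b0 + b1·AoA_i + b2·Lett_i + b3·AoA_i·Lett_i
        + S0_s + I0_i + S1_s·AoA_i + e_si,

S0_s ~ N(0, sig1²)   participant intercepts
I0_i ~ N(0, sig2²)   item intercepts
S1_s ~ N(0, sig3²)   participant AoA slopes (the fixed-random interaction)
e_si ~ N(0, sig4²)   residuals,
```

with AoA the item's age of acquisition and Lett a binary word-length category.
More generally the package handles p covariates, any subset of the
2^p − p − 1 product interactions, and random slopes on either factor, with the
within-factor coefficient covariances Σ_S, Σ_I assembled from SDs and common
correlations and the marginal covariance V = ZGZᵀ + σe²I never formed densely
(Woodbury factorization on the random-effect blocks).

Each SEM iteration alternates:

* **S-step** — a truncated-normal Gibbs sampler redraws the unobserved
  responses from P(Y_unobs | Y_obs, Θ): residuals at censored rows are drawn
  truncated at their censoring thresholds, missing rows bounded by the
  observed response range, and the participant and item random-effect blocks
  are redrawn from their Gaussian full conditionals.
* **M-step** — the completed-data likelihood is maximized: fixed effects and
  BLUPs come from Henderson's mixed-model equations and the variance
  components from a quasi-Newton profile-likelihood search (a closed-form
  moment M-step over the sampled random effects is available as
  `SEMConfig(mstep="moments")`).

The estimate is the post-burn-in average of the iterate trace,
Θ̂ = (N−M)⁻¹ Σ_{j>M} Θ_j.  Two damped variants reuse the same machinery: SAEM
(updates shrunk by a decreasing step-size schedule γ_j — slow-cosine, linear,
or hybrid cosine/6-over-j) and MCEM (m imputations averaged per iteration).  A
Metropolis-within-Gibbs sampler with a Hamiltonian Monte Carlo update for the
random-slope block provides a Bayesian comparator, and a "keep the case empty"
(KE) baseline fits the observed rows only.

## Worked example

Simulate the default 30-participant × 150-item scenario (4500 RTs, generating
vector b0=1045, b1=93.16, b2=−52.28, b3=2.80, sig1=14.57, sig2=230.8,
sig3=9.79, sig4=282.0), corrupt it with 5% MAR missingness plus 5%
right-censoring, and fit:

```python
import numpy as np
from semlmm import (ScenarioSpec, SEMConfig, IncompletenessConfig,
                    build_design, corrupt, simulate_dataset,
                    standard_model_spec, sem_fit, mae, lcor, rcor)

spec = ScenarioSpec(seed=7)                      # 30 x 150, reference truth
sim = simulate_dataset(spec)
design = build_design(standard_model_spec(), sim.data)
data = corrupt(sim.data["RT"].to_numpy(), sim.data,
               IncompletenessConfig(miss_rate=0.05, cens_rate=0.05, seed=42))
trace = sem_fit(design, data, SEMConfig(n_iterations=50, burn_in=10,
                                        gibbs_sweeps=100, seed=0))
theta = trace.theta_hat
print(dict(zip(theta.canonical_names(), np.round(theta.canonical(), 2))))
print(mae(theta, spec.true_params), lcor(theta, spec.true_params),
      rcor(theta, spec.true_params))
```

Output:

```
{'b0': 1039.12, 'b1': 89.05, 'b2': -75.43, 'b3': -6.72,
 'sig1': 16.39, 'sig2': 222.44, 'sig3': 9.03, 'sig4': 281.95}
MAE  6.706   LCor 0.9998   RCor 1.0
```

439 of the 4500 rows were unobserved, yet the eight recovered parameters
correlate with the generating vector at 0.9998 (Pearson) and preserve its
complete rank order; the mean absolute error of 6.7 is dominated by the
item-level fixed effects (b2, b3), whose sampling noise is irreducible at 150
items.  The same workflow is available from the shell:

```bash
semlmm simulate --participants 30 --items 150 --seed 7 --out scenario.csv
semlmm corrupt scenario.csv --miss-rate 0.05 --cens-rate 0.05 --seed 42 --out corrupted.csv
semlmm fit corrupted.csv --method SEM -n 50 -m 10 -g 100 --seed 0 --trace-out trace.csv
semlmm grid --methods SEM,SAEM,MCMC,KE --seed 1 --out report.csv
semlmm report report.csv --metric mae
```

`semlmm grid` runs the full benchmark: a 4 × 4 grid of missingness
(0/5/10/20% MAR) crossed with right-censoring (0/5/10/20%), each condition
corrupted with a derived seed and scored by MAE, Pearson (LCor) and Spearman
(RCor) correlation against the reference vector.

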