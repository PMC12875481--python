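# Methods

## The model

A responder in the ultimatum game sees a proposed split of ¥500 — a
self-reward SR (their share) and an other-reward OR (the proposer's share) —
and must accept or reject within 10 s.  We model each decision as a Wiener
diffusion with unit diffusion coefficient: evidence starts at `z·α` between
an accepting boundary at 0 and a rejecting boundary at `α`, accumulates with
drift

    δ_t = β(SR)·SR_t + β(DI)·DI_t + β(AI)·AI_t ,

and the response time is the first-passage time plus a nondecision time `τ`.
The inequity regressors are

    DI_t = max(OR_t − SR_t, 0)   (disadvantageous inequity)
    AI_t = max(SR_t − OR_t, 0)   (advantageous inequity)

so exactly one of them is nonzero on any unequal trial.  Rewards are scaled
to model units at ¥100 per unit (`scale_yen`), giving SR ∈ [0.25, 3.75]
under the task design; on the raw-yen scale the published coefficient
magnitudes (≈ 0.2–1) and the Uniform(−3, 3) coefficient prior would be
meaningless.  The scale is explicit in the configuration and all outputs.

Nine drift specifications are admissible: the seven non-empty subsets of
{SR, AI, DI}, the {SR, OR} alternative, and a constant-only drift.  They are
compared by trial-wise WAIC (deviance scale, variance-form penalty) summed
over all trials of all participants; the lowest total wins.

### Likelihood

The first-passage density at either boundary is evaluated with the
classical dual series: an image-term ("small-time") expansion and an
eigenfunction ("large-time") expansion of the driftless unit-boundary
density, with the drift and boundary separation restored analytically.  Per
evaluation point the branch needing fewer terms at the truncation tolerance
(default 1e−7) is used.  The analytic absorption probability
`P(reject) = expm1(−2δαz) / expm1(−2δα)` (→ `z` as δ → 0) and the
unconditional mean decision time `(α·P(reject) − zα)/δ` are used for choice
probabilities and RT prediction; both are verified against numerical
quadrature of the density in the test suite.

Timeout trials (no response within 10 s) are retained in data files but
excluded from every likelihood, mirroring the exclusion of error trials in
the experimental design.

### Priors and sampling

Priors: `α, τ ~ HalfNormal(σ = 2)`, `z ~ Uniform(0, 1)`, each
`β ~ Uniform(−3, 3)`.  During sampling `τ` is additionally restricted to
(0, 0.99·min observed RT): the likelihood is exactly zero for `rt ≤ τ`, and
without the restriction chains waste time on a −∞ plateau.

The sampler is a self-contained adaptive Metropolis scheme, fitted
independently per participant but vectorized across (participant, chain)
pairs so that cohort-scale work shares each likelihood evaluation:

1. first 60% of burn-in — component-wise Gaussian random walk with
   Robbins–Monro scale adaptation toward 0.44 acceptance;
2. last 40% of burn-in — scales frozen, states collected to estimate a
   per-participant posterior covariance (pooled over chains);
3. sampling — joint random-walk proposals with covariance
   `(2.38²/d)·Cov̂`, no further adaptation, so retained draws form a
   time-homogeneous Markov chain.

Defaults are 4 chains, 2,000 burn-in and 2,000 retained draws per chain
(the original analysis used 15,000/5,000; the full setting is a constructor
argument).  Convergence is checked with the split-chain Gelman–Rubin
statistic (each chain halved, classic between/within variance ratio),
cross-checked against `arviz.rhat(method="split")` in the tests; synthetic
56-trial fits at the defaults give max R̂ ≈ 1.03.  The point-estimate
convention is the posterior mean.

### The logistic value-model baseline

The choice-only alternative sets `V_reject = 0`, `V_accept = γ0·SR −
γ(AI)·AI − γ(DI)·DI` and `P(reject) = logistic(V_reject − V_accept)`.  It is
fitted by Firth's bias-reduced method — Newton iterations on the
Jeffreys-penalized likelihood `ℓ(γ) + ½ log det X'WX` with step-halving —
so estimates stay finite under complete separation, the typical situation
for responders who accept every offer.  The solver is validated against an
independently coded Nelder–Mead optimization of the penalized likelihood,
and its bias reduction against plain maximum likelihood on small-sample
simulations.  When the two model families are compared on choices alone,
both are scored with a Bernoulli-likelihood WAIC: the DDM through its
analytic rejection probability at each posterior draw, the logistic model
through Metropolis draws under flat Normal(0, 10²) coefficient priors.

## Synthetic cohort generator

The generator emulates the behavioural structure of the published cohort:

* **Task**: 7 base splits (¥350–150 … ¥50–450), 8 trials each, independent
  uniform jitter on a ¥5 grid within ±¥25 per reward, 10-s deadline.
* **Population**: each agent's parameters are independent truncated-normal
  draws anchored to the published across-participant means and SDs
  (boundary 2.16 ± 0.680, bias 0.543 ± 0.0962, nondecision 0.591 ± 0.266 s,
  β(AI) 0.254 ± 0.868, β(DI) 0.371 ± 0.481, β(SR) −0.930 ± 0.504), truncated
  to the parameter supports.
* **All-accept-like subgroup**: with probability 13/63 (matching the
  observed fraction of responders who rejected nothing) an agent instead
  gets β(DI) ≈ 0, small β(AI), and a strongly negative β(SR) (−2.0 ± 0.3,
  truncated to (−3, −1)), which makes rejection rare in every condition
  while response times stay variable.

What the generator deliberately does **not** model: correlations among the
population parameters (unreported for the real cohort; draws are
independent), proposer identity effects, session/time-on-task effects, and
any neural data.  Two consequences matter for interpreting green tests:

* The generated cohorts reproduce the rejection-rate gradient over
  conditions, the slower-accept-than-reject pattern for strongly
  disadvantageous offers, and a strong positive correlation between β(DI)
  and rejection of disadvantageous offers (r ≈ 0.8 at n = 63).
* The published *negative* correlation between β(SR) and rejection rate
  does **not** emerge: with independent draws the mechanistic sign is
  positive (a larger β(SR) pushes drift toward the rejection boundary).
  The empirical negative sign plausibly reflects population correlation
  structure among the real participants (or estimation geometry under the
  strong SR/DI collinearity of the design) that independent draws cannot
  produce.  Tests therefore assert the β(DI) and β(AI) relations and report
  the β(SR) relation without asserting its sign.

## Simulator

Trials are simulated by Euler–Maruyama with step `dt = 1e−3 s` plus an
exact Brownian-bridge crossing probability within each step, which removes
the O(√dt) absorption bias of the plain Euler scheme; at this step size the
simulated choice frequencies match the analytic probabilities within Monte
Carlo error at n = 10⁵ and the decision-time distribution is within
Kolmogorov distance < 0.01 of the density.  An inverse-CDF backend
(`wfpt.quantile_decision_time`) is available for exact time sampling.
Simulated first passages later than the deadline are recorded as timeouts.

## Validation battery

* **Parameter recovery**: canonical reward-seeking (β(SR) = −1.5,
  β(DI) = β(AI) = 0) and inequity-averse (β(DI) = 1.0, β(AI) = 0.5,
  β(SR) = −0.5) agents, both with α = 2, z = 0.5, τ = 0.5 s, are simulated
  for 56 trials and refitted; the package default is 20 repeats (the
  original procedure used 100; the count is a parameter).  One caveat worth
  knowing: the posterior mean of the boundary separation is upward-biased
  by ≈ +0.3 for the reward-seeking agent at 56 trials — with few rejections
  the posterior over α is right-skewed along the boundary/drift trade-off —
  while all other parameters recover with |bias| ≤ 0.15.  Recovery of drift
  coefficients across a grid of truths correlates ≥ 0.8 with the truth, and
  truths beyond the ±3 prior bound come back saturated just below 3.
* **Leave-one-out RT cross-validation**: one valid trial per condition held
  out per fold (8 folds in the standard design), the model refitted on the
  remaining 49 trials, and the held-out RT predicted as τ̂ plus the
  analytic mean first-passage time at the posterior-mean parameters.  The
  analytic predictor is deterministic and testable; a simulation-based
  predictor is available via `predictor="simulate"`.  Predictions are
  unbiased on self-generated data.
* **Posterior-predictive simulation**: replicate datasets simulated at the
  posterior-mean parameters, summarized in the same condition ×
  {accept, reject} tables as observed behaviour.

## Numerical choices and degenerate inputs

* Truncation tolerance of the density series: 1e−7 (configurable); the
  branch switch follows the standard term-count bounds.
* Initial MCMC states are drawn near the prior bulk and re-drawn (up to 200
  times) until the posterior is finite.
* Perfectly collinear design regressors report a +inf VIF sentinel;
  zero-variance regressors are a diagnostics error naming the regressor.
* Correlation pairs with n < 3 raise; zero-variance pairs are flagged NaN
  and excluded from the Holm family with a warning.
* Behavioural cells with no trials of a choice are explicit NaN, never 0.
* Failed fits in a selection run mark the (participant, spec) cell NaN
  rather than aborting; failed recovery repeats are excluded and counted.

## Problem sizes in the shipped checks

The test-suite and acceptance-script sizes are chosen to exercise the
full design (56 trials, 7 conditions, 4 chains) at cohort sizes of 10–63
participants, 10 replicate cohorts for selection recovery, and 20 recovery
repeats; each is a parameter and can be raised to the original study's
settings through the corresponding configuration objects.

## Known limitations

* Per-participant independent fits are the default; a hierarchical
  population model is out of scope for the acceptance surface.
* No collapsing boundaries or trial-to-trial variability parameters
  (sv, sz, st); the plain four-parameter Wiener likelihood is assumed.
* The generator's independence assumption above: pipeline-level checks
  validate internal consistency, not the population correlation structure
  of real cohorts.
* Printed VIFs of the original design (1.29, 2.77, 3.06) depend on the
  exact deposited trial set; the package computes standard VIFs but asserts
  no equality to those values.
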