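# Methods

## Estimands and notation

For a binary exposure X, outcome Y and baseline covariates C we distinguish
four log-scale estimands per outcome type: the marginal associational effect
(β for odds, ψ for hazards, estimated by an unadjusted fit), the marginal
*causal* effect (φ, κ — what an infinitely large randomized trial's
unadjusted analysis would estimate), and the covariate-conditional effect
(ν = ζ for odds, λ = ω for hazards, the coefficient of an adjusted fit).
Under randomization β = φ and ψ = κ; under conditional exchangeability given
C the adjusted coefficients estimate ζ and ω. Noncollapsibility means
|φ| < |ζ| (and |κ| < |ω|) whenever both the exposure and the covariates
affect the outcome, with equality when either association is null.

The package's purpose is the *adjusted-marginal* cell of the 2×2 of
{unadjusted, adjusted} × {marginal, conditional}: estimators that use C (for
efficiency in trials, for confounding control in observational data) while
still targeting the marginal estimand.

## Collapsibility diagnostics (`ccf`)

For a link f and conditional effect ν, the characteristic collapsibility
function g_ν(p) = f⁻¹(f(p) + ν) maps the untreated to the treated outcome
probability at a covariate value. Averaging over C and applying g_ν commute
exactly when g_ν is affine (identity, log and complementary-log links);
otherwise Jensen's inequality attenuates (concave case, ν > 0) or inflates
(convex case) the marginal effect. `classify_ccf` classifies by the sign of
numerical second differences on a 512-point grid in (0.001, 0.999) with
absolute tolerance 1e-8 — robust, cheap, and testable; the affine-CCF links
are short-circuited analytically.

Rates from discrete-time survival models condition on past survival, so even
identity/log rate links yield nonlinear risk-scale CCFs from the second
interval onward. `rate_ccf_eval` computes the implied map; the baseline
per-interval rates are a required input (defaulting to a constant rate
calibrated so total untreated risk is 0.5, a choice made for plotting
convenience only — the qualitative shape, not the curve, is the point).
As the number of intervals grows, the log-rate-link model's cumulative risks
converge to the complementary-log-log CCF (the proportional-hazards limit);
the test suite checks this limit numerically rather than reproducing any
particular figure.

`marginal_effect_by_integration` is the package's internal oracle: adaptive
quadrature (absolute tolerance 1e-10, unbounded covariate supports truncated
at ±8 sd) of the conditional risk over the covariate law, contrasted on the
link scale. The standardization estimators are required (in tests) to agree
with it to 1e-6 on dense-grid covariate distributions.

## Synthetic data (`datagen`)

The generators implement eight mechanisms, four per outcome type: a single
covariate C ~ N(0,1) drawn once per (n, seed) and cached so every
replication of a study shares it; exposure Bernoulli(0.5) (randomized) or
Bernoulli(expit(C)) (observational, making C a confounder); binary outcomes
from logit Pr(Y=1|X,C) = 1 + νX + γC; event times from a conditional
proportional-hazards model with Weibull cumulative baseline hazard
H₀(t) = 0.1·t^1.5. The Weibull is parameterized in PH form — the cumulative
hazard, not the R `rweibull` scale convention — so that λ and ρ are exactly
conditional log hazard ratios; this choice reproduces the reference
attenuation (marginal ≈ 0.66 for conditional 1.0) and is verified by the
acceptance suite. Subjects enter uniformly over a 2-year recruitment window
and are administratively censored 10 years after recruitment start; analysis
time is time-on-study, so entry only sets the censoring time (8–10 years)
and there is no left truncation. The named scenarios set (effect, covariate)
coefficients to (0,1), (1,0), (1,1), and (1,1) with confounded exposure
("(1,1)*").

What the generator does *not* emulate: covariate-dependent or informative
censoring, non-proportional conditional hazards, multiple/mixed covariates,
treatment-covariate interactions. Passing tests therefore demonstrate
correctness of the estimators under a correctly specified conditional model
with independent censoring — not robustness to misspecification.

## Model fitting (`survival`)

Logistic fits use statsmodels (GLM/Binomial; frequency weights for IPTW),
Cox fits use lifelines with Efron tie handling by default (Breslow by flag).
Degenerate inputs raise informative errors: single-class outcomes, constant
exposure, no events, (quasi-)separation (detected by runaway coefficients,
naming the worst column), and non-convergent partial likelihoods.

The Breslow cumulative baseline hazard is computed directly from the fitted
coefficients: jumps d_k / Σ_{risk set} exp(lp_i) at each distinct event time.
With Efron-estimated coefficients this is the usual pairing; the
marginalization grid is tie-free by construction (below), where the two tie
conventions coincide.

One engine special case: the Cox model with a single binary covariate and no
weights (the final marginalization fit on 2m heavily tied records, and the
unadjusted comparator) is solved by a grouped Efron partial-likelihood
scalar Newton iteration (`_fastcox`), which depends on the data only through
per-event-time counts by arm. It equals the lifelines solution to solver
tolerance (asserted in tests, including heavily tied data) and makes
replication studies roughly two orders of magnitude cheaper at that step.

`standardized_survival` averages each subject's model-implied survival curve
exp(−Ĥ₀(t)e^{λ̂x+ρ̂ᵀCᵢ}) over the empirical covariate distribution, or over
user-supplied nonnegative weights to marginalize toward a reference
population (the same weights are accepted by the odds-ratio standardization
and the hazard-ratio marginalization).

## Marginal odds ratio (`odds`)

Standardized risks at x = 1, 0 are contrasted on the log-odds scale. A
standardized risk of exactly 0 or 1 raises rather than being clipped:
silently clipping would bias bootstrap intervals, whereas raising lets the
bootstrap drop and count the degenerate replicate.

## Marginal hazard ratio (`hazard`)

The full procedure: (−1) conditional Cox fit; (0) standardized survival
curves per arm evaluated on the grid of observed *event* times (censoring
times excluded) restricted to the chosen time frame; (1–3) m subjects per
arm drawn from the discrete distribution the curve induces on the grid, with
survivors of the whole grid censored at its end; (4′–10′) the same
construction applied to the censoring process — event indicator flipped,
censoring-time grid, standardized "censoring survival" curves — and each
subject censored at the earlier of its event and censoring draws, an event
counted only if strictly earlier *and* itself not a grid-end censoring;
(5–6) one Cox fit of the 2m stacked records on the simulated exposure.

Numerical and design choices:

- **Sampling.** The literal interval-wise Bernoulli chain and a single
  inverse-transform uniform draw define the identical discrete law; the
  inverse transform is the default (O(m log k) instead of O(mk)), the chain
  is retained and the two are checked against each other distributionally.
- **Ties.** Tied grid times are perturbed by a seeded uniform jitter of
  1e-9 × (smallest positive gap), with a machine-precision `nextafter`
  fallback for exact duplicates created by bootstrap resampling. Ties among
  the *simulated* records at shared grid times are intentional and handled
  by the Efron method; simulated data are never jittered.
- **Time frame.** Defaults to the maximum observed time; shorter frames drop
  later grid times and censor survivors at the truncated end (changing the
  estimand accordingly — a marginal HR is defined relative to a trial
  length). Longer frames are refused: the data cannot support extrapolation.
- **Censoring modes.** `mimic` (default) models censoring on exposure and
  covariates; `none` censors only at the grid end; `admin_only` uses an
  intercept-only (Nelson–Aalen) censoring model — a covariate- and
  arm-independent censoring law that coincides with `mimic` under purely
  administrative censoring, which is the package's operational definition of
  that mode; `external_curves` takes user-supplied per-arm censoring curves
  for marginalizing toward another study's censoring pattern.
- **Choice of m.** Monte-Carlo error scales as 1/√m on top of sampling
  error; `choose_m` doubles m until two runs with different seeds agree
  within a tolerance (default 0.005). The replication studies in this
  repository use m = 5000 per arm (2m = 10000), where the residual
  simulation noise is small relative to sampling noise at n = 1000.
- **Seeds.** The jitter, event-arm and censoring-arm streams are independent
  substreams spawned from the single configuration seed.

## IPTW (`iptw`)

Plain (unstabilized) inverse-probability weights 1/p̂ and 1/(1−p̂) from a
logistic exposure model, applied to the otherwise unadjusted fit; stabilized
weights by flag. No truncation by default — the mechanisms here produce
moderate weights — but a configurable normalized-weight cap triggers a
warning with counts. IPTW targets the same marginal estimand as the
standardization estimators; in randomized scenarios the two have
indistinguishable efficiency, while under confounding standardization is
more efficient (both facts are exercised by the replication tests).

## Bootstrap (`inference`)

Subjects (rows) are resampled with replacement — optionally within exposure
arms — and the *entire* estimation procedure re-runs per replicate, including
both conditional Cox fits and a fresh simulation substream for the
marginalized HR. Per-replicate seeds are spawned deterministically from the
master seed, so parallel (joblib) and serial execution give identical
results. SE is the replicate standard deviation; the CI is the 2.5/97.5
percentile interval. Failed replicates (e.g. separation in a resample) are
dropped and counted, with a warning above 5% and an error at 100%.

## Simulation harness (`simstudy`)

`run_scenario` fixes the covariate vector per (n, base_seed), drives each
replication from substream [base_seed, 1, rep], applies any subset of the
four methods to the same datasets (so between-method comparisons are
paired), logs per-replication failures as NaN, and can checkpoint/resume via
an append-only CSV. Reported Monte-Carlo errors use empSE/√n_sim for means
and empSE/√(2(n_sim−1)) for empirical SEs.

Problem sizes used by the packaged validation runs: binary scenarios at 1000
replications of n = 1000; survival scenarios at 200 replications with
2m = 10000 (tolerances widened by √5 accordingly). Because each study
conditions on one realized covariate vector, across-study agreement is
statistical (within Monte-Carlo error), never digit-for-digit.

## Known limitations

- A single marginal hazard ratio summarizes a generally time-varying
  marginal contrast; the cloglog survival plot (`plots.plot_cloglog_survival`)
  should be inspected for gross non-parallelism, and the estimand depends on
  the chosen time frame and censoring pattern.
- Correct specification of the conditional (and, for `mimic`, censoring)
  Cox model is assumed; no doubly robust protection, no machine-learning
  conditional fits, no stratified or time-varying Cox extensions.
- Delta-method standard errors are not provided (the bootstrap is preferred);
  BCa intervals are not implemented.
- Competing risks are out of scope; composite endpoints must be formed
  upstream.
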