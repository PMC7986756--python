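# marginalize

Covariate-adjusted estimation of **marginal** odds ratios and hazard ratios —
for noncollapsible effect measures, *adjusted* and *conditional* are not the
same thing.

## The problem

Odds ratios and hazard ratios are noncollapsible: even in a perfectly
randomized trial with no confounding, adding a prognostic baseline covariate
C to a logistic or Cox model changes the treatment coefficient, because the
covariate-conditional estimand (ν or λ) is a different quantity from the
marginal one (φ or κ), with |marginal| ≤ |conditional|. Comparing an adjusted
coefficient from one study with an unadjusted one from another — or reading
the usual "adjustment costs precision" advice — silently compares apples with
oranges.

The way out is to adjust for covariates *and* target the marginal estimand:

- **Binary outcomes** (standardization / g-computation): fit
  `logit Pr(Y=1|X,C) = μ + νX + γᵀC`, average predicted risks over the
  empirical covariate distribution at X=1 and X=0,

  P̂ₓ = (1/n) Σᵢ expit(μ̂ + ν̂x + γ̂ᵀCᵢ),

  and report φ̂ = logit(P̂₁) − logit(P̂₀).

- **Right-censored survival outcomes** (this package's main contribution):
  fit a conditional Cox model `h(t|X,C) = h₀(t) exp(λX + ρᵀC)`, form the
  standardized survival curves

  Ŝₓ(t) = (1/n) Σᵢ exp{ −Ĥ₀(t) e^{λ̂x + ρ̂ᵀCᵢ} }   (Breslow baseline Ĥ₀),

  simulate m ≫ n subjects per arm from each curve on the grid of observed
  event times, mimic the study's censoring process the same way with the
  event indicator flipped, overlay the two, and fit a plain Cox model to the
  2m simulated records. Its coefficient κ̂ estimates the marginal causal log
  hazard ratio of a randomized trial with the same time frame and censoring.

Unadjusted, IPTW and conditional estimators are provided as comparators,
inference is by nonparametric bootstrap of the entire procedure, and
characteristic collapsibility functions g_ν(p) = f⁻¹(f(p)+ν) diagnose which
link functions collapse (identity, log) and which do not (logit, probit,
cloglog).

## Worked example

Estimators follow the scikit-learn convention (`fit(X, y)`, fitted
attributes with trailing underscores). Simulate a randomized trial with a
conditional log hazard ratio of 1 and a standard-normal prognostic covariate,
then compare three analyses:

```python
from marginalize import ScenarioSpec, simulate
from marginalize.estimators import (
    UnadjustedLogHR, ConditionalLogHR, SimulatedMarginalLogHR,
)

spec = ScenarioSpec.from_label("tte", "(1,1)", n=1000, seed=7)
df = simulate(spec).to_frame()
X, y = df[["exposure", "c1"]], df[["time", "event"]]

for est in (UnadjustedLogHR(), ConditionalLogHR(),
            SimulatedMarginalLogHR(m=5000, random_state=1)):
    est.bootstrap_inference(X, y, B=200, seed=1)
    r = est.result_
    print(f"{r.method:>17}: log HR = {r.estimate:6.3f}  "
          f"(bootstrap SE {r.se:.3f}, 95% CI [{r.ci_low:.3f}, {r.ci_high:.3f}])")
```

```
       unadjusted: log HR =  0.700  (bootstrap SE 0.071, 95% CI [0.565, 0.840])
      conditional: log HR =  0.998  (bootstrap SE 0.072, 95% CI [0.890, 1.144])
adjusted_marginal: log HR =  0.712  (bootstrap SE 0.056, 95% CI [0.596, 0.803])
```

Reading these: the conditional coefficient (~1.0) is *not* an estimate of the
same quantity as the unadjusted one (~0.66–0.70 here) — that gap is
noncollapsibility, not bias. The simulation-marginalized estimator targets
the same marginal estimand as the unadjusted analysis but uses the covariate,
and its bootstrap SE (0.056 vs 0.071) shows the efficiency gain covariate
adjustment buys once like is compared with like. In confounded observational
data the same estimator also removes the confounding bias.

A command-line interface mirrors the library:

```bash
marginalize simulate --outcome tte --scenario "(1,1)" --n 1000 --seed 7 --out trial.csv
marginalize marginalize-hr trial.csv --m 5000 -B 200 --seed 1
marginalize table1 --nsim 50 --m 500   # small simulation-study smoke run
```

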