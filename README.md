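# growthsde

Fast Bayesian parameter estimation for **stochastic logistic population
growth**, aimed at microbial growth curves such as the thousands of
time-courses produced by quantitative fitness analysis (QFA) screens of
yeast cultures.

## The problem and the models

Growth of a culture with density `x_t` is classically described by the
logistic ODE `dx/dt = r x (1 - x/K)` with carrying capacity `K`, growth
rate `r` and inoculum density `P = x_0`.  Real cultures fluctuate, so we
work with the **stochastic logistic growth model (SLGM)**,

```
dX_t = r X_t (1 - X_t / K) dt + σ X_t dW_t,        X_0 = P,
```

whose transition density is intractable: exact Bayesian inference needs
slow data-augmentation MCMC.  `growthsde` implements three tractable
diffusion approximations, each giving a *linear-Gaussian state-space
model* whose marginal likelihood a Kalman filter computes exactly:

| model | idea | state scale | measurement error |
|-------|------|-------------|-------------------|
| RRTR  | lognormal diffusion with time-varying fertility (no mean reversion) | log | lognormal |
| LNAM  | linear noise approximation of the log-transformed SLGM | log | lognormal |
| LNAA  | linear noise approximation on the natural density scale | natural | normal |

All three share the structure
`state_t | state_s ~ N(v(t) + φ(s,t) (state_s − v(s)), Ξ(s,t))`
with closed-form `v`, `φ`, `Ξ`, plus an observation equation
`log y ~ N(Y_t, ν²)` (RRTR/LNAM) or `y ~ N(X_t, ν²)` (LNAA).
Priors are broad log-normals on `(log K, log r, log P, log ν⁻², log σ⁻²)`,
with `log σ⁻²` truncated to `[1, ∞)` so intrinsic noise cannot mask the
deterministic signal.  Posteriors are sampled by Metropolis-within-Gibbs
with burn-in-only proposal tuning; an arbitrarily exact single-site
data-augmentation sampler for the SLGM itself (SLGM+L / SLGM+N, 15
imputed states per observation interval) serves as the gold standard.

## Worked example

Simulate a synthetic SLGM culture with normal measurement error and fit
the LNAA state-space model:

```python
from growthsde import (EMConfig, GrowthParams, McmcConfig, PriorHyper,
                       make_synthetic_dataset, mwg_sample, posterior_summary)

truth = GrowthParams(K=0.15, r=3.0, P=1e-4, nu=0.005, sigma=0.01)
ds = make_synthetic_dataset(truth, "normal", EMConfig(seed=11))
hyper = PriorHyper.default_for(ds.timecourse)
chain = mwg_sample("lnaa", ds.timecourse, hyper, McmcConfig.desk(seed=5))
print(posterior_summary(chain))
```

Output (one run):

```
           mean        sd
K      0.151744  0.001895
r      2.721125  0.198336
P      0.000203  0.000093
nu     0.004839  0.000824
sigma  0.033353  0.028334
```

The posterior mean of the carrying capacity sits within one posterior sd
of the generating value 0.15, and the growth rate within two posterior
sds of 3 — the fitted state-space model recovers the fitness phenotypes
(`K`, `r`) of the noisy culture from 27 observations in seconds, roughly
50× faster than the data-augmentation alternative.

The same workflow is available from the shell:

```
growthsde simulate --error normal --n-paths 1 --seed 11 --out culture.csv
growthsde fit --model lnaa --data culture.csv --seed 5 --out fit/
```

plus `growthsde mse-study` (forward-simulation accuracy grid),
`growthsde recover` (parameter-recovery table) and `growthsde total-mse`
(posterior-predictive scoring).

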