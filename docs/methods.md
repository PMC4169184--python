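# Methods

## Models

The latent process is the stochastic logistic growth model (SLGM)
`dX = rX(1 − X/K)dt + σX dW`, `X_0 = P`, with the time origin fixed at
t0 = 0 and the initial state a point mass at `P` (an inferred
parameter).  Its Kolmogorov forward equation has no known solution, so
the package provides three approximations with Gaussian transition
densities.  All three are expressed through a deterministic profile
`v(t)`, a residual decay factor `φ(s,t)` and a step variance `Ξ(s,t)`,
so that `state_t | state_s ~ N(v(t) + φ(s,t)(state_s − v(s)), Ξ(s,t))`.

**RRTR.**  Viewing logistic growth as Malthusian growth with
time-dependent fertility `h(t) = Qr/(e^{rt} + Q)`, `Q = K/P − 1`, and
perturbing the fertility with white noise gives the lognormal diffusion
`dX = h(t)X dt + σX dW`.  On the log scale the increments are Gaussian:
`μ = y_s + log[(1 + Qe^{−rs})/(1 + Qe^{−rt})] − σ²(t−s)/2`,
`Ξ = σ²(t−s)`, i.e. a driftless random walk about the Itô-corrected
logistic log-curve (`φ ≡ 1`).  The variance grows linearly without
bound — the RRTR has no mean reversion, which is exactly where it
underperforms at stationary phase.  Note two repairs relative to the
form this transition is sometimes quoted in: the state enters as
`y_s`, not `log(y_s)` (the state is already a log-density), and the
log-ratio must use the offset `Q` with the *earlier* time in the
numerator — both follow from integrating `h` and are enforced by the
σ = 0 reduction test, under which chained means trace the logistic
solution exactly.

**LNAM.**  Itô-transforming the SLGM with `Y = log X` gives
`dY = (a − be^Y)dt + σdW` with `a = r − σ²/2`, `b = r/K`.  Writing
`Y = v + Z` with `v` the deterministic solution
`v(t) = log[aPe^{at}/(bP(e^{at}−1)+a)]` and linearising `e^Z ≈ 1 + Z`
yields the time-varying Ornstein–Uhlenbeck residual
`dZ = −be^{v}Z dt + σdW`, solved exactly by
`φ(s,t) = e^{−a(t−s)}(1+Qe^{−as})/(1+Qe^{−at})`, `Q = a/(bP) − 1`, and
`Ξ(s,t) = σ²[e^{2at}−e^{2as} + 4Q(e^{at}−e^{as}) + 2aQ²(t−s)]
/ (2a(Q+e^{at})²)`.  The conditional mean is `v(t) + φ z_s`: the
decomposition of the previous state into `v + z` is what the quoted
transition means, and the implementation applies the decay to the
residual only (adding `φ z` to the full previous state would count the
residual twice).  `a > 0` is required for `v` to exist; the σ-prior
truncation guarantees it in posterior sampling, and it is checked
everywhere else.

**LNAA.**  The same expansion applied on the natural scale
(`X = v + Z`, drop `Z²` and `Z dW` terms) gives
`dZ = (a − 2bv)Z dt + σv dW` with `a = r`, so `v` is the logistic
solution itself, `φ(s,t) = e^{a(t−s)}(D(s)/D(t))²` with
`D(t) = bP(e^{at}−1) + a`, and
`Ξ(s,t) = σ²aP²e^{2at}/(2D(t)⁴) · [b²P²(e^{2at}−e^{2as})
+ 4bP(a−bP)(e^{at}−e^{as}) + 2a(t−s)(a−bP)²]`.
These closed forms were derived from the integrating factor
`exp(∫(a−2bv))` and verified against adaptive quadrature (the factored
form fixes the ambiguity between the `e^{at_i}` / `e^{at_{i−1}}`
denominators that arises when the expression is quoted loosely; the
discriminating test is that σ = 0 iterated means reproduce the logistic
curve exactly).

All `e^{at}` terms are evaluated through `e^{−at}` rearrangements, so
coefficients remain finite for `a·t` up to and beyond 700.  Tiny
negative step variances from floating-point cancellation (relative
magnitude ≲ 1e−15) are clamped to zero, with a log warning for anything
larger.

## State-space inference

Measurement error is lognormal for the log-scale models
(`log y ~ N(Y_t, ν²)`) and normal for the LNAA (`y ~ N(X_t, ν²)`),
preserving linear-Gaussian structure.  The marginal likelihood is a
scalar Kalman recursion on the residual `z = state − v`, initialised at
the point mass `z(0) = 0`.  For the log-scale models the reported
likelihood includes the Jacobian `−Σ log y` of the log transform, so
likelihoods are comparable across models on the data scale (this
constant does not affect the MCMC).

Priors: independent normals on `(log K, log r, log P, log ν⁻²,
log σ⁻²)`, the last truncated to `[1, ∞)` (with its normalising
constant).  Default hyper-parameters are broad (precision 0.1, sd ≈ 3.2
on the log scale) and centred on crude data-derived guesses: `log K` at
the log of the largest observation, `log P` at the log of the first
positive observation, `log r` at `log 3` (a typical mid-range rate for
healthy microbial cultures on this time scale), and the noise centres
at `ν₀ = 0.05·max(y)` and `σ₀ = 0.05`.  These choices make the
likelihood dominate for the growth parameters while keeping all scales
proper; every value is overridable.

The sampler is Metropolis-within-Gibbs: per sweep one Gaussian
random-walk proposal per log-parameter in the fixed order (K, r, P, ν,
σ) (randomisable behind a flag), accepted through likelihood + prior.
Proposal scales adapt only during burn-in — every 50 sweeps each scale
is multiplied by 1.4 (acceptance > 0.5) or 0.7 (acceptance < 0.2),
targeting the 0.2–0.5 band — and are frozen afterwards, preserving
ergodicity of the retained chain.  Initial values are drawn from the
prior (retried until the posterior density is finite).  The production
schedule is burn-in 600,000 / thinning 4,000 / 1,000 retained draws;
the desk preset (burn-in 20,000 / thinning 50 / 1,000 retained, used by
the tests and the acceptance script) resolves these 27-point posteriors
indistinguishably in well under a minute.  Convergence is monitored
with the Heidelberger–Welch diagnostic: a Cramér–von-Mises test on the
standardised Brownian bridge of cumulative sums, with the long-run
variance estimated by an AIC-selected Yule–Walker AR fit at frequency
zero, applied to iteratively discarded 10% prefixes, followed by the
half-width test (ε = 0.1).

## Exact inference by data augmentation

For the SLGM itself the latent path is imputed on the union of the
observation times and m = 15 evenly spaced interior points per interval
(m configurable), linked by Euler–Maruyama transition densities — of
the log-transformed process for lognormal error (SLGM+L), of the
natural-scale process for normal error (SLGM+N, with positivity of the
latent path enforced).  Latent updates are single-site random walks —
additive on the log-scale path, multiplicative (log-space steps with
the Hastings `log(x'/x)` correction) on the natural-scale path, since
early-growth states sit orders of magnitude below `K` and a shared
additive scale cannot serve both ends of the curve.  The interior sites
split into two interleaved half-grids whose full conditionals are
independent given the other half, so each half is updated in one
vectorised block.  Growth-parameter updates (K, r, P) are *non-centred*:
the proposal shifts the imputed path together with the deterministic
logistic curve (an additive, volume-preserving shift in log space; a
multiplicative shift with its log-Jacobian on the natural scale).
Without this, the path conditionally pins the growth parameters to
their starting values and the chain cannot traverse the posterior at
desk scale.  The path is initialised at the logistic curve through
crude data-derived guesses (growth rate from the exponential-phase
log-slope, `P` from the half-maximum crossing time — the first
observation is noise-dominated under additive error), the noise scales
from the residual sd; the site proposal scale is tuned during burn-in
like the parameter scales.  The first grid state is tied to `P` and
moves with it.  As m grows the posterior stabilises (checked at m = 1,
5, 15); the noise parameters (σ, ν) still mix more slowly than
(K, r, P), which is the classical weakness of single-site data
augmentation and the reason the Kalman-filter models exist.

## Simulation and synthetic data

Euler–Maruyama stepping uses a fine grid in which every inter-output
interval is split into equal sub-steps no longer than `dt` (default
7/5000, so ~5,000 steps over (0, 7]); output times therefore lie
exactly on the grid.  "Fineness" was fixed once by the weak-convergence
check: halving `dt` moves the t = 7 ensemble mean by less than the
Monte-Carlo standard error at 10⁴ paths.  The SLGM and RRTR are stepped
on the log scale (multiplicative-noise processes stay positive in law;
log-scale stepping preserves that), the LNAM state is a log-density,
and the LNAA is stepped on the natural scale where its Gaussian law
lives.  A natural-scale SLGM stepper with reject-and-resample handling
of negative excursions exists for cross-checks only.  Wiener increments
come from counter-based Philox streams, drawn row-per-path so that path
i is reproducible regardless of ensemble size, and chunked to bound
memory.

The synthetic-data generator emulates the study conditions: one
fine-grid SLGM path per culture, observed at 27 evenly spaced times on
(0, 7] (first at 7/27, last at 7), with lognormal
(`y = exp(N(log X, ν²))`) or normal (`y = N(X, ν²)`) measurement error
layered from an independent stream (the latent path is never
perturbed).  Additive normal error can produce non-positive
observations when the latent density is small relative to ν — a real
property of that error model; log-scale models refuse such data.  What
the generator does *not* emulate: plate/position effects, non-logistic
lag phases, irregular sampling and heteroscedastic camera noise of real
QFA data — passing recovery tests therefore demonstrates correctness of
the samplers under the stated model, not robustness to real-data
artefacts.  The "yeast-like" cultures used for predictive scoring
re-draw non-positive observations (optical densities are positive),
which slightly truncates the error distribution in the early
exponential phase; they are labelled synthetic throughout.

## Forward-accuracy study

The grid study simulates 100 trajectories per cell for the SLGM and
each approximation over `K ∈ (0,1)`, `r ∈ (0,8)`, `P ∈ (0,0.005)`,
`σ ∈ (0,0.6)`, five interior values per range (`b·{1..5}/6`; the open
intervals exclude the degenerate endpoints), 27 output times on (0,7].
The per-cell score is the squared difference between the
approximation's pointwise ensemble mean (and separately sd) and the
SLGM's, **summed over the 27 output times**; cell scores are averaged
over the 625 cells.  Each (model, cell) pair draws from its own
counter-based stream, so results are independent of evaluation order;
models are compared through independent streams (a distributional, not
pathwise, comparison).  Measurement error plays no role in this study.

## Numerical and design notes

* Degenerate inputs: transitions require strictly increasing times;
  Δt → 0 returns the previous state with zero variance; σ = 0 gives
  exactly zero step variance; a non-positive innovation variance in the
  filter (e.g. σ = ν = 0) raises a `KalmanError` with parameter
  context rather than returning a misleading value.
* MCMC proposals that leave a model's domain (e.g. LNAM's `a ≤ 0`) are
  rejected through a −∞ likelihood, never silently clipped.
* Posterior summaries are natural-scale means/sds (ddof = 1) of
  back-transformed draws; predictive ensembles recycle draws when more
  simulations than retained draws are requested.
* The posterior-predictive score of a fitted model against a culture is
  the mean over simulated trajectories of the mean squared deviation at
  the observation times; culture scores are summed into the total.

## Known limitations

* The LNAM/LNAA are small-noise expansions: for large σ (approaching
  the truncation bound) their Gaussian transitions misstate the skewed
  tails of the SLGM.
* The LNAA can assign mass to negative densities; it is a good
  description only when `v(t)` is large relative to the residual sd.
* Lognormal-error models cannot ingest non-positive observations, so
  they cannot be fitted to raw additive-error data with near-zero
  signal.
* Single-site data augmentation mixes slowly in (σ, ν); its desk-scale
  posteriors for those parameters are diffuse even when (K, r, P) are
  sharply resolved.
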