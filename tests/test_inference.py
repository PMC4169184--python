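"""Kalman marginal likelihood, priors, MWG sampler and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from growthsde import (
    EMConfig,
    GrowthParams,
    McmcChain,
    McmcConfig,
    PriorHyper,
    filter_inputs,
    heidelberger_welch,
    kalman_loglik,
    log_prior,
    logistic_solution,
    mwg_sample,
    posterior_predictive,
    posterior_summary,
)
from growthsde.growth_models import LOG_PARAM_NAMES
from growthsde.inference import metropolis_accept
from growthsde.timecourse import TimeCourse


def _dense_loglik(model, params, data, data_scale=True):
    """Brute-force joint-Gaussian likelihood by composing step conditionals."""
    v, phi, xi = filter_inputs(model, params, data.times)
    n = v.size
    # Cov(z_i, z_j) = prod(phi_{j+1..i}) Var(z_j), built by the recursion
    var = np.empty(n)
    V = 0.0
    for i in range(n):
        V = phi[i] ** 2 * V + xi[i]
        var[i] = V
    C = np.empty((n, n))
    for j in range(n):
        fac = 1.0
        C[j, j] = var[j]
        for i in range(j + 1, n):
            fac *= phi[i]
            C[i, j] = C[j, i] = fac * var[j]
    C = C + params.nu**2 * np.eye(n)
    w = np.log(data.obs) if model in ("rrtr", "lnam") else data.obs
    ll = stats.multivariate_normal.logpdf(w, mean=v, cov=C, allow_singular=True)
    if data_scale and model in ("rrtr", "lnam"):
        ll -= float(np.sum(np.log(data.obs)))
    return float(ll)


def test_kalman_matches_dense_mvn_oracle():
    """Filter likelihood equals the dense joint-Gaussian density (N <= 6)."""
    rng = np.random.default_rng(12)
    models = ("rrtr", "lnam", "lnaa")
    for k in range(100):
        model = models[k % 3]
        p = GrowthParams(
            K=rng.uniform(0.05, 0.5),
            r=rng.uniform(1.0, 6.0),
            P=10 ** rng.uniform(-5, -3),
            sigma=rng.uniform(0.005, 0.15),
            nu=rng.uniform(0.002, 0.05),
        )
        n = rng.integers(2, 7)
        times = np.sort(rng.uniform(0.2, 7.0, n))
        while np.any(np.diff(times) < 1e-2):
            times = np.sort(rng.uniform(0.2, 7.0, n))
        base = logistic_solution(times, p)
        y = base * np.exp(rng.normal(0.0, 0.2, n))
        data = TimeCourse(times=times, obs=y)
        assert kalman_loglik(model, p, data) == pytest.approx(
            _dense_loglik(model, p, data), abs=1e-8
        )


class _OnePoint:
    """Minimal stand-in course for the N=1 marginal check."""

    def __init__(self, t, y):
        self.times = np.array([t])
        self.obs = np.array([y])

    def require_positive(self):
        pass


def test_kalman_single_observation_marginal():
    """N=1: the marginal is one Gaussian with mean v(t1) and variance Xi + nu^2."""
    p = GrowthParams(K=0.15, r=3.0, P=1e-4, sigma=0.02, nu=0.01)
    v, phi, xi = filter_inputs("lnaa", p, np.array([0.5]))
    expected = stats.norm.logpdf(2e-3, loc=v[0], scale=math.sqrt(xi[0] + p.nu**2))
    assert kalman_loglik("lnaa", p, _OnePoint(0.5, 2e-3)) == pytest.approx(expected, rel=1e-12)


def test_kalman_uninformative_observation_limit():
    """As nu -> inf the state contributes nothing: independent N(v, nu^2) terms."""
    p = GrowthParams(K=0.15, r=3.0, P=1e-4, sigma=0.02, nu=1e6)
    times = np.linspace(0.5, 7.0, 8)
    y = logistic_solution(times, p)
    data = TimeCourse(times=times, obs=y)
    v, _, _ = filter_inputs("lnaa", p, times)
    iid = float(np.sum(stats.norm.logpdf(y, loc=v, scale=p.nu)))
    assert kalman_loglik("lnaa", p, data) == pytest.approx(iid, rel=1e-6)


def test_kalman_rejects_nonpositive_data_for_log_models():
    p = GrowthParams(K=0.15, r=3.0, P=1e-4, sigma=0.02, nu=0.01)
    data = TimeCourse(times=np.array([1.0, 2.0]), obs=np.array([-1e-3, 0.1]))
    with pytest.raises(ValueError):
        kalman_loglik("rrtr", p, data)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def _hyper():
    return PriorHyper.default_for(None)


def test_prior_truncation_below_bound_is_impossible():
    hyper = _hyper()
    theta = hyper._mu.copy()
    theta[4] = 0.99
    assert log_prior(theta, hyper) == -np.inf
    theta[4] = 1.01
    assert np.isfinite(log_prior(theta, hyper))


def test_prior_normal_kernel_symmetry():
    """Density ratio mode vs one-sd-away equals exp(1/2) for an untruncated component."""
    hyper = _hyper()
    at_mode = hyper._mu.copy()
    at_mode[4] = max(at_mode[4], hyper.sigma_trunc_low + 1.0)
    off = at_mode.copy()
    off[0] += 1.0 / math.sqrt(hyper.tau_K)
    assert log_prior(at_mode, hyper) - log_prior(off, hyper) == pytest.approx(0.5, rel=1e-12)


def test_truncated_normal_constant_matches_quadrature():
    hyper = _hyper()
    sd = 1.0 / math.sqrt(hyper.tau_sigma)
    Z, _ = quad(
        lambda x: stats.norm.pdf(x, loc=hyper.mu_sigma, scale=sd), hyper.sigma_trunc_low, np.inf
    )
    assert math.exp(hyper._trunc_logZ) == pytest.approx(Z, abs=1e-8)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def test_mwg_null_sampler_is_constant():
    """Zero proposal scales leave the chain at its initial value."""
    hyper = _hyper()
    cfg = McmcConfig(n_burn=50, thin=1, n_keep=20, scales=np.zeros(5), seed=0)
    chain = mwg_sample(None, None, hyper, cfg)
    assert np.all(chain.draws == chain.draws[0])
    assert np.all(np.isnan(chain.acceptance))


def test_prior_only_sampling_recovers_prior_moments():
    """With the likelihood off, the sampler reproduces the prior marginals."""
    hyper = _hyper()
    cfg = McmcConfig(n_burn=3000, thin=10, n_keep=2000, seed=21)
    chain = mwg_sample(None, None, hyper, cfg)
    target = hyper.marginal_moments()
    for j, name in enumerate(LOG_PARAM_NAMES):
        mu, sd = target.loc[name, "mean"], target.loc[name, "sd"]
        assert abs(chain.draws[:, j].mean() - mu) < 0.35 * sd
        assert chain.draws[:, j].std(ddof=1) == pytest.approx(sd, rel=0.2)
    # truncation never violated in retained draws
    assert np.all(chain.draws[:, 4] >= hyper.sigma_trunc_low)


def test_metropolis_kernel_targets_1d_gaussian():
    """Detailed-balance smoke test of the shared acceptance rule on N(0,1)."""
    rng = np.random.default_rng(3)
    x = 0.0
    draws = np.empty(40_000)
    for i in range(draws.size):
        prop = x + 2.4 * rng.standard_normal()
        if metropolis_accept(rng, 0.5 * (x * x - prop * prop)):
            x = prop
        draws[i] = x
    keep = draws[2000:]
    assert abs(keep.mean()) < 0.05
    assert keep.var(ddof=1) == pytest.approx(1.0, rel=0.08)


def test_lnaa_recovers_carrying_capacity(lnaa_chain_set1):
    """LNAA fitted to normal-error synthetic data recovers K near 0.15."""
    summ = posterior_summary(lnaa_chain_set1)
    assert abs(summ.loc["K", "mean"] - 0.15) <= 3.0 * summ.loc["K", "sd"]
    # truncation respected in every retained draw
    assert np.all(lnaa_chain_set1.draws[:, 4] >= 1.0)


# ---------------------------------------------------------------------------
# summaries and posterior predictive
# ---------------------------------------------------------------------------


def _chain_from_natural(K, r, P, nu, sigma):
    th = np.column_stack(
        [np.log(K), np.log(r), np.log(P), -2.0 * np.log(nu), -2.0 * np.log(sigma)]
    )
    return McmcChain(
        draws=th, names=LOG_PARAM_NAMES, acceptance=np.full(5, np.nan),
        scales=np.full(5, 0.1), model="lnaa", seed=0,
    )


def test_posterior_summary_hand_arithmetic():
    ones = np.ones(2)
    chain = _chain_from_natural(np.array([0.1, 0.2]), 3 * ones, 1e-4 * ones, 0.01 * ones, 0.01 * ones)
    summ = posterior_summary(chain)
    assert summ.loc["K", "mean"] == pytest.approx(0.15)
    assert summ.loc["K", "sd"] == pytest.approx(0.0707, abs=2e-4)
    assert summ.loc["r", "sd"] == 0.0


def test_posterior_summary_matches_streaming_oracle():
    rng = np.random.default_rng(5)
    n = 100_000
    chain = _chain_from_natural(
        rng.lognormal(-2, 0.1, n), rng.lognormal(1, 0.1, n), rng.lognormal(-9, 0.1, n),
        rng.lognormal(-5, 0.1, n), rng.lognormal(-4, 0.1, n),
    )
    summ = posterior_summary(chain)
    nat = chain.natural()
    for name in ("K", "r", "P", "nu", "sigma"):
        # Welford streaming moments as the independent second route
        mean = 0.0
        m2 = 0.0
        for i, x in enumerate(nat[name].to_numpy(), start=1):
            d = x - mean
            mean += d / i
            m2 += d * (x - mean)
        assert summ.loc[name, "mean"] == pytest.approx(mean, rel=1e-10)
        assert summ.loc[name, "sd"] == pytest.approx(math.sqrt(m2 / (n - 1)), rel=1e-10)


def test_posterior_predictive_deterministic_draw():
    """A single sigma=0, nu=0 draw yields the deterministic logistic curve."""
    chain = _chain_from_natural(
        np.array([0.15]), np.array([3.0]), np.array([1e-4]), np.array([1e-12]), np.array([1e-12])
    )
    cfg = EMConfig(seed=0)
    ens = posterior_predictive("lnaa", chain, cfg, n_sims=5)
    ref = logistic_solution(cfg.t_grid, GrowthParams(K=0.15, r=3.0, P=1e-4))
    # residual spread only from the vanishing sigma=1e-12 noise floor
    assert np.allclose(ens.paths, ens.paths[0], atol=1e-8)
    # agreement with the exact curve is Euler-limited: natural-scale stepping
    # of exponential growth carries O(r^2 t dt / 2) ~ 1% relative error
    np.testing.assert_allclose(ens.mean, ref, rtol=2e-2)


def test_posterior_predictive_self_consistency(lnaa_chain_set1, normal_set1):
    """Predictive mean tracks the true latent mean curve of the generating SLGM.

    The discrepancy budget is the pointwise predictive spread (posterior
    parameter uncertainty plus intrinsic and measurement noise), since
    the posterior mean differs from the generating truth by a draw of
    that posterior uncertainty.
    """
    cfg = EMConfig(seed=13)
    ens = posterior_predictive("lnaa", lnaa_chain_set1, cfg, n_sims=500)
    truth_mean = logistic_solution(cfg.t_grid, normal_set1.true_params)
    spread = ens.paths.std(axis=0, ddof=1)
    assert np.all(np.abs(ens.mean - truth_mean) < 3.0 * spread + 5e-4)


# ---------------------------------------------------------------------------
# Heidelberger-Welch
# ---------------------------------------------------------------------------


def test_heidelberger_welch_calibrated_under_null():
    """An i.i.d. Gaussian chain passes stationarity in >= 90% of replicates."""
    passed = 0
    for seed in range(20):
        x = np.random.default_rng(seed).standard_normal(10_000)
        if heidelberger_welch(x).stationary:
            passed += 1
    assert passed >= 18


def test_heidelberger_welch_detects_trend():
    x = np.random.default_rng(1).standard_normal(10_000) + np.linspace(0.0, 5.0, 10_000)
    res = heidelberger_welch(x)
    assert not res.stationary


def test_heidelberger_welch_constant_chain_flagged():
    res = heidelberger_welch(np.zeros(500))
    assert res.degenerate and not res.stationary


def test_heidelberger_welch_rejects_short_chain():
    with pytest.raises(ValueError):
        heidelberger_welch(np.arange(10.0))
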