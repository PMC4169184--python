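"""Bayesian inference for the approximating diffusions.

The three approximations are linear-Gaussian state-space models:

    RRTR / LNAM :  log(y_ti) ~ N(Y_ti, nu^2)   (lognormal measurement error)
    LNAA        :      y_ti  ~ N(X_ti, nu^2)   (normal measurement error)

with the latent state propagated by the Gaussian step moments of
:mod:`growthsde.growth_models`.  The marginal likelihood of a
time-course is computed exactly by a scalar Kalman filter on the
residual z = state - v, so no latent path ever needs to be imputed.
Posterior sampling is Metropolis-within-Gibbs: one Gaussian
random-walk update per log-scale parameter per sweep, each accepted
through the Kalman marginal likelihood plus the log-scale priors, with
proposal scales adapted only during burn-in.

Priors (on the log scale): independent normals on log K, log r, log P,
log nu^-2 and log sigma^-2, the last truncated to [sigma_trunc_low,
inf) to keep intrinsic noise from masking the deterministic signal —
the linear noise approximation assumes small intrinsic noise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .growth_models import (
    LOG_PARAM_NAMES,
    GrowthParams,
    InvalidParameterError,
    filter_inputs,
)
from .simulate import EMConfig, Ensemble, em_paths
from .timecourse import TimeCourse

__all__ = [
    "PriorHyper",
    "McmcConfig",
    "McmcChain",
    "KalmanError",
    "kalman_loglik",
    "log_prior",
    "mwg_sample",
    "posterior_summary",
    "posterior_predictive",
    "heidelberger_welch",
    "HeidelbergerWelch",
    "metropolis_accept",
]

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

#: parameter update order within one Gibbs sweep (theta indices):
#: K, r, P, nu, sigma
_SWEEP_ORDER = (0, 1, 2, 3, 4)


class KalmanError(RuntimeError):
    """Raised when the filter recursion produces a degenerate variance."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass
class PriorHyper:
    """Normal mean/precision pairs for the log-scale parameters.

    ``(mu_x, tau_x)`` parameterise ``log x ~ N(mu_x, 1/tau_x)`` for
    K, r and P, and ``log x^-2 ~ N(mu_x, 1/tau_x)`` for the noise
    scales nu and sigma; ``log sigma^-2`` is additionally truncated to
    ``[sigma_trunc_low, inf)``.
    """

    mu_K: float
    tau_K: float
    mu_r: float
    tau_r: float
    mu_P: float
    tau_P: float
    mu_nu: float
    tau_nu: float
    mu_sigma: float
    tau_sigma: float
    sigma_trunc_low: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_K", "tau_r", "tau_P", "tau_nu", "tau_sigma"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.sigma_trunc_low):
            raise ValueError("sigma_trunc_low must be finite")
        # theta order: log K, log r, log P, log nu^-2, log sigma^-2
        self._mu = np.array([self.mu_K, self.mu_r, self.mu_P, self.mu_nu, self.mu_sigma])
        self._tau = np.array([self.tau_K, self.tau_r, self.tau_P, self.tau_nu, self.tau_sigma])
        sd_sigma = 1.0 / math.sqrt(self.tau_sigma)
        # log of the truncated-normal normalising constant P(log sigma^-2 >= low)
        self._trunc_logZ = float(
            stats.norm.logsf(self.sigma_trunc_low, loc=self.mu_sigma, scale=sd_sigma)
        )

    @classmethod
    def default_for(cls, data: Optional[TimeCourse] = None, precision: float = 0.1) -> "PriorHyper":
        """Broad priors centred on crude data-derived guesses.

        log K is centred at the log of the largest observation, log P at
        the log of the first positive observation and log r at log 3;
        the noise centres correspond to nu0 = 0.05 * max(y) and
        sigma0 = 0.05.  With the default precision 0.1 every prior sd
        is ~3.2 on the log scale, i.e. relatively uninformative.
        """
        if data is not None:
            pos = data.obs[data.obs > 0.0]
            if pos.size == 0:
                raise ValueError("cannot centre priors: no positive observations")
            k0 = float(pos.max())
            p0 = float(pos[0])
            nu0 = max(0.05 * k0, 1e-8)
        else:
            k0, p0, nu0 = 0.1, 1e-4, 0.005
        return cls(
            mu_K=math.log(k0),
            tau_K=precision,
            mu_r=math.log(3.0),
            tau_r=precision,
            mu_P=math.log(p0),
            tau_P=precision,
            mu_nu=math.log(nu0**-2),
            tau_nu=precision,
            mu_sigma=math.log(0.05**-2),
            tau_sigma=precision,
        )

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        """One draw of the five log-scale parameters from the prior."""
        sd = 1.0 / np.sqrt(self._tau)
        theta = self._mu + sd * rng.standard_normal(5)
        a = (self.sigma_trunc_low - self.mu_sigma) * math.sqrt(self.tau_sigma)
        theta[4] = stats.truncnorm.rvs(
            a, np.inf, loc=self.mu_sigma, scale=sd[4], random_state=rng
        )
        return theta

    def marginal_moments(self) -> pd.DataFrame:
        """Prior means and sds of the five log-scale parameters."""
        mean = self._mu.copy()
        sd = 1.0 / np.sqrt(self._tau)
        a = (self.sigma_trunc_low - self.mu_sigma) * math.sqrt(self.tau_sigma)
        m, v = stats.truncnorm.stats(a, np.inf, loc=self.mu_sigma, scale=sd[4], moments="mv")
        mean[4], sd_arr = float(m), sd.copy()
        sd_arr[4] = math.sqrt(float(v))
        return pd.DataFrame({"mean": mean, "sd": sd_arr}, index=list(LOG_PARAM_NAMES))


def _log_prior_theta(theta: np.ndarray, hyper: PriorHyper) -> float:
    if theta[4] < hyper.sigma_trunc_low:
        return -math.inf
    d = theta - hyper._mu
    lp = float(np.sum(0.5 * np.log(hyper._tau / (2.0 * math.pi)) - 0.5 * hyper._tau * d * d))
    return lp - hyper._trunc_logZ


def log_prior(params, hyper: PriorHyper) -> float:
    """Joint log prior density; accepts GrowthParams or a theta vector.

    Returns -inf when ``log sigma^-2`` falls below the truncation bound;
    the truncated component includes its normalising constant.
    """
    theta = params.to_log() if isinstance(params, GrowthParams) else np.asarray(params, float)
    return _log_prior_theta(theta, hyper)


# ---------------------------------------------------------------------------
# Kalman marginal likelihood
# ---------------------------------------------------------------------------


def kalman_loglik(
    model: str, params: GrowthParams, data: TimeCourse, data_scale: bool = True
) -> float:
    """Exact log marginal likelihood of a time-course.

    Runs the scalar Kalman recursion on the residual z (initially the
    point mass 0 at t0 = 0): predict ``m' = phi m``, ``V' = phi^2 V + Xi``;
    the observation is ``v + z + N(0, nu^2)`` on the model's scale (log
    density for RRTR/LNAM, density for LNAA).  For the log-scale models
    ``data_scale=True`` (default) adds the Jacobian of the log
    transform, ``-sum(log y)``, so that likelihoods are comparable
    across models on the scale of the data.
    """
    model = model.lower()
    y = data.obs
    if model in ("rrtr", "lnam"):
        data.require_positive()
        w = np.log(y)
        jac = -float(np.sum(w)) if data_scale else 0.0
    elif model == "lnaa":
        w = y
        jac = 0.0
    else:
        raise InvalidParameterError(f"unknown state-space model {model!r}")

    v, phi, xi = filter_inputs(model, params, data.times)
    obs_var = params.nu**2

    m = 0.0
    V = 0.0
    ll = 0.0
    vl, pl, xl, wl = v.tolist(), phi.tolist(), xi.tolist(), w.tolist()
    for i in range(len(wl)):
        f = pl[i]
        m = f * m
        V = f * f * V + xl[i]
        F = V + obs_var
        if not (F > 0.0) or not math.isfinite(F):
            raise KalmanError(
                f"degenerate innovation variance F={F!r} at step {i} "
                f"(model={model}, params={params})"
            )
        e = wl[i] - vl[i] - m
        ll += -0.5 * (_LOG2PI + math.log(F) + e * e / F)
        G = V / F
        m += G * e
        V -= G * V
    if not math.isfinite(ll):
        raise KalmanError(f"non-finite log-likelihood (model={model}, params={params})")
    return ll + jac


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    """Sampler schedule and tuning settings.

    The defaults are the long production schedule (burn-in 600,000,
    thinning 4,000, 1,000 retained draws); :meth:`desk` gives a
    desk-scale preset (burn-in 20,000, thinning 50) that resolves these
    27-point posteriors well in well under a minute.
    """

    n_burn: int = 600_000
    thin: int = 4_000
    n_keep: int = 1_000
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]
    tune_interval: int = 50
    target_low: float = 0.2
    target_high: float = 0.5
    seed: int = 0
    randomize_order: bool = False

    def __post_init__(self) -> None:
        if self.scales is None:
            self.scales = np.full(5, 0.1)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.shape != (5,) or np.any(self.scales < 0.0):
            raise ValueError("scales must be 5 non-negative proposal sds")
        if self.n_burn < 0 or self.thin < 1 or self.n_keep < 1:
            raise ValueError("invalid sampler schedule")
        if not 0.0 <= self.target_low < self.target_high <= 1.0:
            raise ValueError("invalid target acceptance band")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "McmcConfig":
        kw.setdefault("n_burn", 20_000)
        kw.setdefault("thin", 50)
        kw.setdefault("n_keep", 1_000)
        return cls(seed=seed, **kw)


@dataclass
class McmcChain:
    """Retained posterior draws of the five log-scale parameters."""

    draws: np.ndarray
    names: tuple
    acceptance: np.ndarray
    scales: np.ndarray
    model: str
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.names))

    def natural(self) -> pd.DataFrame:
        """Draws back-transformed to (K, r, P, nu, sigma)."""
        th = self.draws
        return pd.DataFrame(
            {
                "K": np.exp(th[:, 0]),
                "r": np.exp(th[:, 1]),
                "P": np.exp(th[:, 2]),
                "nu": np.exp(-0.5 * th[:, 3]),
                "sigma": np.exp(-0.5 * th[:, 4]),
            }
        )

    def params_at(self, i: int) -> GrowthParams:
        return GrowthParams.from_log(self.draws[i])

    def diagnose(self, alpha: float = 0.05) -> Dict[str, "HeidelbergerWelch"]:
        return {
            name: heidelberger_welch(self.draws[:, j], alpha=alpha)
            for j, name in enumerate(self.names)
        }


def metropolis_accept(rng: np.random.Generator, log_ratio: float) -> bool:
    """Symmetric-proposal Metropolis acceptance decision."""
    if log_ratio >= 0.0:
        return True
    return math.log(rng.uniform()) < log_ratio


def tune_scale(scale: float, rate: float, low: float, high: float) -> float:
    """Nudge a proposal sd toward the target acceptance band."""
    if rate < low:
        scale *= 0.7
    elif rate > high:
        scale *= 1.4
    return float(np.clip(scale, 1e-8, 50.0))


def mwg_sample(
    model: Optional[str],
    data: Optional[TimeCourse],
    hyper: PriorHyper,
    config: McmcConfig,
) -> McmcChain:
    """Metropolis-within-Gibbs posterior sampling via the Kalman filter.

    Each sweep updates the five log-scale parameters in turn (K, r, P,
    nu, sigma) with Gaussian random-walk proposals, accepted through
    the Kalman marginal likelihood plus prior.  Proposal scales adapt
    toward the target acceptance band only during burn-in and are
    frozen afterwards, preserving ergodicity.  ``data=None`` switches
    the likelihood off and samples the prior (used for validation).
    """
    rng = np.random.default_rng(config.seed)
    prior_only = data is None
    if not prior_only:
        model = model.lower()  # type: ignore[union-attr]
        if model in ("rrtr", "lnam"):
            data.require_positive()

    def safe_ll(theta: np.ndarray) -> float:
        if prior_only:
            return 0.0
        try:
            return kalman_loglik(model, GrowthParams.from_log(theta), data)
        except (InvalidParameterError, KalmanError):
            return -math.inf

    # initial values drawn from the prior, retried until the posterior
    # density is finite
    theta = None
    for _ in range(500):
        cand = hyper.sample_theta(rng)
        lp = _log_prior_theta(cand, hyper)
        ll = safe_ll(cand)
        if math.isfinite(lp + ll):
            theta, lp_cur, ll_cur = cand, lp, ll
            break
    if theta is None:
        raise RuntimeError("could not find a finite-posterior initial value from the prior")

    scales = config.scales.copy()
    n_total = config.n_burn + config.n_keep * config.thin
    draws = np.empty((config.n_keep, 5))
    win_prop = np.zeros(5)
    win_acc = np.zeros(5)
    post_prop = np.zeros(5)
    post_acc = np.zeros(5)
    kept = 0

    for it in range(n_total):
        order = rng.permutation(5) if config.randomize_order else _SWEEP_ORDER
        in_burn = it < config.n_burn
        for j in order:
            if scales[j] == 0.0:
                continue
            prop = theta.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_new = _log_prior_theta(prop, hyper)
            if math.isfinite(lp_new):
                ll_new = safe_ll(prop)
                accepted = math.isfinite(ll_new) and metropolis_accept(
                    rng, (ll_new + lp_new) - (ll_cur + lp_cur)
                )
            else:
                accepted = False
            if in_burn:
                win_prop[j] += 1
                win_acc[j] += accepted
            else:
                post_prop[j] += 1
                post_acc[j] += accepted
            if accepted:
                theta, lp_cur, ll_cur = prop, lp_new, ll_new
        if in_burn and (it + 1) % config.tune_interval == 0:
            for j in range(5):
                if win_prop[j] > 0:
                    scales[j] = tune_scale(
                        scales[j], win_acc[j] / win_prop[j], config.target_low, config.target_high
                    )
            win_prop[:] = 0.0
            win_acc[:] = 0.0
        if not in_burn and (it - config.n_burn + 1) % config.thin == 0:
            draws[kept] = theta
            kept += 1

    with np.errstate(invalid="ignore"):
        acc_rate = np.where(post_prop > 0, post_acc / np.maximum(post_prop, 1), np.nan)
    stuck = (post_prop > 0) & (post_acc == 0)
    if np.any(stuck):
        warnings.warn(
            "MCMC chain accepted no post-burn-in proposals for "
            f"{[LOG_PARAM_NAMES[j] for j in np.flatnonzero(stuck)]}; "
            "treat the posterior sample as unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return McmcChain(
        draws=draws[:kept],
        names=LOG_PARAM_NAMES,
        acceptance=acc_rate,
        scales=scales,
        model="prior" if prior_only else model,  # type: ignore[arg-type]
        seed=config.seed,
    )


def posterior_summary(chain: McmcChain) -> pd.DataFrame:
    """Natural-scale posterior means and sds of (K, r, P, nu, sigma)."""
    nat = chain.natural()
    if len(nat) == 0:
        raise ValueError("empty chain")
    return pd.DataFrame({"mean": nat.mean(), "sd": nat.std(ddof=1).fillna(0.0)})


def posterior_predictive(
    model: str,
    chain: McmcChain,
    config: EMConfig,
    error_kind: Optional[str] = None,
    n_sims: Optional[int] = None,
) -> Ensemble:
    """Observed-scale forward ensemble from posterior draws.

    One E-M forward path per retained draw (draws are recycled if
    ``n_sims`` exceeds the chain length), with measurement error of the
    model's kind added at the output times; returned on the observed
    scale for plotting and MSE scoring.
    """
    model = model.lower()
    if error_kind is None:
        if model in ("rrtr", "lnam"):
            error_kind = "lognormal"
        elif model == "lnaa":
            error_kind = "normal"
        else:
            raise ValueError("error_kind is required for SLGM predictive simulation")
    n_draws = chain.draws.shape[0]
    if n_draws == 0:
        raise ValueError("empty chain")
    n = n_sims if n_sims is not None else n_draws
    idx = np.resize(np.arange(n_draws), n)
    th = chain.draws[idx]
    pars = {
        "K": np.exp(th[:, 0]),
        "r": np.exp(th[:, 1]),
        "P": np.exp(th[:, 2]),
        "sigma": np.exp(-0.5 * th[:, 4]),
    }
    nu = np.exp(-0.5 * th[:, 3])
    path_ss, err_ss = np.random.SeedSequence(config.seed).spawn(2)
    states = em_paths(model, pars, config, seed_seq=path_ss, n_paths=n)
    rng = np.random.Generator(np.random.Philox(err_ss))
    if error_kind == "lognormal":
        logx = states if model != "lnaa" else np.log(np.maximum(states, 1e-300))
        y = np.exp(rng.normal(logx, nu[:, None]))
    elif error_kind == "normal":
        x = states if model == "lnaa" else np.exp(states)
        y = rng.normal(x, nu[:, None])
    else:
        raise ValueError(f"unknown error_kind {error_kind!r}")
    return Ensemble.from_paths(config.t_grid, y)


# ---------------------------------------------------------------------------
# Heidelberger-Welch convergence diagnostic
# ---------------------------------------------------------------------------


@dataclass
class HeidelbergerWelch:
    """Stationarity and half-width test results for one parameter chain."""

    stationary: bool
    start_frac: float
    cvm_stat: float
    mean: float
    halfwidth: float
    halfwidth_ok: bool
    degenerate: bool = False


#: asymptotic Cramer-von-Mises critical values (level -> critical value)
_CVM_CRIT = {0.10: 0.347, 0.05: 0.461, 0.025: 0.581, 0.01: 0.743}


def _spectrum0(x: np.ndarray, max_order: int = 10) -> float:
    """Spectral density of a chain at frequency zero via an AR fit.

    Fits AR(p) models by Yule-Walker for p = 0..max_order, selects by
    AIC and returns ``sigma^2 / (1 - sum(ar_coefs))^2``.
    """
    from statsmodels.regression.linear_model import yule_walker

    n = x.size
    xc = x - x.mean()
    var0 = float(np.var(xc))
    if var0 <= 0.0:
        return 0.0
    best = (n * math.log(var0), var0, np.array([]))
    for p in range(1, min(max_order, n // 10) + 1):
        try:
            rho, sig = yule_walker(xc, order=p, method="mle")
        except Exception:  # ill-conditioned fit at high order
            continue
        s2 = float(sig) ** 2
        if s2 <= 0.0:
            continue
        aic = n * math.log(s2) + 2.0 * p
        if aic < best[0]:
            best = (aic, s2, rho)
    _, s2, rho = best
    denom = (1.0 - float(np.sum(rho))) ** 2
    if denom <= 0.0:
        return 0.0
    return s2 / denom


def heidelberger_welch(
    x: np.ndarray, alpha: float = 0.05, eps: float = 0.1
) -> HeidelbergerWelch:
    """Heidelberger-Welch stationarity and half-width diagnostic.

    The stationarity test compares the Cramer-von-Mises statistic of
    the standardised Brownian bridge of cumulative sums (with the
    long-run variance estimated by an AR spectral fit at frequency
    zero) with its asymptotic critical value, discarding 10% prefixes
    iteratively up to half the chain.  The half-width test then checks
    that the 95% interval half-width of the retained mean is below
    ``eps`` times its magnitude.  A (near-)constant chain returns a
    degenerate flag instead of crashing.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("heidelberger_welch needs a chain of length >= 100")
    if float(np.ptp(x)) == 0.0:
        return HeidelbergerWelch(
            stationary=False, start_frac=0.0, cvm_stat=math.nan,
            mean=float(x[0]), halfwidth=0.0, halfwidth_ok=False, degenerate=True,
        )
    crit = _CVM_CRIT.get(round(alpha, 3))
    if crit is None:
        raise ValueError(f"alpha must be one of {sorted(_CVM_CRIT)}")

    stationary = False
    start_frac = 0.5
    cvm = math.nan
    y = x
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n):]
        ny = y.size
        s0 = _spectrum0(y)
        if s0 <= 0.0:
            return HeidelbergerWelch(
                stationary=False, start_frac=frac, cvm_stat=math.nan,
                mean=float(y.mean()), halfwidth=0.0, halfwidth_ok=False, degenerate=True,
            )
        S = np.cumsum(y)
        k = np.arange(1, ny + 1)
        bridge = (S - k * (S[-1] / ny)) / math.sqrt(ny * s0)
        cvm = float(np.mean(bridge**2))
        if cvm < crit:
            stationary = True
            start_frac = frac
            break

    ny = y.size
    s0 = _spectrum0(y)
    mean = float(y.mean())
    halfwidth = 1.96 * math.sqrt(s0 / ny)
    hw_ok = bool(stationary and mean != 0.0 and halfwidth <= eps * abs(mean))
    return HeidelbergerWelch(
        stationary=stationary, start_frac=start_frac, cvm_stat=cvm,
        mean=mean, halfwidth=halfwidth, halfwidth_ok=hw_ok,
    )
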