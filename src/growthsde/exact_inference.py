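"""Arbitrarily exact data-augmentation MCMC for the SLGM.

Inference for the stochastic logistic growth model itself (no
analytically tractable transition density) by imputing the latent path
on a fine grid: each inter-observation interval carries ``m`` evenly
spaced imputed states (default 15), and adjacent grid states are
linked by the Euler-Maruyama transition density of the SLGM — of the
log-transformed process for lognormal measurement error (SLGM+L), of
the natural-scale process for normal error (SLGM+N).  As the
imputation gets finer the posterior converges to that of the exact
diffusion.

The sampler is single-site: parameters and latent grid states are
updated in turn with symmetric Gaussian random-walk proposals.  The
interior sites of the path form two interleaved half-grids whose full
conditionals are mutually independent given the other half, so each
half is proposed and accepted in one vectorised block.  The initial
state is tied to the parameter P (a point mass at t0 = 0) and moves
with it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .growth_models import LOG_PARAM_NAMES
from .inference import (
    McmcChain,
    McmcConfig,
    PriorHyper,
    _log_prior_theta,
    metropolis_accept,
    tune_scale,
)
from .timecourse import TimeCourse

__all__ = ["AugmentedPath", "da_mcmc"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class AugmentedPath:
    """Latent states on the union of observation times and imputed points."""

    times: np.ndarray
    states: np.ndarray
    obs_idx: np.ndarray
    scale: str  # "log" (SLGM+L) or "natural" (SLGM+N)


def _build_grid(times: np.ndarray, m: int) -> tuple:
    """Fine grid: t0=0 plus m evenly spaced interior points per interval."""
    edges = np.concatenate(([0.0], times))
    grid = [0.0]
    obs_idx = []
    for i in range(times.size):
        seg = np.linspace(edges[i], edges[i + 1], m + 2)[1:]
        grid.extend(seg.tolist())
        obs_idx.append(len(grid) - 1)
    return np.array(grid), np.array(obs_idx, dtype=int)


def _unpack(theta: np.ndarray) -> tuple:
    K = math.exp(theta[0])
    r = math.exp(theta[1])
    P = math.exp(theta[2])
    nu = math.exp(-0.5 * theta[3])
    sigma = math.exp(-0.5 * theta[4])
    return K, r, P, nu, sigma


def _edge_loglik(
    left: np.ndarray, right: np.ndarray, dt: np.ndarray, theta: np.ndarray, scale: str
) -> np.ndarray:
    """E-M transition log-densities for all grid edges (vectorised)."""
    K, r, P, nu, sigma = _unpack(theta)
    s2 = sigma * sigma
    if scale == "log":
        mean = left + (r - 0.5 * s2 - (r / K) * np.exp(left)) * dt
        var = s2 * dt
    else:
        mean = left + r * left * (1.0 - left / K) * dt
        var = s2 * left * left * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = -0.5 * (_LOG2PI + np.log(var) + (right - mean) ** 2 / var)
    if scale == "natural":
        ll = np.where(left > 0.0, ll, -np.inf)
    return ll


def _obs_loglik(states_obs: np.ndarray, w: np.ndarray, nu: float) -> np.ndarray:
    v = nu * nu
    return -0.5 * (_LOG2PI + math.log(v) + (w - states_obs) ** 2 / v)


def da_mcmc(
    error_kind: str,
    data: TimeCourse,
    hyper: PriorHyper,
    config: McmcConfig,
    m: int = 15,
) -> McmcChain:
    """Single-site data-augmentation MCMC for the SLGM.

    ``error_kind='lognormal'`` runs the SLGM+L model (latent path on
    the log scale, measurement ``log y ~ N(., nu^2)``);
    ``error_kind='normal'`` runs the SLGM+N model (natural-scale path,
    ``y ~ N(., nu^2)``, positivity of the latent path enforced).
    Returns the chain over the five log-scale parameters with the
    latent path integrated out by sampling.
    """
    error_kind = error_kind.lower()
    if error_kind not in ("lognormal", "normal"):
        raise ValueError(f"error_kind must be 'lognormal' or 'normal', got {error_kind!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    scale = "log" if error_kind == "lognormal" else "natural"
    if scale == "log":
        data.require_positive()
        w = np.log(data.obs)
    else:
        w = data.obs.copy()

    grid, obs_idx = _build_grid(data.times, m)
    dt = np.diff(grid)
    n_sites = grid.size
    rng = np.random.default_rng(config.seed)

    # deterministic initialisation: logistic curve through crude data-derived
    # guesses.  Single-site path updates move the early path very slowly, so
    # the initial curve must be in the right neighbourhood: the growth rate
    # comes from the log-slope of the exponential phase and P from the
    # half-maximum crossing time (the first positive observation is noise-
    # dominated under additive error and is useless as a P guess).
    y = data.obs
    K0 = float(y[y > 0.0].max())
    phase = (y > 0.1 * K0) & (y < 0.8 * K0)
    if int(phase.sum()) >= 2:
        slope = np.polyfit(data.times[phase], np.log(y[phase]), 1)[0]
        r0 = float(np.clip(slope, 0.3, 20.0))
    else:
        r0 = 3.0
    cand = np.flatnonzero(y > 0.0)
    i_half = cand[np.argmin(np.abs(y[cand] - 0.5 * K0))]
    ratio = max(K0 / y[i_half] - 1.0, 1e-6)
    Q0 = ratio * math.exp(r0 * data.times[i_half])
    P0 = float(np.clip(K0 / (1.0 + Q0), 1e-12, K0))
    curve0 = K0 / (1.0 + (K0 / P0 - 1.0) * np.exp(-r0 * data.times))
    nu0 = float(max(np.std(y - curve0), 1e-6))
    theta = np.array(
        [
            math.log(K0),
            math.log(r0),
            math.log(P0),
            math.log(nu0**-2),
            max(hyper.mu_sigma, hyper.sigma_trunc_low + 0.5),
        ]
    )
    path_nat = K0 / (1.0 + (K0 / P0 - 1.0) * np.exp(-r0 * grid))
    states = np.log(path_nat) if scale == "log" else path_nat
    states[0] = theta[2] if scale == "log" else math.exp(theta[2])

    def complete_loglik(th: np.ndarray, st: np.ndarray) -> float:
        if scale == "natural" and np.any(st <= 0.0):
            return -math.inf
        nu = math.exp(-0.5 * th[3])
        ll = float(np.sum(_edge_loglik(st[:-1], st[1:], dt, th, scale)))
        ll += float(np.sum(_obs_loglik(st[obs_idx], w, nu)))
        return ll if math.isfinite(ll) else -math.inf

    lp_cur = _log_prior_theta(theta, hyper)
    ll_cur = complete_loglik(theta, states)
    if not math.isfinite(lp_cur + ll_cur):
        raise RuntimeError("data-augmentation initialisation has zero posterior density")

    # site proposals: additive random walk on the log-scale path (SLGM+L),
    # multiplicative random walk (log-space step, Hastings-corrected) on the
    # natural-scale path (SLGM+N) so the proposal magnitude tracks the local
    # state — early-growth states are orders of magnitude below K
    scales = config.scales.copy()
    site_scale = 0.05
    interior = np.arange(1, n_sites)
    halves = (interior[interior % 2 == 0], interior[interior % 2 == 1])
    is_obs = np.zeros(n_sites, dtype=bool)
    is_obs[obs_idx] = True
    obs_pos = np.full(n_sites, -1, dtype=int)
    obs_pos[obs_idx] = np.arange(obs_idx.size)

    n_total = config.n_burn + config.n_keep * config.thin
    draws = np.empty((config.n_keep, 5))
    kept = 0
    win_prop = np.zeros(5)
    win_acc = np.zeros(5)
    post_prop = np.zeros(5)
    post_acc = np.zeros(5)
    site_prop = 0.0
    site_acc = 0.0

    for it in range(n_total):
        in_burn = it < config.n_burn

        # --- parameter updates (Metropolis with complete-data likelihood).
        # Growth-parameter moves are non-centred: the path is shifted with
        # the deterministic logistic curve (additive shift in log space is
        # volume-preserving; the multiplicative natural-scale shift carries
        # its log-Jacobian), so the imputed path does not pin (K, r, P) to
        # their initial values.
        def _curve(th: np.ndarray) -> np.ndarray:
            Kc, rc, Pc = math.exp(th[0]), math.exp(th[1]), math.exp(th[2])
            return Kc / (1.0 + (Kc / Pc - 1.0) * np.exp(-rc * grid))

        for j in range(5):
            if scales[j] == 0.0:
                continue
            prop = theta.copy()
            prop[j] += scales[j] * rng.standard_normal()
            lp_new = _log_prior_theta(prop, hyper)
            if math.isfinite(lp_new):
                jac = 0.0
                if j <= 2:  # K, r, P: move the path with the curve
                    vc, vp = _curve(theta), _curve(prop)
                    st = states.copy()
                    if scale == "log":
                        st += np.log(vp) - np.log(vc)
                        st[0] = prop[2]
                    else:
                        ratio = vp / vc
                        st *= ratio
                        st[0] = math.exp(prop[2])
                        jac = float(np.sum(np.log(ratio[1:])))
                else:
                    st = states
                ll_new = complete_loglik(prop, st)
                accepted = math.isfinite(ll_new) and metropolis_accept(
                    rng, (ll_new + lp_new + jac) - (ll_cur + lp_cur)
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
                if j <= 2:
                    states = st

        # --- latent path updates, one interleaved half-grid at a time
        nu = math.exp(-0.5 * theta[3])
        edge_old = _edge_loglik(states[:-1], states[1:], dt, theta, scale)
        for block in halves:
            if site_scale == 0.0:
                continue
            eps = site_scale * rng.standard_normal(block.size)
            prop_states = states.copy()
            if scale == "log":
                prop_states[block] += eps
                hastings = 0.0
            else:
                prop_states[block] *= np.exp(eps)
                hastings = eps  # log q(x|x') - log q(x'|x) = log(x'/x)
            edge_new = _edge_loglik(prop_states[:-1], prop_states[1:], dt, theta, scale)
            d_edge = edge_new - edge_old
            delta = d_edge[block - 1] + hastings
            right = block[block <= n_sites - 2]
            delta[block <= n_sites - 2] += d_edge[right]
            obs_sites = is_obs[block]
            if np.any(obs_sites):
                k = block[obs_sites]
                delta[obs_sites] += _obs_loglik(prop_states[k], w[obs_pos[k]], nu) - _obs_loglik(
                    states[k], w[obs_pos[k]], nu
                )
            if scale == "natural":
                delta = np.where(prop_states[block] > 0.0, delta, -np.inf)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.uniform(size=block.size)) < delta
            if np.any(accept):
                states[block[accept]] = prop_states[block[accept]]
                edge_old = _edge_loglik(states[:-1], states[1:], dt, theta, scale)
            site_prop += block.size
            site_acc += int(accept.sum())
        ll_cur = complete_loglik(theta, states)

        if in_burn and (it + 1) % config.tune_interval == 0:
            for j in range(5):
                if win_prop[j] > 0:
                    scales[j] = tune_scale(
                        scales[j], win_acc[j] / win_prop[j], config.target_low, config.target_high
                    )
            if site_prop > 0:
                site_scale = tune_scale(
                    site_scale, site_acc / site_prop, config.target_low, config.target_high
                )
            win_prop[:] = 0.0
            win_acc[:] = 0.0
            site_prop = site_acc = 0.0

        if not in_burn and (it - config.n_burn + 1) % config.thin == 0:
            draws[kept] = theta
            kept += 1

    with np.errstate(invalid="ignore"):
        acc_rate = np.where(post_prop > 0, post_acc / np.maximum(post_prop, 1), np.nan)
    stuck = (post_prop > 0) & (post_acc == 0)
    if np.any(stuck):
        warnings.warn(
            "data-augmentation chain accepted no post-burn-in proposals for "
            f"{[LOG_PARAM_NAMES[j] for j in np.flatnonzero(stuck)]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return McmcChain(
        draws=draws[:kept],
        names=LOG_PARAM_NAMES,
        acceptance=acc_rate,
        scales=scales,
        model="slgm+l" if error_kind == "lognormal" else "slgm+n",
        seed=config.seed,
    )
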