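"""Closed-form machinery for logistic growth diffusions.

The stochastic logistic growth model (SLGM)

    dX_t = r X_t (1 - X_t / K) dt + sigma X_t dW_t,   X_0 = P,

has no tractable transition density.  This module implements the
deterministic logistic solution together with three analytically
tractable Gaussian approximations of the SLGM:

RRTR
    The Roman-Roman & Torres-Ruiz lognormal diffusion, obtained by
    treating the logistic model as Malthusian growth with a
    deterministic time-dependent fertility and perturbing that
    fertility with white noise.  Its log-density increments are
    Gaussian with variance growing linearly in time (no mean
    reversion).
LNAM
    Linear noise approximation of the log-transformed SLGM
    (multiplicative intrinsic noise).  The residual about the
    deterministic path solves a time-varying Ornstein-Uhlenbeck SDE,
    giving Gaussian transitions on the log-density scale.
LNAA
    Linear noise approximation of the SLGM on the natural density
    scale (additive intrinsic noise), again an Ornstein-Uhlenbeck
    residual, with Gaussian transitions on the density scale.

All three share the structural form

    state_t | state_s  ~  N( v(t) + phi(s, t) * (state_s - v(s)),  Xi(s, t) )

where ``v`` is the model's deterministic profile on its own scale,
``phi`` is the residual decay factor (identically 1 for the RRTR) and
``Xi`` the conditional variance.  That triple is everything a Kalman
filter needs, and :func:`filter_inputs` assembles it for a whole
observation grid in one vectorised call.

Time conventions: the origin is t0 = 0 and the latent initial state is
exactly P (a point mass); all formulas below assume t >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "MODELS",
    "InvalidParameterError",
    "TimeOrderingError",
    "GrowthParams",
    "ModelCoeffs",
    "TransitionMoments",
    "LatentDecomposition",
    "logistic_solution",
    "lnam_deterministic_path",
    "lnaa_deterministic_path",
    "rrtr_transition",
    "lnam_transition",
    "lnaa_transition",
    "state_profile",
    "step_moments",
    "filter_inputs",
]

log = logging.getLogger(__name__)

MODELS = ("rrtr", "lnam", "lnaa")

#: relative tolerance below which negative conditional variances are treated
#: as floating-point cancellation and clamped to zero
_XI_CLAMP_REL = 1e-15

ArrayLike = Union[float, np.ndarray]


class InvalidParameterError(ValueError):
    """Raised for parameter values outside a model's domain."""


class TimeOrderingError(ValueError):
    """Raised when transition times are not strictly increasing."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

#: order of the log-scale parameterisation used throughout the samplers
LOG_PARAM_NAMES = ("log_K", "log_r", "log_P", "log_inv_nu2", "log_inv_sigma2")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth and noise parameters on the natural scale.

    Parameters
    ----------
    K : float
        Carrying capacity (scaled density), strictly positive.
    r : float
        Intrinsic growth rate (per unit time), strictly positive.
    P : float
        Initial density ``x(0)``, strictly positive.
    sigma : float
        Intrinsic-noise scale of the SDE diffusion term (per square
        root of time), non-negative.
    nu : float
        Measurement-error standard deviation of the observation
        equation (log scale for multiplicative error models, density
        scale for additive ones), non-negative.
    """

    K: float
    r: float
    P: float
    sigma: float = 0.0
    nu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K", "r", "P"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0.0:
                raise InvalidParameterError(
                    f"{name} must be finite and strictly positive, got {v!r}"
                )
        for name in ("sigma", "nu"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0.0:
                raise InvalidParameterError(
                    f"{name} must be finite and non-negative, got {v!r}"
                )

    def to_log(self) -> np.ndarray:
        """Log-scale vector ``(log K, log r, log P, log nu^-2, log sigma^-2)``.

        Zero noise maps to ``+inf`` log-precision; the round trip through
        :meth:`from_log` is lossless.
        """
        with np.errstate(divide="ignore"):
            return np.array(
                [
                    np.log(self.K),
                    np.log(self.r),
                    np.log(self.P),
                    -2.0 * np.log(self.nu),
                    -2.0 * np.log(self.sigma),
                ]
            )

    @classmethod
    def from_log(cls, theta: np.ndarray) -> "GrowthParams":
        """Inverse of :meth:`to_log`."""
        th = np.asarray(theta, dtype=float)
        if th.shape != (5,):
            raise InvalidParameterError(f"expected 5 log-parameters, got {th.shape}")
        return cls(
            K=float(np.exp(th[0])),
            r=float(np.exp(th[1])),
            P=float(np.exp(th[2])),
            nu=float(np.exp(-0.5 * th[3])),
            sigma=float(np.exp(-0.5 * th[4])),
        )


@dataclass(frozen=True)
class ModelCoeffs:
    """Derived coefficients (a, b, Q) for one approximating diffusion.

    ``a`` is the effective linear growth rate (``r`` for RRTR/LNAA,
    ``r - sigma^2/2`` for the LNAM after the Ito log transform),
    ``b = r / K`` the saturation coefficient and ``Q`` the offset of
    the deterministic solution, ``Q = a/(b P) - 1`` (which equals
    ``K/P - 1`` whenever ``a = r``).
    """

    model: str
    a: float
    b: float
    Q: float

    @classmethod
    def for_model(cls, model: str, params: GrowthParams) -> "ModelCoeffs":
        model = model.lower()
        if model not in MODELS:
            raise InvalidParameterError(f"unknown model {model!r}; expected one of {MODELS}")
        b = params.r / params.K
        if model == "lnam":
            a = params.r - 0.5 * params.sigma**2
            if a <= 0.0:
                raise InvalidParameterError(
                    f"LNAM requires a = r - sigma^2/2 > 0 (r={params.r}, sigma={params.sigma})"
                )
        else:
            a = params.r
        Q = a / (b * params.P) - 1.0
        return cls(model=model, a=a, b=b, Q=Q)


@dataclass(frozen=True)
class TransitionMoments:
    """Gaussian conditional moments of one inter-observation step.

    ``mu`` is on the log-density scale for RRTR/LNAM and the natural
    density scale for the LNAA; ``xi`` is the conditional variance on
    the same scale squared.
    """

    mu: ArrayLike
    xi: ArrayLike


@dataclass(frozen=True)
class LatentDecomposition:
    """Split of a latent state into deterministic part and residual.

    ``v + z`` reconstructs the state exactly; ``scale`` records whether
    the decomposition lives on the log or the natural density scale.
    """

    v: ArrayLike
    z: ArrayLike
    scale: str

    def reconstruct(self) -> ArrayLike:
        return self.v + self.z

    @classmethod
    def from_state(
        cls, model: str, state: ArrayLike, t: ArrayLike, params: GrowthParams
    ) -> "LatentDecomposition":
        v = state_profile(model, params, t)
        scale = "natural" if model.lower() == "lnaa" else "log"
        return cls(v=v, z=np.asarray(state, dtype=float) - v, scale=scale)


# ---------------------------------------------------------------------------
# deterministic solutions
# ---------------------------------------------------------------------------


def _as_times(t: ArrayLike, minimum: float = 0.0) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < minimum):
        raise TimeOrderingError(f"times must be >= {minimum}, got minimum {arr.min()}")
    return arr


def _maybe_scalar(x: np.ndarray, template: ArrayLike) -> ArrayLike:
    return float(x) if np.ndim(template) == 0 else x


def logistic_solution(t: ArrayLike, params: GrowthParams) -> ArrayLike:
    """Deterministic logistic curve ``x(t) = K / (1 + Q e^{-rt})``.

    ``Q = K/P - 1`` with the time origin at t0 = 0, so ``x(0) = P`` and
    ``x(t) -> K`` as ``t -> inf``.
    """
    tt = _as_times(t)
    Q = params.K / params.P - 1.0
    x = params.K / (1.0 + Q * np.exp(-params.r * tt))
    return _maybe_scalar(x, t)


def lnam_deterministic_path(t: ArrayLike, coeffs: ModelCoeffs, P: float) -> ArrayLike:
    """Log-scale deterministic profile of the LNAM.

    Solves ``dv = (a - b e^v) dt`` with ``v(0) = log P``:

        v(t) = log[ a P e^{at} / (b P (e^{at} - 1) + a) ].

    Computed through ``e^{-at}`` so the result stays finite for large
    ``a t`` (no overflow up to a*t ~ 700 and beyond).
    """
    if coeffs.a <= 0.0:
        raise InvalidParameterError(f"deterministic path requires a > 0, got a={coeffs.a}")
    tt = _as_times(t)
    bP = coeffs.b * P
    v = np.log(P) + np.log(coeffs.a) - np.log(bP + (coeffs.a - bP) * np.exp(-coeffs.a * tt))
    return _maybe_scalar(v, t)


def lnaa_deterministic_path(t: ArrayLike, coeffs: ModelCoeffs, P: float) -> ArrayLike:
    """Natural-scale deterministic profile of the LNAA.

    With ``a = r`` this is exactly the logistic solution:
    ``v(t) = a P e^{at} / (b P (e^{at} - 1) + a)``.
    """
    if coeffs.a <= 0.0:
        raise InvalidParameterError(f"deterministic path requires a > 0, got a={coeffs.a}")
    tt = _as_times(t)
    bP = coeffs.b * P
    v = coeffs.a * P / (bP + (coeffs.a - bP) * np.exp(-coeffs.a * tt))
    return _maybe_scalar(v, t)


def state_profile(model: str, params: GrowthParams, t: ArrayLike) -> ArrayLike:
    """Deterministic profile v(t) on the model's own state scale.

    For the RRTR the latent log-density drifts below the logistic curve
    by the Ito correction, ``v(t) = log x(t) - sigma^2 t / 2``, which
    makes the residual ``z = Y - v`` a driftless random walk (and keeps
    ``E[X_t]`` on the logistic curve, as expected of a lognormal
    process).  For LNAM/LNAA it is the corresponding deterministic
    solution of the linear noise expansion.
    """
    model = model.lower()
    tt = _as_times(t)
    if model == "rrtr":
        Q = params.K / params.P - 1.0
        v = (
            np.log(params.K)
            - np.log1p(Q * np.exp(-params.r * tt))
            - 0.5 * params.sigma**2 * tt
        )
        return _maybe_scalar(v, t)
    coeffs = ModelCoeffs.for_model(model, params)
    if model == "lnam":
        return lnam_deterministic_path(t, coeffs, params.P)
    if model == "lnaa":
        return lnaa_deterministic_path(t, coeffs, params.P)
    raise InvalidParameterError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# transition moments
# ---------------------------------------------------------------------------


def _clamp_xi(xi: np.ndarray) -> np.ndarray:
    """Clamp tiny negative variances produced by cancellation to zero."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0.0):
        scale = float(np.max(np.abs(xi))) if xi.size else 0.0
        worst = float(np.min(xi))
        if worst < -_XI_CLAMP_REL * max(scale, 1.0) * 1e3:
            log.warning(
                "clamping negative transition variance %.3e (scale %.3e) to zero",
                worst,
                scale,
            )
        xi = np.where(xi < 0.0, 0.0, xi)
    return xi


def step_moments(
    model: str, params: GrowthParams, t_prev: ArrayLike, t: ArrayLike
) -> tuple:
    """Residual decay ``phi`` and conditional variance ``Xi`` per step.

    Vectorised over aligned arrays ``t_prev < t``.  The step moments
    satisfy the Chapman-Kolmogorov composition exactly for LNAM/LNAA
    (both are exact solutions of linear SDEs) and trivially for the
    RRTR random walk.
    """
    model = model.lower()
    t0 = np.asarray(t_prev, dtype=float)
    t1 = np.asarray(t, dtype=float)
    dt = t1 - t0
    if np.any(dt <= 0.0):
        raise TimeOrderingError("transition requires t > t_prev")
    s2 = params.sigma**2

    if model == "rrtr":
        phi = np.ones(np.broadcast(t0, t1).shape)
        xi = s2 * dt
        return phi, _clamp_xi(xi)

    coeffs = ModelCoeffs.for_model(model, params)
    a, b, Q = coeffs.a, coeffs.b, coeffs.Q
    ed = np.exp(-a * dt)

    if model == "lnam":
        E0 = np.exp(-a * t0)
        E1 = np.exp(-a * t1)
        phi = ed * (1.0 + Q * E0) / (1.0 + Q * E1)
        # Xi = sigma^2 [e^{2at}-e^{2as} + 4Q(e^{at}-e^{as}) + 2aQ^2(t-s)]
        #      / (2a (Q + e^{at})^2), rearranged through e^{-at} for stability
        num = (1.0 - ed**2) + 4.0 * Q * E1 * (1.0 - ed) + 2.0 * a * dt * (Q * E1) ** 2
        xi = s2 * num / (2.0 * a * (1.0 + Q * E1) ** 2)
        return phi, _clamp_xi(xi)

    if model == "lnaa":
        bP = b * params.P
        c = a - bP
        E0 = np.exp(-a * t0)
        E1 = np.exp(-a * t1)
        D0 = bP + c * E0
        D1 = bP + c * E1
        phi = ed * (D0 / D1) ** 2
        # Xi = sigma^2 a P^2 e^{2at} / (2 D(t)^4)
        #      * [b^2P^2(e^{2at}-e^{2as}) + 4bP(a-bP)(e^{at}-e^{as})
        #         + 2a(t-s)(a-bP)^2], rearranged through e^{-at}
        num = (
            bP**2 * (1.0 - ed**2)
            + 4.0 * bP * c * E1 * (1.0 - ed)
            + 2.0 * a * dt * (c * E1) ** 2
        )
        xi = s2 * a * params.P**2 * num / (2.0 * D1**4)
        return phi, _clamp_xi(xi)

    raise InvalidParameterError(f"unknown model {model!r}")


def _transition(
    model: str, state_prev: ArrayLike, t_prev: ArrayLike, t: ArrayLike, params: GrowthParams
) -> TransitionMoments:
    v0 = state_profile(model, params, t_prev)
    v1 = state_profile(model, params, t)
    phi, xi = step_moments(model, params, t_prev, t)
    mu = v1 + phi * (np.asarray(state_prev, dtype=float) - v0)
    if np.ndim(state_prev) == 0 and np.ndim(t) == 0:
        return TransitionMoments(mu=float(mu), xi=float(xi))
    return TransitionMoments(mu=mu, xi=xi)


def rrtr_transition(
    y_prev: ArrayLike, t_prev: ArrayLike, t: ArrayLike, params: GrowthParams
) -> TransitionMoments:
    """RRTR log-density transition.

    ``mu = y_prev + log[(1 + Q e^{-r t_prev}) / (1 + Q e^{-r t})] - sigma^2 (t - t_prev)/2``
    with ``Q = K/P - 1`` and ``Xi = sigma^2 (t - t_prev)``: a Gaussian
    random walk about the Ito-corrected logistic log-curve, so the
    variance accumulates without bound.
    """
    return _transition("rrtr", y_prev, t_prev, t, params)


def lnam_transition(
    y_prev: ArrayLike, t_prev: ArrayLike, t: ArrayLike, params: GrowthParams
) -> TransitionMoments:
    """LNAM log-density transition (time-varying Ornstein-Uhlenbeck).

    The residual ``z = y - v`` decays by
    ``phi = e^{-a dt} (1 + Q e^{-a t_prev}) / (1 + Q e^{-a t})`` and picks
    up the closed-form variance of the linear SDE ``dZ = -b e^v Z dt + sigma dW``.
    """
    return _transition("lnam", y_prev, t_prev, t, params)


def lnaa_transition(
    x_prev: ArrayLike, t_prev: ArrayLike, t: ArrayLike, params: GrowthParams
) -> TransitionMoments:
    """LNAA natural-scale transition (Ornstein-Uhlenbeck about the logistic curve).

    Residual decay ``phi = e^{a dt} (D(t_prev)/D(t))^2`` with
    ``D(t) = b P (e^{at} - 1) + a``, and the closed-form variance of
    ``dZ = (a - 2 b v) Z dt + sigma v dW``.
    """
    return _transition("lnaa", x_prev, t_prev, t, params)


def filter_inputs(model: str, params: GrowthParams, times: np.ndarray) -> tuple:
    """Per-step state-space quantities for a Kalman filter.

    Given strictly increasing observation times ``t_1 < ... < t_N`` (all
    > 0; the latent state starts at the point mass P at t0 = 0), returns
    the triple of length-N arrays ``(v, phi, xi)``: deterministic
    profile at each observation time, residual decay over each step
    ``t_{i-1} -> t_i`` and conditional step variance.
    """
    tt = np.asarray(times, dtype=float)
    if tt.ndim != 1 or tt.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if tt[0] <= 0.0 or np.any(np.diff(tt) <= 0.0):
        raise TimeOrderingError("observation times must be strictly increasing and > 0")
    t_prev = np.concatenate(([0.0], tt[:-1]))
    v = state_profile(model, params, tt)
    phi, xi = step_moments(model, params, t_prev, tt)
    return np.asarray(v, dtype=float), np.asarray(phi, dtype=float), np.asarray(xi, dtype=float)
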