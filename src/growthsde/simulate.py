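"""Euler-Maruyama simulation and the synthetic-data generator.

Simulates the SLGM and its three approximating diffusions on a fine
time grid, builds forward-trajectory ensembles with pointwise summary
statistics, and generates the synthetic observation datasets (latent
SLGM path plus lognormal or normal measurement error) used by the
experiments and the test suite.

Positivity: the SLGM and RRTR carry multiplicative noise and stay
positive in law, so they are stepped on the log scale (Euler-Maruyama
applied to the Ito-transformed SDE); the LNAM state is already a
log-density and the LNAA is a Gaussian process on the natural scale.
A natural-scale SLGM stepper with reject-and-resample handling of
negative excursions is available for cross-checks.

Randomness: Wiener increments are i.i.d. Gaussians of variance dt
drawn from a counter-based Philox stream.  Increment matrices are
generated row-per-path (chunked for memory), so path ``i`` of an
ensemble is reproducible regardless of the total ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .growth_models import GrowthParams, InvalidParameterError
from .timecourse import TimeCourse

__all__ = [
    "EMConfig",
    "Trajectory",
    "Ensemble",
    "SyntheticDataset",
    "observation_times",
    "em_simulate",
    "em_paths",
    "forward_ensemble",
    "make_synthetic_dataset",
]

SIM_MODELS = ("slgm", "rrtr", "lnam", "lnaa")

#: maximum number of floats drawn per noise chunk (memory guard)
_CHUNK_ELEMENTS = 20_000_000


def observation_times(n: int = 27, t_max: float = 7.0) -> np.ndarray:
    """``n`` evenly spaced observation times on (0, t_max], last at t_max."""
    return t_max * np.arange(1, n + 1) / n


@dataclass
class EMConfig:
    """Euler-Maruyama configuration.

    ``dt`` is the target fine step (each inter-output interval is split
    into equal sub-steps no longer than dt, so output times always lie
    on the fine grid); ``t_grid`` the output times; ``seed`` the Philox
    stream seed; ``n_paths`` the ensemble size.
    """

    dt: float = 7.0 / 5000.0
    t_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int = 0
    n_paths: int = 100

    def __post_init__(self) -> None:
        if self.t_grid is None:
            self.t_grid = observation_times()
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.t_grid.ndim != 1 or self.t_grid.size < 1:
            raise ValueError("t_grid must be a non-empty 1-D array")
        gaps = np.diff(np.concatenate(([0.0], self.t_grid)))
        if np.any(gaps <= 0.0):
            raise ValueError("t_grid must be strictly increasing and > 0")
        if not self.dt > 0.0:
            raise ValueError("dt must be positive")
        if self.dt > gaps.min() + 1e-12:
            raise ValueError(
                f"dt={self.dt} exceeds the minimum output spacing {gaps.min():.3g}"
            )
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")


@dataclass
class Trajectory:
    """A single fine-grid latent path on the model's state scale."""

    times: np.ndarray
    states: np.ndarray
    model: str
    scale: str  # "log" or "natural"

    @property
    def densities(self) -> np.ndarray:
        return np.exp(self.states) if self.scale == "log" else self.states

    def at(self, times: np.ndarray) -> np.ndarray:
        """States at a subset of the fine grid times."""
        idx = np.searchsorted(self.times, times)
        if not np.allclose(self.times[idx], times, rtol=0, atol=1e-9):
            raise ValueError("requested times are not on the fine grid")
        return self.states[idx]


@dataclass
class Ensemble:
    """Forward-trajectory ensemble with pointwise summary statistics.

    ``paths`` holds the trajectories on the natural density scale
    (rows: paths, columns: output times); ``mean``/``sd`` are pointwise
    over paths (sample sd, ddof=1).
    """

    times: np.ndarray
    paths: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_paths(cls, times: np.ndarray, paths: np.ndarray) -> "Ensemble":
        return cls(
            times=times,
            paths=paths,
            mean=paths.mean(axis=0),
            sd=paths.std(axis=0, ddof=1),
        )

    def band(self, lo: float = 2.5, hi: float = 97.5) -> tuple:
        """Pointwise percentile band across paths."""
        return (
            np.percentile(self.paths, lo, axis=0),
            np.percentile(self.paths, hi, axis=0),
        )


@dataclass
class SyntheticDataset:
    """A synthetic observation set with its generating latent truth."""

    timecourse: TimeCourse
    latent: Trajectory
    true_params: GrowthParams
    error_kind: str

    @property
    def latent_at_obs(self) -> np.ndarray:
        """Latent density at the observation times."""
        return np.exp(self.latent.at(self.timecourse.times))


# ---------------------------------------------------------------------------
# fine grid and the vectorised stepping engine
# ---------------------------------------------------------------------------


def _fine_grid(t_grid: np.ndarray, dt: float) -> tuple:
    """Fine grid from 0 through t_grid; returns (times, output indices)."""
    edges = np.concatenate(([0.0], t_grid))
    times = [0.0]
    out_idx = []
    for i in range(t_grid.size):
        gap = edges[i + 1] - edges[i]
        nsub = max(1, int(np.ceil(gap / dt - 1e-9)))
        sub = edges[i] + gap * np.arange(1, nsub + 1) / nsub
        times.extend(sub.tolist())
        out_idx.append(len(times) - 1)
    return np.array(times), np.array(out_idx, dtype=int)


def _broadcast_params(params, n_paths: int) -> dict:
    """Accept a GrowthParams or a dict of arrays; return per-path arrays."""
    if isinstance(params, GrowthParams):
        d = {"K": params.K, "r": params.r, "P": params.P, "sigma": params.sigma}
    else:
        d = dict(params)
    out = {}
    for k in ("K", "r", "P", "sigma"):
        out[k] = np.broadcast_to(np.asarray(d[k], dtype=float), (n_paths,)).copy()
    return out


def _run_paths(
    model: str,
    pars: dict,
    times_fine: np.ndarray,
    record_idx: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Step ``noise.shape[0]`` paths over the fine grid; record states.

    Returns an (n_paths, len(record_idx)) array on the model's state
    scale (log for slgm/rrtr/lnam, natural for lnaa).
    """
    model = model.lower()
    K, r, P, sig = pars["K"], pars["r"], pars["P"], pars["sigma"]
    s2 = sig * sig
    n = noise.shape[0]
    out = np.empty((n, record_idx.size))
    rec = {int(j): k for k, j in enumerate(record_idx)}

    if model in ("slgm", "rrtr", "lnam"):
        state = np.log(P).astype(float).copy()
    else:
        state = P.astype(float).copy()

    if model == "rrtr":
        Q = K / P - 1.0
    elif model == "lnam":
        a = r - 0.5 * s2
        if np.any(a <= 0.0):
            raise InvalidParameterError("LNAM simulation requires r - sigma^2/2 > 0")
        b = r / K
        bP = b * P
        c = a - bP
        logaP = np.log(a * P)
    elif model == "lnaa":
        a = r
        b = r / K
        bP = b * P
        c = a - bP
    elif model != "slgm":
        raise InvalidParameterError(f"unknown model {model!r}; expected one of {SIM_MODELS}")

    if 0 in rec:
        out[:, rec[0]] = state

    with np.errstate(over="ignore"):
        for k in range(times_fine.size - 1):
            t = times_fine[k]
            d = times_fine[k + 1] - t
            sq = np.sqrt(d)
            if model == "slgm":
                drift = r - 0.5 * s2 - (r / K) * np.exp(state)
                diff = sig
            elif model == "rrtr":
                E = np.exp(-r * t)
                drift = Q * r * E / (1.0 + Q * E) - 0.5 * s2
                diff = sig
            elif model == "lnam":
                den = bP + c * np.exp(-a * t)
                v = logaP - np.log(den)
                bev = b * a * P / den
                drift = a - bev * (1.0 + state - v)
                diff = sig
            else:  # lnaa
                v = a * P / (bP + c * np.exp(-a * t))
                drift = b * v * v + (a - 2.0 * b * v) * state
                diff = sig * v
            state = state + drift * d + diff * sq * noise[:, k]
            if (k + 1) in rec:
                out[:, rec[k + 1]] = state
    return out


def em_paths(
    model: str,
    params,
    config: EMConfig,
    seed_seq: Optional[np.random.SeedSequence] = None,
    noise: Optional[np.ndarray] = None,
    n_paths: Optional[int] = None,
) -> np.ndarray:
    """Vectorised E-M: many paths, optionally with per-path parameters.

    ``params`` may be a :class:`GrowthParams` (shared across paths) or a
    mapping of arrays ``{K, r, P, sigma}`` broadcastable to the number
    of paths.  Returns states at ``config.t_grid`` on the model's state
    scale, shape (n_paths, len(t_grid)).
    """
    times_fine, out_idx = _fine_grid(config.t_grid, config.dt)
    n_steps = times_fine.size - 1
    n = n_paths if n_paths is not None else (noise.shape[0] if noise is not None else config.n_paths)
    pars = _broadcast_params(params, n)

    if noise is not None:
        if noise.shape != (n, n_steps):
            raise ValueError(f"noise must have shape {(n, n_steps)}")
        return _run_paths(model, pars, times_fine, out_idx, noise)

    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.Philox(ss))
    chunk = max(1, _CHUNK_ELEMENTS // max(n_steps, 1))
    blocks = []
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        sub = {k: v[start:stop] for k, v in pars.items()}
        z = rng.standard_normal((stop - start, n_steps))
        blocks.append(_run_paths(model, sub, times_fine, out_idx, z))
    return np.concatenate(blocks, axis=0)


def em_simulate(
    model: str,
    params: GrowthParams,
    config: EMConfig,
    seed_seq: Optional[np.random.SeedSequence] = None,
    natural_slgm: bool = False,
) -> Trajectory:
    """One E-M path on the full fine grid.

    ``natural_slgm=True`` steps the SLGM on the density scale instead
    of the log scale, with negative excursions rejected and resampled
    at the step level (for oracle cross-checks only).
    """
    model = model.lower()
    times_fine, _ = _fine_grid(config.t_grid, config.dt)
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.Philox(ss))

    if model == "slgm" and natural_slgm:
        x = float(params.P)
        states = np.empty(times_fine.size)
        states[0] = x
        for k in range(times_fine.size - 1):
            d = times_fine[k + 1] - times_fine[k]
            mu = x + params.r * x * (1.0 - x / params.K) * d
            sd = params.sigma * x * np.sqrt(d)
            new = mu + sd * rng.standard_normal()
            tries = 0
            while new <= 0.0 and tries < 100:
                new = mu + sd * rng.standard_normal()
                tries += 1
            x = new if new > 0.0 else max(mu, 1e-300)
            states[k + 1] = x
        return Trajectory(times=times_fine, states=states, model=model, scale="natural")

    pars = _broadcast_params(params, 1)
    noise = rng.standard_normal((1, times_fine.size - 1))
    states = _run_paths(model, pars, times_fine, np.arange(times_fine.size), noise)
    scale = "natural" if model == "lnaa" else "log"
    return Trajectory(times=times_fine, states=states[0], model=model, scale=scale)


def forward_ensemble(
    model: str,
    params: GrowthParams,
    config: EMConfig,
    seed_seq: Optional[np.random.SeedSequence] = None,
) -> Ensemble:
    """Ensemble of E-M paths with pointwise mean and sd on the density scale."""
    if config.n_paths < 2:
        raise ValueError("an ensemble needs n_paths >= 2")
    states = em_paths(model, params, config, seed_seq=seed_seq)
    dens = states if model.lower() == "lnaa" else np.exp(states)
    return Ensemble.from_paths(config.t_grid, dens)


def make_synthetic_dataset(
    params: GrowthParams, error_kind: str, config: EMConfig
) -> SyntheticDataset:
    """A synthetic observation set: fine-grid SLGM path + measurement error.

    ``lognormal``: y = exp(N(log X, nu^2)); ``normal``: y = N(X, nu^2)
    (which may produce non-positive observations when the latent
    density is small relative to nu — this is a property of the
    additive-error model, and log-scale models will refuse such data).
    The latent path and the error draws come from independent child
    streams of ``config.seed``, so the same seed yields the same latent
    path under either error kind and error layering never perturbs the
    latent path.
    """
    error_kind = error_kind.lower()
    if error_kind not in ("lognormal", "normal"):
        raise ValueError(f"error_kind must be 'lognormal' or 'normal', got {error_kind!r}")
    path_ss, err_ss = np.random.SeedSequence(config.seed).spawn(2)
    latent = em_simulate("slgm", params, config, seed_seq=path_ss)
    x_obs = np.exp(latent.at(config.t_grid))
    rng = np.random.Generator(np.random.Philox(err_ss))
    if error_kind == "lognormal":
        y = np.exp(rng.normal(np.log(x_obs), params.nu))
    else:
        y = rng.normal(x_obs, params.nu)
    tc = TimeCourse(times=config.t_grid.copy(), obs=y, culture_id=f"synthetic-{error_kind}")
    return SyntheticDataset(
        timecourse=tc, latent=latent, true_params=params, error_kind=error_kind
    )
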