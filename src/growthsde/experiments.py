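"""Simulation studies: forward-MSE grid, parameter recovery, total MSE.

Quantifies how well each tractable diffusion approximates the SLGM:

* :func:`mse_vs_slgm` — forward-simulation study over a 4-D parameter
  grid, scoring each approximation's ensemble mean and sd curves
  against the SLGM's (the headline ordering is LNAM < LNAA << RRTR).
* :func:`recovery_study` — fit state-space models to synthetic SLGM
  datasets and tabulate posterior means/sds against the generating
  truth.
* :func:`total_mse` — posterior-predictive scoring of fitted models
  against observed time-courses, summed over cultures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .growth_models import GrowthParams
from .inference import (
    McmcChain,
    McmcConfig,
    PriorHyper,
    mwg_sample,
    posterior_predictive,
    posterior_summary,
)
from .simulate import EMConfig, em_paths, make_synthetic_dataset, observation_times
from .timecourse import TimeCourse

__all__ = [
    "MseGridSpec",
    "MseReport",
    "mse_vs_slgm",
    "cell_ensemble_stats",
    "recovery_study",
    "total_mse",
    "make_yeast_like_cultures",
    "TABLE2_PARAM_SETS",
]

#: the three true-parameter sets used for the synthetic recovery studies
#: (K, r, P, nu, sigma)
TABLE2_PARAM_SETS = (
    GrowthParams(K=0.15, r=3.0, P=1e-4, nu=0.005, sigma=0.01),
    GrowthParams(K=0.11, r=4.0, P=5e-5, nu=0.001, sigma=0.05),
    GrowthParams(K=0.30, r=6.0, P=2e-4, nu=0.01, sigma=0.02),
)

_MODEL_SEED_TAG = {"slgm": 0, "rrtr": 1, "lnam": 2, "lnaa": 3}


# ---------------------------------------------------------------------------
# forward-simulation MSE grid
# ---------------------------------------------------------------------------


@dataclass
class MseGridSpec:
    """Parameter grid for the forward-simulation MSE study.

    Each range ``(0, b)`` is an open interval; ``n_values`` evenly
    spaced interior points are used, ``b * {1..n} / (n + 1)``, since
    the boundary values are degenerate.  Measurement error plays no
    role here: the comparison is between latent trajectories.
    """

    K_max: float = 1.0
    r_max: float = 8.0
    P_max: float = 0.005
    sigma_max: float = 0.6
    n_values: int = 5
    n_traj: int = 100
    n_times: int = 27
    t_max: float = 7.0
    dt: float = 7.0 / 5000.0

    def values(self, b: float) -> np.ndarray:
        return b * np.arange(1, self.n_values + 1) / (self.n_values + 1)

    def cells(self) -> np.ndarray:
        """All parameter combinations, shape (n_values^4, 4): K, r, P, sigma."""
        return np.array(
            list(
                itertools.product(
                    self.values(self.K_max),
                    self.values(self.r_max),
                    self.values(self.P_max),
                    self.values(self.sigma_max),
                )
            )
        )

    def em_config(self) -> EMConfig:
        return EMConfig(
            dt=self.dt, t_grid=observation_times(self.n_times, self.t_max), n_paths=self.n_traj
        )


@dataclass
class MseReport:
    """Average and per-cell MSEs of each approximation against the SLGM."""

    mean_mse: Dict[str, float]
    sd_mse: Dict[str, float]
    per_cell: pd.DataFrame


def cell_ensemble_stats(
    spec: MseGridSpec, model: str, cell: np.ndarray, cell_idx: int, seed: int, seed_tag: Optional[int] = None
) -> tuple:
    """Pointwise ensemble mean and sd for one grid cell and model.

    Each (model, cell) pair gets its own counter-based noise stream
    derived from ``(seed, model tag, cell index)``, so results do not
    depend on the order in which cells are evaluated.
    """
    tag = _MODEL_SEED_TAG[model.lower()] if seed_tag is None else seed_tag
    K, r, P, sigma = (float(v) for v in cell)
    cfg = spec.em_config()
    ss = np.random.SeedSequence((seed, tag, cell_idx))
    states = em_paths(
        model,
        {"K": K, "r": r, "P": P, "sigma": sigma},
        cfg,
        seed_seq=ss,
        n_paths=spec.n_traj,
    )
    dens = states if model.lower() == "lnaa" else np.exp(states)
    return dens.mean(axis=0), dens.std(axis=0, ddof=1)


def mse_vs_slgm(
    spec: MseGridSpec,
    models: Sequence[str] = ("rrtr", "lnam", "lnaa"),
    seed: int = 0,
    share_seeds: bool = False,
) -> MseReport:
    """Forward-simulation MSE of each approximation against the SLGM.

    For every grid cell, ``n_traj`` trajectories are simulated from the
    SLGM and from each approximation; the cell score is the squared
    difference between the approximation's pointwise ensemble statistic
    (mean, and separately sd, of density) and the SLGM's, accumulated
    over the output-time grid.  Reported averages are means over all
    cells.
    ``share_seeds=True`` reuses the SLGM's noise streams for every
    model (useful only for self-comparison checks).
    """
    cells = spec.cells()
    rows = []
    for ci, cell in enumerate(cells):
        ref_mean, ref_sd = cell_ensemble_stats(spec, "slgm", cell, ci, seed)
        for model in models:
            tag = 0 if share_seeds else None
            m, s = cell_ensemble_stats(spec, model, cell, ci, seed, seed_tag=tag)
            rows.append(
                {
                    "cell": ci,
                    "K": cell[0],
                    "r": cell[1],
                    "P": cell[2],
                    "sigma": cell[3],
                    "model": model,
                    "mse_mean": float(np.sum((m - ref_mean) ** 2)),
                    "mse_sd": float(np.sum((s - ref_sd) ** 2)),
                }
            )
    per_cell = pd.DataFrame(rows)
    g = per_cell.groupby("model")
    return MseReport(
        mean_mse=g["mse_mean"].mean().to_dict(),
        sd_mse=g["mse_sd"].mean().to_dict(),
        per_cell=per_cell,
    )


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

_MATCHING_ERROR = {"rrtr": "lognormal", "lnam": "lognormal", "lnaa": "normal"}


def recovery_study(
    param_sets: Sequence[GrowthParams],
    error_kind: str,
    models: Sequence[str],
    mcmc: McmcConfig,
    em: Optional[EMConfig] = None,
    hyper: Optional[PriorHyper] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit state-space models to synthetic SLGM datasets.

    Generates one dataset per parameter set (shared by all fitted
    models) and reports, per (set, model, parameter), the posterior
    mean and sd, the generating truth, a recovery flag
    ``|mean - truth| <= 3 sd`` and whether every parameter chain passed
    the Heidelberger-Welch stationarity test.
    """
    em = em or EMConfig()
    rows = []
    for si, truth in enumerate(param_sets):
        cfg = EMConfig(dt=em.dt, t_grid=em.t_grid.copy(), seed=seed + 1000 * si, n_paths=1)
        ds = make_synthetic_dataset(truth, error_kind, cfg)
        for mi, model in enumerate(models):
            hy = hyper or PriorHyper.default_for(ds.timecourse)
            mc = McmcConfig(
                n_burn=mcmc.n_burn,
                thin=mcmc.thin,
                n_keep=mcmc.n_keep,
                scales=mcmc.scales.copy(),
                tune_interval=mcmc.tune_interval,
                target_low=mcmc.target_low,
                target_high=mcmc.target_high,
                seed=mcmc.seed + 101 * si + mi,
            )
            chain = mwg_sample(model, ds.timecourse, hy, mc)
            summ = posterior_summary(chain)
            diag = chain.diagnose()
            converged = all(d.stationary for d in diag.values())
            truth_map = {"K": truth.K, "r": truth.r, "P": truth.P, "nu": truth.nu, "sigma": truth.sigma}
            for pname, row in summ.iterrows():
                rows.append(
                    {
                        "set": si,
                        "model": model,
                        "param": pname,
                        "posterior_mean": row["mean"],
                        "posterior_sd": row["sd"],
                        "truth": truth_map[pname],
                        "recovered": bool(
                            abs(row["mean"] - truth_map[pname]) <= 3.0 * row["sd"]
                        ),
                        "hw_stationary": converged,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior-predictive total MSE
# ---------------------------------------------------------------------------


def total_mse(
    data: Sequence[TimeCourse],
    model: str,
    chains: Sequence[McmcChain],
    n_sims: int = 1000,
    em: Optional[EMConfig] = None,
    seed: int = 0,
    ensembles: Optional[Sequence] = None,
) -> dict:
    """Posterior-predictive MSE of a fitted model against observed cultures.

    For each culture, ``n_sims`` forward trajectories with measurement
    error are simulated from its posterior sample; the per-culture MSE
    is the mean over trajectories of the mean squared deviation from
    the observed time-course at the observation times.  Returns the sum
    over cultures, the per-culture values and their sd.  Precomputed
    predictive ``ensembles`` may be supplied instead of chains (one per
    culture), in which case no simulation is run.
    """
    if ensembles is None and len(data) != len(chains):
        raise ValueError("need exactly one chain per culture")
    if ensembles is not None and len(ensembles) != len(data):
        raise ValueError("need exactly one ensemble per culture")
    per_culture = []
    for ci, tc in enumerate(data):
        if ensembles is not None:
            ens = ensembles[ci]
        else:
            cfg = EMConfig(
                dt=(em.dt if em else EMConfig().dt), t_grid=tc.times.copy(), seed=seed + ci, n_paths=1
            )
            ens = posterior_predictive(model, chains[ci], cfg, n_sims=n_sims)
        mse = float(np.mean(np.mean((ens.paths - tc.obs[None, :]) ** 2, axis=1)))
        per_culture.append(mse)
    arr = np.array(per_culture)
    return {
        "total": float(arr.sum()),
        "per_culture": per_culture,
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


def make_yeast_like_cultures(
    params: GrowthParams,
    n_cultures: int,
    seed: int = 0,
    em: Optional[EMConfig] = None,
) -> List[TimeCourse]:
    """Synthetic stand-ins for observed yeast growth cultures.

    Independent SLGM trajectories with additive normal measurement
    error, with non-positive observations re-drawn: optical-density
    measurements are strictly positive, and a positive dataset lets the
    lognormal-error models be fitted for comparison.  These are
    synthetic constructs, not reproductions of any deposited dataset.
    """
    em = em or EMConfig()
    out = []
    for ci in range(n_cultures):
        culture_seed = int(np.random.SeedSequence((seed, ci)).generate_state(1)[0] % (2**31))
        cfg = EMConfig(dt=em.dt, t_grid=em.t_grid.copy(), seed=culture_seed, n_paths=1)
        ds = make_synthetic_dataset(params, "normal", cfg)
        y = ds.timecourse.obs.copy()
        x = ds.latent_at_obs
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, ci, 7))))
        bad = y <= 0.0
        tries = 0
        while np.any(bad) and tries < 1000:
            y[bad] = rng.normal(x[bad], params.nu)
            bad = y <= 0.0
            tries += 1
        if np.any(bad):  # pathological nu/x ratio: fall back to half the latent value
            y[bad] = 0.5 * x[bad]
        out.append(TimeCourse(times=ds.timecourse.times, obs=y, culture_id=f"synthetic-yeast-{ci}"))
    return out
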