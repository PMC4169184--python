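"""Figure helpers: forward-ensemble panels and posterior-predictive ribbons."""

from __future__ import annotations

from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .simulate import Ensemble
from .timecourse import TimeCourse

__all__ = ["plot_forward_ensembles", "plot_predictive_band"]

_COLORS = {"slgm": "black", "rrtr": "tab:red", "lnam": "tab:green", "lnaa": "tab:blue"}


def plot_forward_ensembles(ensembles: Dict[str, Ensemble], path: Optional[str] = None):
    """One panel of trajectories per model plus a shared sd-over-time panel."""
    n = len(ensembles)
    fig, axes = plt.subplots(1, n + 1, figsize=(3.2 * (n + 1), 3.0), sharex=True)
    for ax, (name, ens) in zip(axes[:-1], ensembles.items()):
        ax.plot(ens.times, ens.paths.T, color=_COLORS.get(name, "gray"), alpha=0.15, lw=0.5)
        ax.plot(ens.times, ens.mean, color=_COLORS.get(name, "gray"), lw=1.5)
        ax.set_title(name.upper())
        ax.set_xlabel("time")
        ax.set_ylabel("density")
    for name, ens in ensembles.items():
        axes[-1].plot(ens.times, ens.sd, color=_COLORS.get(name, "gray"), label=name.upper())
    axes[-1].set_title("ensemble sd")
    axes[-1].set_xlabel("time")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_predictive_band(
    ensemble: Ensemble, data: TimeCourse, path: Optional[str] = None, model: str = ""
):
    """Posterior-predictive 95% ribbon and mean over the observed data."""
    lo, hi = ensemble.band()
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.fill_between(ensemble.times, lo, hi, color="tab:blue", alpha=0.25, label="95% predictive")
    ax.plot(ensemble.times, ensemble.mean, color="tab:blue", lw=1.5, label="predictive mean")
    ax.plot(data.times, data.obs, "ko", ms=3, label="observed")
    ax.set_xlabel("time")
    ax.set_ylabel("density")
    if model:
        ax.set_title(model.upper())
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
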