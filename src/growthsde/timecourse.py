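"""Observed growth time-courses and their CSV I/O.

A :class:`TimeCourse` is one culture's (time, density) observations.
CSV layouts supported: a two-column file ``time,observation`` for a
single culture, or long format with a ``culture_id`` column holding
many cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "read_timecourses", "write_timecourses"]


@dataclass
class TimeCourse:
    """Ordered observation times and measured densities for one culture.

    Times are measured from the latent-process origin t0 = 0 and must
    be strictly increasing and positive (the latent initial state sits
    at t0, strictly before the first observation).  Observations may be
    non-positive — additive-error models allow it — but log-scale
    models must call :meth:`require_positive` before use.
    """

    times: np.ndarray
    obs: np.ndarray
    culture_id: str = "culture"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.obs = np.asarray(self.obs, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.obs.shape:
            raise ValueError("times and obs must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a time-course needs at least 2 observations")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.obs)):
            raise ValueError("times and obs must be finite")
        if np.any(np.diff(self.times) <= 0.0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] <= 0.0:
            # shift so the first observation sits one median gap after the origin
            gap = float(np.median(np.diff(self.times)))
            self.times = self.times - self.times[0] + gap

    @property
    def n(self) -> int:
        return int(self.times.size)

    def require_positive(self) -> None:
        """Raise if any observation is non-positive (log-scale models)."""
        if np.any(self.obs <= 0.0):
            raise ValueError(
                f"culture {self.culture_id!r} has non-positive observations; "
                "log-scale measurement models need strictly positive data"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"culture_id": self.culture_id, "time": self.times, "observation": self.obs}
        )


def read_timecourses(
    path, time_col: str = "time", obs_col: str = "observation", id_col: str = "culture_id"
) -> List[TimeCourse]:
    """Read one or many cultures from a CSV file."""
    df = pd.read_csv(path)
    if time_col not in df.columns or obs_col not in df.columns:
        raise ValueError(f"CSV must contain columns {time_col!r} and {obs_col!r}")
    out = []
    if id_col in df.columns:
        for cid, grp in df.groupby(id_col, sort=False):
            grp = grp.sort_values(time_col)
            out.append(
                TimeCourse(
                    times=grp[time_col].to_numpy(),
                    obs=grp[obs_col].to_numpy(),
                    culture_id=str(cid),
                )
            )
    else:
        df = df.sort_values(time_col)
        out.append(TimeCourse(times=df[time_col].to_numpy(), obs=df[obs_col].to_numpy()))
    return out


def write_timecourses(path, timecourses: List[TimeCourse]) -> None:
    """Write cultures to a long-format CSV."""
    pd.concat([tc.to_frame() for tc in timecourses], ignore_index=True).to_csv(
        path, index=False
    )
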