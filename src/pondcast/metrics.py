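"""Forecast verification: ensemble-mean RMSE and the (mean) continuous
ranked probability score.

CRPS for an m-member ensemble forecast x and scalar observation y is the
exact integral of the squared difference between the empirical forecast
CDF and the observation step function,

    CRPS = (1/m) sum_i |x_i - y| - (1/(2 m^2)) sum_ij |x_i - x_j|,

which reduces to the absolute error for a single member.  The optional
"fair" variant divides the spread term by m(m-1) instead of m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = ["rmse", "crps", "mcrps", "SkillReport"]


def rmse(ensemble_values, observations) -> float:
    """RMSE of the ensemble mean against paired observations.

    ``ensemble_values`` is (M, m) member values at M observation times, or
    a length-M vector of already-averaged forecasts.
    """
    arr = np.asarray(ensemble_values, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if arr.ndim == 2:
        means = arr.mean(axis=1)
    else:
        means = arr
    if means.shape != obs.shape or obs.size == 0:
        raise ValueError("need at least one paired forecast/observation time")
    return float(np.sqrt(np.mean((means - obs) ** 2)))


def _mean_abs_pairwise(x: np.ndarray) -> float:
    """(1/m^2) sum_ij |x_i - x_j| in O(m log m) via the sorted identity."""
    m = x.size
    xs = np.sort(x)
    i = np.arange(m)
    return float(2.0 * np.sum((2 * i - m + 1) * xs) / (m * m))


def crps(members, observation: float, *, fair: bool = False) -> float:
    """CRPS of one ensemble against one observation (exact empirical-CDF
    integral; ``fair`` applies the finite-ensemble spread correction)."""
    x = np.asarray(members, dtype=float).ravel()
    m = x.size
    if m == 0:
        raise ValueError("need at least one ensemble member")
    mae = float(np.mean(np.abs(x - observation)))
    spread = _mean_abs_pairwise(x)
    if fair:
        if m == 1:
            return mae
        spread = spread * m / (m - 1)
    return mae - 0.5 * spread


def mcrps(ensemble_values, observations, *, fair: bool = False) -> float:
    """Mean CRPS over paired observation times; values shaped (M, m)."""
    arr = np.atleast_2d(np.asarray(ensemble_values, dtype=float))
    obs = np.asarray(observations, dtype=float)
    if arr.shape[0] != obs.size or obs.size == 0:
        raise ValueError("need at least one paired forecast/observation time")
    return float(np.mean([crps(arr[t], obs[t], fair=fair) for t in range(obs.size)]))


@dataclass
class SkillReport:
    """Per-forecast-cycle verification scores for one experiment."""

    experiment: str
    cycle_times: List[object] = field(default_factory=list)
    cycle_rmse: List[float] = field(default_factory=list)
    cycle_mcrps: List[float] = field(default_factory=list)
    cycle_n_obs: List[int] = field(default_factory=list)

    def add_cycle(self, time, rmse_value: float, mcrps_value: float, n_obs: int):
        if rmse_value < 0 or mcrps_value < 0:
            raise ValueError("scores must be >= 0")
        self.cycle_times.append(time)
        self.cycle_rmse.append(float(rmse_value))
        self.cycle_mcrps.append(float(mcrps_value))
        self.cycle_n_obs.append(int(n_obs))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.cycle_rmse))

    @property
    def mean_mcrps(self) -> float:
        return float(np.mean(self.cycle_mcrps))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cycle": self.cycle_times,
                "rmse": self.cycle_rmse,
                "mcrps": self.cycle_mcrps,
                "n_obs": self.cycle_n_obs,
            }
        )
        df.insert(0, "experiment", self.experiment)
        return df
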