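"""Berry sugar from simulated dry matter.

The bridge from the carbon balance to fruit quality: measured °Brix,
sampled weekly between veraison and harvest, is regressed linearly on the
simulated cumulative dry matter at the matching days.  The fitted line
then predicts the whole sugar trajectory from any simulated season — in
particular under cluster-thinning scenarios, where the number of clusters
per vine is overridden and the season re-simulated.

Cluster number feeds back on sugar only through cluster maintenance
respiration (fewer clusters → smaller respiratory loss → more dry matter
→ higher predicted Brix); per-berry dilution is not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .carbon_balance import CarbonBalanceParams, simulate_season
from .errors import VitisimError
from .weather import WeatherSeries

__all__ = [
    "BrixObservation",
    "RegressionFit",
    "fit_brix_dm",
    "predict_brix",
    "run_cluster_scenarios",
]


@dataclass(frozen=True)
class BrixObservation:
    """One refractometer reading: day after sprouting and must °Brix."""

    das: int
    brix: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.brix <= 35.0:
            raise VitisimError("brix must lie in [0, 35]")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of °Brix on cumulative dry matter (g per vine)."""

    slope: float  # °Brix per g DM
    intercept: float  # °Brix
    r2: float
    n: int


def fit_brix_dm(
    brix_obs: Sequence[BrixObservation], result: pd.DataFrame
) -> RegressionFit:
    """Ordinary least squares of measured °Brix on simulated dry matter.

    Each observation is matched to ``dm_cumulative`` at its DAS in the
    simulation ``result``; r² is the squared Pearson correlation.
    """
    obs = list(brix_obs)
    if len(obs) < 3:
        raise VitisimError("need at least 3 Brix observations")
    sim = result.set_index("das")["dm_cumulative"]
    das = [o.das for o in obs]
    missing = [d for d in das if d not in sim.index]
    if missing:
        raise VitisimError(f"Brix observation days outside simulated range: {missing}")
    dm = sim.loc[das].to_numpy(dtype=float)
    brix = np.array([o.brix for o in obs], dtype=float)
    if np.ptp(dm) == 0:
        raise VitisimError("dry matter is constant over the observation days")
    if np.ptp(brix) == 0:
        return RegressionFit(slope=0.0, intercept=float(brix[0]), r2=0.0, n=len(obs))
    fit = stats.linregress(dm, brix)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(obs),
    )


def predict_brix(fit: RegressionFit, dm_trajectory) -> np.ndarray:
    """Predicted °Brix along a dry-matter trajectory, clamped at zero."""
    dm = np.asarray(dm_trajectory, dtype=float)
    return np.maximum(fit.intercept + fit.slope * dm, 0.0)


def run_cluster_scenarios(
    weather: WeatherSeries,
    canopy: pd.DataFrame,
    params: CarbonBalanceParams,
    fit: RegressionFit,
    cluster_counts: Iterable[float],
) -> dict[float, pd.DataFrame]:
    """Re-simulate the season under alternative cluster numbers.

    For each count, ``clusters`` is overridden for every day of the
    season, the carbon balance re-run and the Brix trajectory predicted
    from ``fit``.  Returns ``{count: DataFrame(das, dm_cumulative,
    brix)}``.  Because clusters enter only through respiration, predicted
    Brix is pointwise non-increasing in cluster count whenever the
    cluster respiration rate and the fitted slope are positive.
    """
    out: dict[float, pd.DataFrame] = {}
    for count in cluster_counts:
        if count < 0:
            raise VitisimError("cluster count must be non-negative")
        scenario_canopy = canopy.copy()
        scenario_canopy["clusters"] = float(count)
        result = simulate_season(weather, scenario_canopy, params)
        out[float(count)] = pd.DataFrame(
            {
                "das": result["das"],
                "dm_cumulative": result["dm_cumulative"],
                "brix": predict_brix(fit, result["dm_cumulative"]),
            }
        )
    return out
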