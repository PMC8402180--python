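"""Daily carbon balance and seasonal dry-matter accumulation.

The daily loop subtracts total organ respiration from total canopy
photosynthesis, converts the resulting CO₂ balance to dry matter with a
fixed stoichiometric factor (default 30/44 ≈ 0.682 g carbohydrate per g
CO₂), and accumulates it from sprouting to harvest.  Negative daily
balances are allowed and accumulate — early-season respiration can exceed
photosynthesis.

Also provides a one-parameter calibration: a multiplicative factor on the
light-saturated leaf rate fitted by least squares to measured cumulative
dry matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import CoverageError, VitisimError
from .photosynthesis import PhotosynthesisParams, _daily_photosynthesis_vec
from .respiration import RespirationParams, daily_respiration
from .weather import WeatherSeries

__all__ = [
    "CarbonBalanceParams",
    "CalibrationResult",
    "co2_to_dry_matter",
    "simulate_season",
    "calibrate_scale",
]

#: g dry matter per g CO2 under CH2O stoichiometry (30/44).
CH2O_PER_CO2 = 30.0 / 44.0


@dataclass(frozen=True)
class CarbonBalanceParams:
    """All parameters of one simulation run."""

    co2_to_dm: float = CH2O_PER_CO2
    photosynthesis: PhotosynthesisParams = field(default_factory=PhotosynthesisParams)
    respiration: RespirationParams = field(default_factory=RespirationParams)
    n_steps: int = 48

    def __post_init__(self) -> None:
        if not 0.0 < self.co2_to_dm <= 1.0:
            raise VitisimError("co2_to_dm must lie in (0, 1]")
        if self.n_steps < 4:
            raise VitisimError("n_steps must be at least 4")


@dataclass(frozen=True)
class CalibrationResult:
    scale: float
    sse: float


def co2_to_dry_matter(co2, factor: float = CH2O_PER_CO2):
    """Convert a CO₂ mass (g) to dry matter (g); sign-preserving."""
    if not 0.0 < factor <= 1.0:
        raise VitisimError("conversion factor must lie in (0, 1]")
    out = np.asarray(co2, dtype=float) * factor
    return float(out) if np.isscalar(co2) else out


def simulate_season(
    weather: WeatherSeries,
    canopy: pd.DataFrame,
    params: CarbonBalanceParams | None = None,
) -> pd.DataFrame:
    """Run the daily carbon balance over the season.

    ``canopy`` is the daily state table from
    :func:`vitisim.vine_state.interpolate_canopy`; the weather series must
    cover every DAS in its index.  Returns one row per day with columns
    ``das, p_gross_vine, r_total_vine, co2_balance, dm_daily,
    dm_cumulative`` (g CO₂ resp. g dry matter, per vine).
    """
    if params is None:
        params = CarbonBalanceParams()
    wdf = weather.data.set_index("das")
    missing = canopy.index.difference(wdf.index)
    if len(missing):
        raise CoverageError(
            f"weather does not cover simulated days (das): {list(missing)[:10]}"
        )
    w = wdf.loc[canopy.index]
    tmean = (w["tmin"].to_numpy() + w["tmax"].to_numpy()) / 2.0

    p_gross = _daily_photosynthesis_vec(
        tmean,
        w["radiation"].to_numpy(),
        w["day_length"].to_numpy(),
        canopy["light_interception"].to_numpy(),
        params.photosynthesis,
        n_steps=params.n_steps,
    )
    r_total = daily_respiration(
        w["tmin"].to_numpy(),
        w["tmax"].to_numpy(),
        w["day_length"].to_numpy(),
        canopy["shoot_surface"].to_numpy(),
        canopy["cluster_weight"].to_numpy(),
        canopy["clusters"].to_numpy(),
        canopy["leaf_area_increment"].to_numpy(),
        params.respiration,
    )
    balance = p_gross - r_total
    dm_daily = balance * params.co2_to_dm
    return pd.DataFrame(
        {
            "das": canopy.index.to_numpy(),
            "p_gross_vine": p_gross,
            "r_total_vine": r_total,
            "co2_balance": balance,
            "dm_daily": dm_daily,
            "dm_cumulative": np.cumsum(dm_daily),
        }
    )


def _with_pn_scale(params: CarbonBalanceParams, scale: float) -> CarbonBalanceParams:
    p = params.photosynthesis
    return dataclasses.replace(
        params, photosynthesis=dataclasses.replace(p, pn_max=p.pn_max * scale)
    )


def calibrate_scale(
    weather: WeatherSeries,
    canopy: pd.DataFrame,
    params: CarbonBalanceParams,
    observed_dm: Sequence[tuple[int, float]],
    bounds: tuple[float, float] = (0.1, 10.0),
) -> CalibrationResult:
    """Fit a multiplicative factor on ``pn_max`` to measured dry matter.

    Minimises the sum of squared *relative* residuals between observed
    cumulative dry matter at the given DAS values and the simulated
    trajectory, over a single scale factor within ``bounds`` (1-D bounded
    minimisation of a smooth unimodal objective).  Relative residuals are
    the maximum-likelihood weighting when measurement error scales with
    the measured value (a constant coefficient of variation), which is
    how replicated dry-matter samples behave; an absolute-residual
    objective would let the late-season points dominate the fit.
    """
    obs = list(observed_dm)
    if len(obs) < 3:
        raise VitisimError("need at least 3 dry-matter observations to calibrate")
    das_obs = np.array([d for d, _ in obs], dtype=int)
    dm_obs = np.array([v for _, v in obs], dtype=float)
    # keep the scaled pn_max inside its physical ceiling (0.005 g m-2 s-1)
    hi = min(bounds[1], 0.005 / params.photosynthesis.pn_max)
    bounds = (bounds[0], hi)

    if np.any(dm_obs == 0):
        raise VitisimError("observed dry matter must be nonzero for relative residuals")

    def sse(scale: float) -> float:
        result = simulate_season(weather, canopy, _with_pn_scale(params, scale))
        sim = result.set_index("das")["dm_cumulative"]
        try:
            pred = sim.loc[das_obs].to_numpy()
        except KeyError as exc:
            raise VitisimError(f"observation day outside simulated range: {exc}")
        return float(np.sum(((dm_obs - pred) / dm_obs) ** 2))

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-5})
    if not np.isfinite(res.fun):
        raise VitisimError("calibration objective is non-finite")
    return CalibrationResult(scale=float(res.x), sse=float(res.fun))
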