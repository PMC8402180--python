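"""Meteorological inputs and derived quantities.

The daily carbon-balance model consumes, per day: minimum and maximum air
temperature (°C), total shortwave radiation (MJ m⁻² day⁻¹) and day length
(s).  This module ingests a daily weather table, derives day length from
geometric solar geometry when it is not supplied, expands the daily
radiation total into a sub-daily irradiance profile, and computes the
Winkler growing-degree-day index.

Conventions
-----------
* Day length is geometric sunrise-to-sunset (no atmospheric refraction),
  using the Cooper declination ``δ = 23.44°·sin(2π(284+n)/365)`` and the
  hour-angle relation ``cos ω = −tan φ · tan δ``.
* Daily mean temperature is ``(tmin + tmax) / 2``.
* The sub-daily irradiance profile is a half-sine over the daylight period,
  which conserves the daily radiation total by construction.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PolarLatitudeError, VitisimError

__all__ = [
    "WeatherSeries",
    "day_length",
    "gdd_winkler",
    "irradiance_profile",
    "load_weather",
    "make_weather_series",
]

#: Latitude band (degrees) outside which polar day/night occurs in-season.
LAT_LIMIT = 66.0

_REQUIRED_COLUMNS = ("date", "tmin", "tmax", "radiation")


def day_length(latitude: float, day_of_year) -> np.ndarray | float:
    """Geometric day length in seconds.

    Parameters
    ----------
    latitude
        Site latitude in degrees, must lie in ``[-66, 66]``.
    day_of_year
        Day of year (1–366); scalar or array.

    Returns
    -------
    Sunrise-to-sunset duration in seconds (scalar if the input was scalar).
    """
    if not -LAT_LIMIT <= latitude <= LAT_LIMIT:
        raise PolarLatitudeError(
            f"latitude {latitude} outside [{-LAT_LIMIT}, {LAT_LIMIT}]; "
            "polar day/night geometry is not supported"
        )
    doy = np.asarray(day_of_year, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise VitisimError("day_of_year must lie in [1, 366]")
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    phi = np.deg2rad(latitude)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)  # half-day hour angle, radians
    seconds = 2.0 * omega / (2.0 * np.pi) * 86400.0
    return float(seconds) if np.isscalar(day_of_year) else seconds


@dataclass(frozen=True)
class WeatherSeries:
    """A contiguous daily weather record for one site and season.

    ``data`` holds one row per day with columns ``date``, ``das`` (days
    after sprouting), ``doy``, ``tmin``, ``tmax``, ``radiation``,
    ``day_length`` and optionally ``rainfall``.
    """

    data: pd.DataFrame = field(repr=False)
    latitude: float = 43.668

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise VitisimError(f"weather table missing columns: {missing}")
        dates = pd.to_datetime(df["date"])
        deltas = dates.diff().dropna()
        if len(df) > 1 and not (deltas == pd.Timedelta(days=1)).all():
            raise VitisimError("weather dates must be strictly increasing daily with no gaps")
        if (df["tmin"] > df["tmax"]).any():
            raise VitisimError("tmin exceeds tmax on at least one day")
        if (df["radiation"] < 0).any():
            raise VitisimError("negative radiation")
        if not -LAT_LIMIT <= self.latitude <= LAT_LIMIT:
            raise PolarLatitudeError(f"latitude {self.latitude} outside supported band")
        dl = df["day_length"]
        if ((dl <= 0) | (dl >= 86_400)).any():
            raise VitisimError("day_length must lie in (0, 86400) seconds")

    @property
    def tmean(self) -> pd.Series:
        return (self.data["tmin"] + self.data["tmax"]) / 2.0

    def __len__(self) -> int:
        return len(self.data)


def make_weather_series(
    df: pd.DataFrame, latitude: float, sprouting: _dt.date | str | None = None
) -> WeatherSeries:
    """Normalise a raw weather frame into a :class:`WeatherSeries`.

    Adds ``doy``, ``das`` and (if absent) a derived ``day_length`` column.
    ``das`` counts days from ``sprouting`` (default: the first table row).
    """
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["doy"] = df["date"].dt.dayofyear
    if sprouting is None:
        start = df["date"].iloc[0]
    else:
        start = pd.Timestamp(sprouting)
    df["das"] = (df["date"] - start).dt.days
    if "day_length" not in df.columns:
        df["day_length"] = day_length(latitude, df["doy"].to_numpy())
    return WeatherSeries(data=df.reset_index(drop=True), latitude=latitude)


def load_weather(
    path, latitude: float, sprouting: _dt.date | str | None = None
) -> WeatherSeries:
    """Read a comma-separated daily weather table.

    Expected header: ``date,tmin,tmax,radiation[,rainfall]`` with ISO-8601
    dates; ``day_length`` is computed from ``latitude`` when absent.
    """
    df = pd.read_csv(path, comment="#")
    return make_weather_series(df, latitude=latitude, sprouting=sprouting)


def gdd_winkler(
    series: WeatherSeries,
    base: float = 10.0,
    window: tuple[tuple[int, int], tuple[int, int]] = ((4, 1), (10, 31)),
) -> float:
    """Winkler growing-degree-day index, °C·day.

    Sums ``max(0, (tmin+tmax)/2 − base)`` over the days of ``series``
    falling inside the calendar ``window`` (default 1 April – 31 October).
    Days outside the window are clipped with a warning; an empty overlap is
    an error.
    """
    df = series.data
    dates = pd.to_datetime(df["date"])
    (m0, d0), (m1, d1) = window
    key = dates.dt.month * 100 + dates.dt.day
    mask = (key >= m0 * 100 + d0) & (key <= m1 * 100 + d1)
    if not mask.any():
        raise VitisimError("weather series has no overlap with the GDD window")
    if not mask.all():
        warnings.warn(
            "weather series extends outside the GDD window; clipping", stacklevel=2
        )
    tmean = (df.loc[mask, "tmin"] + df.loc[mask, "tmax"]) / 2.0
    return float(np.maximum(0.0, tmean - base).sum())


def irradiance_profile(
    radiation: float, day_length: float, n_steps: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a daily radiation total into a half-sine daylight profile.

    Returns ``(t, irradiance)`` with ``n_steps + 1`` sample points spanning
    ``[0, day_length]`` seconds; irradiance in W m⁻².  The trapezoid
    integral of the profile equals ``radiation`` (MJ m⁻²) to within the
    quadrature error of the sine, below 0.1% for ``n_steps ≥ 48``.
    """
    if day_length <= 0:
        raise VitisimError("day_length must be positive")
    if n_steps < 4:
        raise VitisimError("n_steps must be at least 4")
    t = np.linspace(0.0, day_length, n_steps + 1)
    peak = np.pi * radiation * 1e6 / (2.0 * day_length)  # W m⁻²
    irr = peak * np.sin(np.pi * t / day_length)
    return t, irr
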