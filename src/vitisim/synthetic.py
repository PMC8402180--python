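"""Seeded synthetic seasons: weather, canopy and observations.

No field dataset accompanies the model, so every stage of the pipeline is
exercised on generated seasons that carry the statistical structure the
analysis assumes:

* **Weather** — daily mean temperature as a seasonal sinusoid plus AR(1)
  deviations; the diurnal range widens on clear days; radiation is the
  extraterrestrial envelope times a clear-sky ceiling (0.75) times a
  sampled clear-sky fraction in (0.15, 1].  Default ranges emulate a
  temperate mid-latitude (≈43.7° N) April–September season.
* **Canopy** — weekly observations with logistic leaf-area and
  shoot-surface growth that flattens at the trimming date (86 DAS),
  light interception proportional to leaf area up to a trellis-specific
  cap, a double-sigmoid cluster fresh-weight curve and a constant cluster
  count.  Two named profiles, VSP-like (vertical shoot positioning:
  smaller canopy, 16% interception cap) and SHW-like (single high wire:
  larger canopy, 18% cap), differ exactly where the two trellis systems
  differ.
* **Observations** — cumulative dry matter read off the simulated curve
  at ~8 sampling dates with multiplicative Gaussian noise, and °Brix
  generated from a true linear law on dry matter plus additive noise at
  ~10 post-veraison dates.

One :class:`numpy.random.Generator` seeded from ``SyntheticConfig.seed``
is threaded through all three generators, so a season is a single
reproducible object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon_balance import CarbonBalanceParams, simulate_season
from .errors import VitisimError
from .sugar_model import BrixObservation
from .vine_state import CanopyObservation, interpolate_canopy
from .weather import WeatherSeries, day_length

__all__ = [
    "TrellisProfile",
    "SyntheticConfig",
    "PROFILES",
    "generate_weather",
    "generate_canopy",
    "generate_observations",
    "generate_season",
]


@dataclass(frozen=True)
class TrellisProfile:
    """Caps that distinguish the two trellis systems."""

    name: str
    leaf_area_cap: float  # m2 main leaf area per vine
    lateral_cap: float  # m2 lateral leaf area per vine
    shoot_cap: float  # m2 shoot surface per vine
    li_cap: float  # max PAR interception fraction
    cluster_weight_cap: float  # g per cluster at harvest
    clusters_per_vine: float


PROFILES: dict[str, TrellisProfile] = {
    "vsp": TrellisProfile("vsp", 3.6, 1.6, 0.16, 0.16, 250.0, 10.2),
    "shw": TrellisProfile("shw", 4.0, 1.2, 0.25, 0.18, 300.0, 9.2),
}

#: Trimming day: canopy growth flattens here (days after sprouting).
TRIM_DAS = 86
#: Approximate veraison (onset of ripening); Brix sampling starts here.
VERAISON_DAS = 105


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic season.

    Temperature: ``tmean = temp_mean − temp_amplitude·cos(2π(doy−15)/365)``
    plus an AR(1) process (sd ``ar1_sd`` °C, autocorrelation ``ar1_phi``).
    Cloudiness: clear-sky fraction ``1 − cloud_depletion·Beta(a, b)``.
    """

    seed: int = 0
    n_days: int = 165
    latitude: float = 43.668
    start_doy: int = 91  # 1 April
    temp_mean: float = 18.5
    temp_amplitude: float = 6.5
    ar1_sd: float = 2.0
    ar1_phi: float = 0.7
    dtr_base: float = 7.0  # diurnal range, °C, fully overcast
    dtr_clear: float = 6.0  # extra range on a perfectly clear day
    dtr_noise_sd: float = 0.8
    cloud_depletion: float = 0.85
    cloud_beta: tuple[float, float] = (1.2, 3.5)
    clear_sky_fraction: float = 0.75  # of extraterrestrial radiation
    profile: str = "vsp"
    canopy_jitter_sd: float = 0.03  # lognormal sd of the per-season size factor
    dm_noise_frac: float = 0.05
    brix_noise_sd: float = 0.4
    brix_slope: float = 0.013  # °Brix per g DM, true law
    brix_intercept: float = 9.0  # °Brix (harvest ≈ 23 °Brix at ~1 kg DM)
    n_dm_obs: int = 8
    n_brix_obs: int = 10

    def __post_init__(self) -> None:
        for name in ("ar1_sd", "dtr_noise_sd", "dm_noise_frac", "brix_noise_sd",
                     "canopy_jitter_sd"):
            if getattr(self, name) < 0:
                raise VitisimError(f"{name} must be non-negative")
        if self.profile not in PROFILES:
            raise VitisimError(f"unknown profile {self.profile!r}; choose from {list(PROFILES)}")
        if not 0.0 <= self.cloud_depletion < 1.0:
            raise VitisimError("cloud_depletion must lie in [0, 1)")

    @property
    def trellis(self) -> TrellisProfile:
        return PROFILES[self.profile]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _extraterrestrial_radiation(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Daily extraterrestrial radiation Ra, MJ m⁻² day⁻¹ (FAO-56 form)."""
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    return (24.0 * 60.0 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )


def generate_weather(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> WeatherSeries:
    """Generate one season of daily weather as a :class:`WeatherSeries`."""
    if rng is None:
        rng = config.rng()
    n = config.n_days
    das = np.arange(n)
    doy = (config.start_doy - 1 + das) % 365 + 1

    base = config.temp_mean - config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - 15) / 365.0
    )
    eps = np.zeros(n)
    if config.ar1_sd > 0:
        innov_sd = config.ar1_sd * np.sqrt(1.0 - config.ar1_phi**2)
        innov = rng.normal(0.0, innov_sd, n)
        eps[0] = rng.normal(0.0, config.ar1_sd)
        for i in range(1, n):
            eps[i] = config.ar1_phi * eps[i - 1] + innov[i]
    tmean = base + eps

    a, b = config.cloud_beta
    clear = 1.0 - config.cloud_depletion * rng.beta(a, b, n)
    dtr = config.dtr_base + config.dtr_clear * clear
    if config.dtr_noise_sd > 0:
        dtr = dtr + rng.normal(0.0, config.dtr_noise_sd, n)
    dtr = np.maximum(dtr, 2.0)

    ra = _extraterrestrial_radiation(config.latitude, doy.astype(float))
    radiation = config.clear_sky_fraction * ra * clear

    start = pd.Timestamp("2020-01-01") + pd.Timedelta(days=config.start_doy - 1)
    dates = pd.date_range(start, periods=n, freq="D")
    df = pd.DataFrame(
        {
            "date": dates,
            "das": das,
            "doy": doy,
            "tmin": tmean - dtr / 2.0,
            "tmax": tmean + dtr / 2.0,
            "radiation": radiation,
            "rainfall": np.where(clear < 0.45, rng.gamma(1.5, 4.0, n), 0.0),
            "day_length": day_length(config.latitude, doy),
        }
    )
    return WeatherSeries(data=df, latitude=config.latitude)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_canopy(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[CanopyObservation]:
    """Generate weekly canopy observations for one trellis profile."""
    if rng is None:
        rng = config.rng()
    prof = config.trellis
    das = np.arange(7, config.n_days, 7)
    grown = np.minimum(das, TRIM_DAS).astype(float)  # no regrowth after trimming

    size_factor = float(np.exp(rng.normal(0.0, config.canopy_jitter_sd))) \
        if config.canopy_jitter_sd > 0 else 1.0

    la = prof.leaf_area_cap * _sigmoid((grown - 45.0) / 12.0) * size_factor
    lateral = prof.lateral_cap * _sigmoid((grown - 60.0) / 15.0) * size_factor
    shoot = prof.shoot_cap * _sigmoid((grown - 45.0) / 12.0) * size_factor
    li = prof.li_cap * la / la.max()
    cw = prof.cluster_weight_cap * (
        0.35 * _sigmoid((das - 55.0) / 7.0) + 0.65 * _sigmoid((das - 110.0) / 9.0)
    )
    length = 10.0 + 140.0 * _sigmoid((grown - 45.0) / 12.0)

    return [
        CanopyObservation(
            das=int(d),
            shoot_surface=float(shoot[i]),
            leaf_area=float(la[i]),
            lateral_leaf_area=float(lateral[i]),
            cluster_weight=float(cw[i]),
            clusters=prof.clusters_per_vine,
            light_interception=float(li[i]),
            shoot_length=float(length[i]),
        )
        for i, d in enumerate(das)
    ]


def generate_observations(
    config: SyntheticConfig,
    weather: WeatherSeries,
    canopy_obs: list[CanopyObservation],
    params: CarbonBalanceParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[int, float]], list[BrixObservation]]:
    """Sample noisy dry-matter and °Brix observations from a simulation.

    Dry matter: the simulated ``dm_cumulative`` at ``n_dm_obs`` evenly
    spread dates, times ``1 + N(0, dm_noise_frac)``.  Brix: the true
    linear law ``intercept + slope·DM`` plus ``N(0, brix_noise_sd)`` at
    ``n_brix_obs`` post-veraison dates.
    """
    if rng is None:
        rng = config.rng()
    if params is None:
        params = CarbonBalanceParams()
    daily = interpolate_canopy(canopy_obs, range(config.n_days))
    result = simulate_season(weather, daily, params)
    sim = result.set_index("das")["dm_cumulative"]

    dm_das = np.linspace(21, config.n_days - 2, config.n_dm_obs).astype(int)
    dm_true = sim.loc[dm_das].to_numpy()
    dm_noise = rng.normal(0.0, config.dm_noise_frac, len(dm_das)) \
        if config.dm_noise_frac > 0 else np.zeros(len(dm_das))
    dm_obs = [(int(d), float(v)) for d, v in zip(dm_das, dm_true * (1.0 + dm_noise))]

    brix_das = np.linspace(VERAISON_DAS, config.n_days - 1, config.n_brix_obs).astype(int)
    brix_true = config.brix_intercept + config.brix_slope * sim.loc[brix_das].to_numpy()
    noise = rng.normal(0.0, config.brix_noise_sd, len(brix_das)) \
        if config.brix_noise_sd > 0 else np.zeros(len(brix_das))
    brix_obs = [
        BrixObservation(das=int(d), brix=float(np.clip(v, 0.0, 35.0)))
        for d, v in zip(brix_das, brix_true + noise)
    ]
    return dm_obs, brix_obs


def generate_season(
    config: SyntheticConfig, params: CarbonBalanceParams | None = None
) -> dict:
    """Generate a full reproducible season bundle.

    Returns a dict with keys ``weather`` (WeatherSeries), ``canopy_obs``
    (weekly observations), ``canopy`` (daily state), ``dm_obs`` and
    ``brix_obs``, all drawn from one seeded random stream.
    """
    rng = config.rng()
    weather = generate_weather(config, rng)
    canopy_obs = generate_canopy(config, rng)
    dm_obs, brix_obs = generate_observations(config, weather, canopy_obs, params, rng)
    return {
        "weather": weather,
        "canopy_obs": canopy_obs,
        "canopy": interpolate_canopy(canopy_obs, range(config.n_days)),
        "dm_obs": dm_obs,
        "brix_obs": brix_obs,
    }
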