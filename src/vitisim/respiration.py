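"""Organ respiration sub-module.

Daily respiratory CO₂ loss per vine (g CO₂ vine⁻¹ day⁻¹) as an Arrhenius
temperature response of each organ pool.  Shoot-surface and cluster terms
are maintenance respiration (reference rates at 20 °C, scaled by the
Arrhenius factor); new leaf area costs a fixed growth-respiration charge
per m² of new tissue, independent of temperature.

The day is split into a daylight phase at ``T_day = (tmax + tmean)/2``
and a night phase at ``T_night = (tmin + tmean)/2``, weighted by the
day-length fraction — the natural use of the day-length input this
sub-module receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VitisimError

__all__ = ["RespirationParams", "arrhenius_factor", "daily_respiration"]

R_GAS = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class RespirationParams:
    """Reference rates at 20 °C and the Arrhenius activation energy.

    r20_shoot
        g CO₂ per m² shoot surface per day at 20 °C.
    r20_cluster
        g CO₂ per g cluster fresh weight per day at 20 °C.
    growth_coeff
        g CO₂ per m² of newly grown leaf area (temperature-independent).
    ea
        Activation energy, J mol⁻¹.  The default 51,200 gives Q10 ≈ 2
        between 20 and 30 °C.
    t_ref
        Reference temperature, K.
    """

    r20_shoot: float = 1.0
    r20_cluster: float = 1.0e-3
    growth_coeff: float = 5.0
    ea: float = 51_200.0
    t_ref: float = 293.15

    def __post_init__(self) -> None:
        for name in ("r20_shoot", "r20_cluster", "growth_coeff", "ea"):
            if getattr(self, name) < 0:
                raise VitisimError(f"{name} must be non-negative")
        if self.t_ref <= 0:
            raise VitisimError("t_ref must be a positive absolute temperature")


def arrhenius_factor(t_celsius, ea: float, t_ref: float = 293.15):
    """Arrhenius rate multiplier relative to ``t_ref``.

    ``exp[(ea/R)·(1/t_ref − 1/T)]``; equals 1 at T = t_ref and for ea = 0.
    Vectorised over ``t_celsius``.
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -273.15):
        raise VitisimError("temperature at or below absolute zero")
    t_k = t + 273.15
    out = np.exp((ea / R_GAS) * (1.0 / t_ref - 1.0 / t_k))
    return float(out) if np.isscalar(t_celsius) else out


def daily_respiration(
    tmin,
    tmax,
    day_length,
    shoot_surface,
    cluster_weight,
    clusters_per_vine,
    leaf_area_increment,
    params: RespirationParams,
):
    """Daily total respiration per vine, g CO₂ vine⁻¹ day⁻¹.

    ``R = (r20_shoot·A_shoot + r20_cluster·w_cluster·n_cluster)·w(T)
    + growth_coeff·ΔLA`` with the day/night-weighted Arrhenius factor
    ``w(T)``.  All organ arguments are per vine; vectorised over days.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    dl = np.asarray(day_length, float)
    tmean = (tmin + tmax) / 2.0
    day_frac = dl / 86_400.0
    w = day_frac * arrhenius_factor((tmax + tmean) / 2.0, params.ea, params.t_ref) + (
        1.0 - day_frac
    ) * arrhenius_factor((tmin + tmean) / 2.0, params.ea, params.t_ref)
    maintenance = (
        params.r20_shoot * np.asarray(shoot_surface, float)
        + params.r20_cluster
        * np.asarray(cluster_weight, float)
        * np.asarray(clusters_per_vine, float)
    )
    out = maintenance * w + params.growth_coeff * np.asarray(leaf_area_increment, float)
    return float(out) if out.ndim == 0 else out
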