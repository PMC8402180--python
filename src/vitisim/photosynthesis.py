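"""Canopy photosynthesis sub-module.

Daily gross assimilation per vine (g CO₂ vine⁻¹ day⁻¹) from a
light-response model scaled to the canopy.

The leaf response is a rectangular hyperbola with initial slope α
(quantum yield, µg CO₂ J⁻¹) saturating at ``P_max`` (g CO₂ m⁻² leaf s⁻¹).
Canopy assimilation integrates that response over leaves receiving
Beer–Lambert-attenuated irradiance ``I·e^{−K·ℓ}`` down cumulative leaf
area ℓ, which has the closed form

    P_c(I) = (P_max / K) · ln[(α′KI + P_max) / (α′KI·e^{−KL} + P_max)]

per m² of ground, with α′ = α·10⁻⁶ g J⁻¹ and effective leaf-area index
``L = −ln(1 − LI) / K`` inverted from the measured light-interception
fraction LI.  Daily totals integrate P_c over a half-sine irradiance
profile and are modulated by a piecewise-quadratic temperature factor on
the daily mean temperature (0 at ``t_base`` and ``t_ceiling``, 1 at
``t_opt``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VitisimError
from .weather import irradiance_profile

__all__ = [
    "PhotosynthesisParams",
    "leaf_light_response",
    "effective_lai",
    "canopy_instantaneous",
    "temperature_factor",
    "daily_photosynthesis",
]


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Leaf and canopy parameters of the photosynthesis sub-module.

    pn_max
        Light-saturated leaf rate, g CO₂ m⁻² s⁻¹ (typical 0–0.001).
    quantum_yield
        Initial slope α of the light response, µg CO₂ J⁻¹.
    k
        Beer–Lambert light-extinction coefficient, dimensionless.
    ground_area
        Ground allotted per vine, m².
    t_base, t_opt, t_ceiling
        Temperature-response anchors, °C.
    """

    pn_max: float = 1.0e-3
    quantum_yield: float = 2.0
    k: float = 0.55
    ground_area: float = 3.6
    t_base: float = 10.0
    t_opt: float = 27.5
    t_ceiling: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pn_max <= 0.005:
            raise VitisimError("pn_max must lie in (0, 0.005] g CO2 m-2 s-1")
        if not 0.0 < self.quantum_yield <= 10.0:
            raise VitisimError("quantum_yield must lie in (0, 10] ug CO2 J-1")
        if not 0.0 < self.k <= 1.0:
            raise VitisimError("k must lie in (0, 1]")
        if self.ground_area <= 0:
            raise VitisimError("ground_area must be positive")
        if not self.t_base < self.t_opt < self.t_ceiling:
            raise VitisimError("temperature anchors must satisfy t_base < t_opt < t_ceiling")


def leaf_light_response(irradiance, alpha: float, pn_max: float):
    """Rectangular-hyperbola leaf assimilation, g CO₂ m⁻² leaf s⁻¹.

    ``P = α′·I·P_max / (α′·I + P_max)`` with α in µg CO₂ J⁻¹ and I in
    W m⁻².  Vectorised over ``irradiance``.
    """
    a = alpha * 1e-6
    i = np.asarray(irradiance, dtype=float)
    out = a * i * pn_max / (a * i + pn_max)
    return float(out) if np.isscalar(irradiance) else out


def effective_lai(light_interception, k: float):
    """Effective leaf-area index from intercepted-light fraction.

    Beer–Lambert inversion ``L = −ln(1 − LI) / K``; LI = 1 would imply an
    infinitely deep canopy and is rejected.
    """
    li = np.asarray(light_interception, dtype=float)
    if np.any((li < 0) | (li >= 1)):
        raise VitisimError("light_interception must lie in [0, 1)")
    out = -np.log1p(-li) / k
    return float(out) if np.isscalar(light_interception) else out


def canopy_instantaneous(irradiance, params: PhotosynthesisParams, light_interception):
    """Instantaneous canopy assimilation, g CO₂ m⁻² ground s⁻¹.

    Closed-form integral of the leaf light response over the
    Beer–Lambert-attenuated irradiance profile within the canopy.
    Vectorised over ``irradiance`` and ``light_interception`` jointly.
    """
    lai = effective_lai(light_interception, params.k)
    a = params.quantum_yield * 1e-6
    i = np.asarray(irradiance, dtype=float)
    aki = a * params.k * i
    num = aki + params.pn_max
    den = aki * np.exp(-params.k * lai) + params.pn_max
    out = (params.pn_max / params.k) * np.log(num / den)
    scalar = np.isscalar(irradiance) and np.isscalar(light_interception)
    return float(out) if scalar else out


def temperature_factor(tmean, params: PhotosynthesisParams):
    """Dimensionless temperature modifier of daily photosynthesis, in [0, 1].

    Inverted-parabola branches on each side of the optimum::

        f = 1 − ((T − t_opt)/(t_opt − t_base))²      t_base < T ≤ t_opt
        f = 1 − ((T − t_opt)/(t_ceiling − t_opt))²   t_opt < T < t_ceiling

    and 0 outside (t_base, t_ceiling).  Continuous in T.
    """
    t = np.asarray(tmean, dtype=float)
    width = np.where(t <= params.t_opt, params.t_opt - params.t_base,
                     params.t_ceiling - params.t_opt)
    f = 1.0 - ((t - params.t_opt) / width) ** 2
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.isscalar(tmean) else f


def daily_photosynthesis(
    tmean: float,
    radiation: float,
    day_length: float,
    light_interception: float,
    params: PhotosynthesisParams,
    n_steps: int = 48,
) -> float:
    """Daily gross photosynthesis per vine, g CO₂ vine⁻¹ day⁻¹.

    Trapezoid integration of :func:`canopy_instantaneous` over the
    half-sine irradiance profile, scaled by ground area and the
    temperature factor.
    """
    if radiation == 0 or light_interception == 0:
        return 0.0
    t, irr = irradiance_profile(radiation, day_length, n_steps)
    pc = canopy_instantaneous(irr, params, light_interception)
    integral = np.trapezoid(pc, t)  # g CO2 m-2 ground day-1
    return float(params.ground_area * temperature_factor(tmean, params) * integral)


def _daily_photosynthesis_vec(
    tmean: np.ndarray,
    radiation: np.ndarray,
    day_length: np.ndarray,
    light_interception: np.ndarray,
    params: PhotosynthesisParams,
    n_steps: int = 48,
) -> np.ndarray:
    """Vectorised daily totals for a whole season (days × sub-steps)."""
    tmean = np.asarray(tmean, float)
    radiation = np.asarray(radiation, float)
    dl = np.asarray(day_length, float)
    li = np.asarray(light_interception, float)
    frac = np.linspace(0.0, 1.0, n_steps + 1)  # fraction of daylight
    peak = np.pi * radiation * 1e6 / (2.0 * dl)
    irr = peak[:, None] * np.sin(np.pi * frac)[None, :]

    lai = effective_lai(li, params.k)
    a = params.quantum_yield * 1e-6
    aki = a * params.k * irr
    num = aki + params.pn_max
    den = aki * np.exp(-params.k * lai)[:, None] + params.pn_max
    pc = (params.pn_max / params.k) * np.log(num / den)
    integral = np.trapezoid(pc, dx=1.0 / n_steps, axis=1) * dl
    return params.ground_area * temperature_factor(tmean, params) * integral
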