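"""Daily vine-description trajectories from weekly field observations.

The simulation runs at a daily time step but the vine is described weekly
(organ sizes, light interception).  This module interpolates the weekly
observations to a daily :class:`CanopyState` table, derives the daily leaf
area increment consumed by growth respiration, and provides the
vein-length allometry used to estimate total leaf area in the field.

Interpolation rules: sizes and light interception are piecewise linear
between observations, ramp linearly from zero at DAS 0 before the first
observation, and are held constant after the last one.  Cluster counts are
held piecewise-constant at the nearest prior observation (counts do not
interpolate physically).

Lateral leaf area is carried as data but deliberately excluded from the
photosynthesis pathway: the model's light-interception input is measured
on the whole canopy, while the simulated assimilating surface follows the
main-leaf trajectory only.  This mirrors the known tendency of the model
to underestimate dry matter in canopies with a large lateral share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import VitisimError

__all__ = [
    "CanopyObservation",
    "interpolate_canopy",
    "leaf_area_increment",
    "estimate_total_leaf_area",
    "load_canopy",
]

#: CanopyState columns interpolated piecewise-linearly.
_LINEAR_FIELDS = (
    "shoot_surface",
    "leaf_area",
    "lateral_leaf_area",
    "cluster_weight",
    "light_interception",
)


@dataclass(frozen=True)
class CanopyObservation:
    """One weekly vine description.

    Sizes are per vine: shoot surface and leaf areas in m², cluster fresh
    weight in g per cluster, ``clusters`` per vine (may be a fractional
    block mean), ``light_interception`` as a PAR fraction in [0, 1].
    """

    das: int
    shoot_surface: float
    leaf_area: float
    lateral_leaf_area: float
    cluster_weight: float
    clusters: float
    light_interception: float
    shoot_length: float = float("nan")

    def __post_init__(self) -> None:
        if self.das < 0:
            raise VitisimError("das must be non-negative")
        for name in ("shoot_surface", "leaf_area", "lateral_leaf_area",
                     "cluster_weight", "clusters"):
            if getattr(self, name) < 0:
                raise VitisimError(f"{name} must be non-negative")
        if not 0.0 <= self.light_interception <= 1.0:
            raise VitisimError("light_interception must lie in [0, 1]")


def interpolate_canopy(
    observations: Sequence[CanopyObservation], das_range: Iterable[int]
) -> pd.DataFrame:
    """Interpolate weekly observations to a daily canopy-state table.

    Returns a DataFrame indexed by DAS with the observation fields plus
    ``leaf_area_increment`` (m² day⁻¹, first difference clamped at zero).
    """
    if len(observations) < 2:
        raise VitisimError("need at least 2 canopy observations")
    das_obs = np.array([o.das for o in observations], dtype=float)
    if np.any(np.diff(das_obs) <= 0):
        raise VitisimError("observation das must be strictly increasing")
    days = np.asarray(list(das_range), dtype=float)
    if days.size == 0:
        raise VitisimError("empty das_range")

    state: dict[str, np.ndarray] = {}
    for name in _LINEAR_FIELDS:
        y = np.array([getattr(o, name) for o in observations], dtype=float)
        # anchor a zero at DAS 0 so pre-observation days ramp from nothing
        if das_obs[0] > 0:
            xs = np.concatenate([[0.0], das_obs])
            ys = np.concatenate([[0.0], y])
        else:
            xs, ys = das_obs, y
        state[name] = np.interp(days, xs, ys)

    counts = np.array([o.clusters for o in observations], dtype=float)
    idx = np.searchsorted(das_obs, days, side="right") - 1
    state["clusters"] = counts[np.clip(idx, 0, len(counts) - 1)]

    df = pd.DataFrame(state, index=pd.Index(days.astype(int), name="das"))
    df["leaf_area_increment"] = leaf_area_increment(df["leaf_area"].to_numpy())
    return df


def leaf_area_increment(leaf_area: np.ndarray) -> np.ndarray:
    """Daily new leaf area, m² day⁻¹: first difference clamped at zero."""
    la = np.asarray(leaf_area, dtype=float)
    inc = np.diff(la, prepend=la[:1])
    return np.maximum(inc, 0.0)


def estimate_total_leaf_area(
    main_vein_lengths: Sequence[float], coefficient: float
) -> float:
    """Total vine leaf area (m²) from main-vein lengths (cm).

    Uses the quadratic allometry ``area_i = coefficient · L_i²`` (cm²) and
    sums over leaves.  The coefficient is a cultivar calibration the user
    must supply.
    """
    if coefficient <= 0:
        raise VitisimError("coefficient must be positive")
    lengths = np.asarray(list(main_vein_lengths), dtype=float)
    if lengths.size == 0:
        return 0.0
    if np.any(lengths < 0):
        raise VitisimError("vein lengths must be non-negative")
    return float(coefficient * np.sum(lengths**2) / 1e4)


def load_canopy(path) -> list[CanopyObservation]:
    """Read a weekly vine-description table.

    Expected header:
    ``das,shoot_surface,leaf_area,lateral_leaf_area,cluster_weight,clusters,light_interception[,shoot_length]``.
    """
    df = pd.read_csv(path, comment="#")
    obs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        obs.append(
            CanopyObservation(
                das=int(d["das"]),
                shoot_surface=float(d["shoot_surface"]),
                leaf_area=float(d["leaf_area"]),
                lateral_leaf_area=float(d["lateral_leaf_area"]),
                cluster_weight=float(d["cluster_weight"]),
                clusters=float(d["clusters"]),
                light_interception=float(d["light_interception"]),
                shoot_length=float(d.get("shoot_length", float("nan"))),
            )
        )
    return obs
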