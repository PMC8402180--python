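"""Run configuration: one YAML file describing a whole simulation run.

The file carries the site (latitude, ground area), season calendar,
parameter blocks for the photosynthesis / respiration / carbon-balance
stages, input file paths, scenario cluster counts and the seed.  A SHA-256
digest of the resolved configuration is embedded in every output file so
result tables are traceable to the exact parameterisation that produced
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .carbon_balance import CarbonBalanceParams
from .errors import VitisimError
from .photosynthesis import PhotosynthesisParams
from .respiration import RespirationParams

__all__ = ["RunConfig", "load_config", "config_digest"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one pipeline run."""

    latitude: float = 43.668
    sprouting: str | None = None  # ISO date; default: first weather row
    weather_path: str | None = None
    canopy_path: str | None = None
    dm_obs_path: str | None = None
    brix_obs_path: str | None = None
    params: CarbonBalanceParams = field(default_factory=CarbonBalanceParams)
    scenario_clusters: tuple[float, ...] = (6.0, 12.0)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario_clusters"] = list(self.scenario_clusters)
        return d


def _build_params(raw: dict) -> CarbonBalanceParams:
    photo = PhotosynthesisParams(**raw.get("photosynthesis", {}))
    resp = RespirationParams(**raw.get("respiration", {}))
    kwargs = {
        k: raw[k] for k in ("co2_to_dm", "n_steps") if k in raw
    }
    return CarbonBalanceParams(photosynthesis=photo, respiration=resp, **kwargs)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise VitisimError(f"configuration file {path} is not a mapping")
    params = _build_params(raw.get("params", {}))
    known = {
        k: raw[k]
        for k in (
            "latitude", "sprouting", "weather_path", "canopy_path",
            "dm_obs_path", "brix_obs_path", "seed",
        )
        if k in raw
    }
    if "scenario_clusters" in raw:
        known["scenario_clusters"] = tuple(float(c) for c in raw["scenario_clusters"])
    known.update(overrides)
    return RunConfig(params=params, **known)


def config_digest(config: RunConfig) -> str:
    """Short stable SHA-256 digest of the resolved configuration."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
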