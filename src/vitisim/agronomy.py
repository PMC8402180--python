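"""Per-vine yield arithmetic and treatment comparisons.

Cluster weight (yield / cluster number), the Ravaz index (yield / pruning
weight, a crop-load balance indicator) and signed percent differences
between treatment means.  Ratios are computed per vine and then averaged
(group-mean ratios differ when vines vary and are offered as a flagged
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import VitisimError

__all__ = [
    "VineYieldRecord",
    "cluster_weight",
    "ravaz_index",
    "percent_difference",
    "summarize_treatment",
]


@dataclass(frozen=True)
class VineYieldRecord:
    """Harvest record for one vine: yield (kg), cluster count, optional
    pruning weight (kg)."""

    vine: str
    yield_kg: float
    cluster_count: float
    pruning_weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.yield_kg < 0 or self.cluster_count < 0:
            raise VitisimError("yield and cluster count must be non-negative")
        if self.pruning_weight_kg is not None and self.pruning_weight_kg < 0:
            raise VitisimError("pruning weight must be non-negative")


def cluster_weight(record: VineYieldRecord) -> float:
    """Mean cluster weight in grams: 1000 · yield / cluster count."""
    if record.cluster_count == 0:
        raise VitisimError(f"vine {record.vine}: zero clusters")
    return 1000.0 * record.yield_kg / record.cluster_count


def ravaz_index(record: VineYieldRecord) -> float:
    """Yield-to-pruning-weight ratio (dimensionless)."""
    if record.pruning_weight_kg is None or record.pruning_weight_kg <= 0:
        raise VitisimError(f"vine {record.vine}: missing or zero pruning weight")
    return record.yield_kg / record.pruning_weight_kg


def percent_difference(treatment_mean: float, reference_mean: float) -> float:
    """Signed percent difference, 100·(treatment − reference)/reference."""
    if reference_mean == 0:
        raise VitisimError("reference mean is zero")
    return 100.0 * (treatment_mean - reference_mean) / reference_mean


def summarize_treatment(
    records: Sequence[VineYieldRecord], per_vine: bool = True
) -> dict[str, float]:
    """Treatment-level means of yield, cluster weight and Ravaz index.

    With ``per_vine=True`` (default) ratios are computed per vine then
    averaged; otherwise ratios of group means are reported.
    """
    if not records:
        raise VitisimError("no records")
    yields = np.array([r.yield_kg for r in records])
    counts = np.array([r.cluster_count for r in records])
    prunings = [r.pruning_weight_kg for r in records]
    out: dict[str, float] = {
        "n": float(len(records)),
        "yield_kg": float(yields.mean()),
        "cluster_count": float(counts.mean()),
    }
    if per_vine:
        out["cluster_weight_g"] = float(
            np.mean([cluster_weight(r) for r in records])
        )
        if all(p is not None for p in prunings):
            out["ravaz_index"] = float(np.mean([ravaz_index(r) for r in records]))
    else:
        if counts.mean() == 0:
            raise VitisimError("zero mean cluster count")
        out["cluster_weight_g"] = 1000.0 * float(yields.mean()) / float(counts.mean())
        if all(p is not None for p in prunings):
            out["ravaz_index"] = float(yields.mean()) / float(np.mean(prunings))
    return out
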