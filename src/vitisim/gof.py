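"""Goodness-of-fit indicators for observed-vs-simulated comparisons.

Four indicators: r² (squared Pearson correlation), mean absolute error
(MAE, units of the variable), relative root-mean-square error (RRMSE,
RMSE divided by the observed mean, dimensionless) and percentage bias

    PBIAS = 100 · Σ(Oᵢ − Pᵢ) / ΣOᵢ

Sign convention: PBIAS is positive when the model underestimates the
observations — a model that under-predicts dry matter reports a positive
percentage bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import VitisimError

__all__ = ["GofReport", "evaluate"]


@dataclass(frozen=True)
class GofReport:
    r2: float
    mae: float
    rrmse: float
    pbias: float  # percent; positive = model underestimates

    def __str__(self) -> str:  # CLI-friendly rendering
        return (
            f"R2    {self.r2:.4f}\n"
            f"MAE   {self.mae:.4f}\n"
            f"RRMSE {self.rrmse:.4f}\n"
            f"PBIAS {self.pbias:+.2f}%"
        )


def evaluate(observed, predicted) -> GofReport:
    """Compute the four indicators for paired observed/predicted vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise VitisimError("observed and predicted must be equal-length 1-D vectors")
    n = obs.size
    if n < 2:
        raise VitisimError("need at least 2 paired values")
    if np.ptp(obs) == 0:
        raise VitisimError("observed values are constant; r2 undefined")
    mean_obs = obs.mean()
    if mean_obs == 0:
        raise VitisimError("observed mean is zero; RRMSE and PBIAS undefined")
    if np.ptp(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(obs, pred).statistic ** 2)
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    rrmse = float(np.sqrt(np.mean(err**2)) / mean_obs)
    pbias = float(100.0 * np.sum(obs - pred) / np.sum(obs))
    return GofReport(r2=r2, mae=mae, rrmse=rrmse, pbias=pbias)
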