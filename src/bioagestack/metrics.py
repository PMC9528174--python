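"""Fit metrics shared by the BA model zoo: RMSE, R², MAE, Pearson r with CI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["FitMetrics", "regression_metrics", "pearson_ci"]


@dataclass(frozen=True)
class FitMetrics:
    model_tag: str
    partition: str        # train | test | full
    rmse: float
    r2: float
    mae: float
    pearson_r: float
    r_ci_low: float
    r_ci_high: float

    def __post_init__(self) -> None:
        if not np.isnan(self.rmse) and self.rmse + 1e-12 < self.mae:
            raise ValueError("rmse cannot be below mae")
        if not np.isnan(self.pearson_r) and not (-1.0 <= self.pearson_r <= 1.0):
            raise ValueError("pearson_r out of range")


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + level / 2.0)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def regression_metrics(y: np.ndarray, yhat: np.ndarray, model_tag: str,
                       partition: str) -> FitMetrics:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    if y.std() == 0 or yhat.std() == 0:
        r = float("nan")      # degenerate: constant target or prediction
        lo = hi = float("nan")
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
        lo, hi = pearson_ci(r, len(y))
    return FitMetrics(model_tag, partition, rmse, r2, mae, r, lo, hi)
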