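"""Shared metric kernel for the regression grid and the network evaluation.

Two RMSE conventions coexist in this package, because growth-model
construction tables and validation tables in the agronomic literature
often use different ones:

* construction ("dof") RMSE  = sqrt(SSE / (n - p - 1)), a residual
  standard error that accounts for the p fitted features, and
* validation ("plain") RMSE  = sqrt(MSE) = sqrt(SSE / n).

Both are exposed explicitly; nothing in this module guesses which one a
caller wants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricReport",
    "score",
    "adjusted_r2",
    "rmse_from_sse",
    "rmse_from_mse",
    "construction_metrics",
    "validation_metrics",
]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class MetricReport:
    """Five-metric prediction report: R², RMSE, MSE, MAE and MAPE (percent).

    ``mape`` is NaN when any target value is exactly zero (the ratio is
    undefined there); the other four metrics are always populated.
    """

    r2: float
    rmse: float
    mse: float
    mae: float
    mape: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mse": self.mse,
            "mae": self.mae,
            "mape": self.mape,
        }


def _validate_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise MetricError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise MetricError("need at least 2 observations")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SSE/SST.

    May be negative out of sample. Raises :class:`MetricError` on a
    constant target (SST = 0).
    """
    y, yhat = _validate_pair(y, yhat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise MetricError("R^2 undefined: target has zero total sum of squares")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise MetricError(f"adjusted R^2 needs n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse_from_sse(sse: float, n: int, p: int) -> float:
    """Residual standard error sqrt(SSE/(n-p-1)) — construction-table RMSE."""
    if n <= p + 1:
        raise MetricError(f"dof-corrected RMSE needs n > p + 1 (got n={n}, p={p})")
    if sse < 0:
        raise MetricError("SSE must be nonnegative")
    return float(np.sqrt(sse / (n - p - 1)))


def rmse_from_mse(mse: float) -> float:
    """Validation-table RMSE = sqrt(MSE)."""
    if mse < 0:
        raise MetricError("MSE must be nonnegative")
    return float(np.sqrt(mse))


def score(y, yhat) -> MetricReport:
    """Full five-metric report (R², RMSE, MSE, MAE, MAPE in percent).

    MAPE = 100 · mean(|y - ŷ| / |y|). A zero target makes MAPE undefined:
    it is reported as NaN and a warning is emitted; all other metrics are
    still returned.
    """
    y, yhat = _validate_pair(y, yhat)
    err = y - yhat
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    r2 = r_squared(y, yhat)
    if np.any(y == 0.0):
        warnings.warn(
            "MAPE undefined: target contains exact zeros; reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        mape = float("nan")
    else:
        # near-zero targets legitimately blow MAPE up; report the value
        # without numpy's overflow chatter
        with np.errstate(over="ignore", divide="ignore"):
            mape = float(100.0 * np.mean(np.abs(err) / np.abs(y)))
    return MetricReport(r2=r2, rmse=float(np.sqrt(mse)), mse=mse, mae=mae, mape=mape)


def construction_metrics(y, yhat, p: int) -> dict[str, float]:
    """Training-split metric row: SSE, dof-corrected RMSE, R², adjusted R².

    ``rmse_plain`` (sqrt(SSE/n)) is also included under its own key for
    callers that want the uncorrected convention.
    """
    y, yhat = _validate_pair(y, yhat)
    n = y.size
    sse = float(np.sum((y - yhat) ** 2))
    r2 = r_squared(y, yhat)
    return {
        "sse": sse,
        "rmse": rmse_from_sse(sse, n, p),
        "rmse_plain": float(np.sqrt(sse / n)),
        "r2": r2,
        "ar": adjusted_r2(r2, n, p),
        "n": n,
        "p": p,
    }


def validation_metrics(y, yhat, p: int) -> dict[str, float]:
    """Held-out metric row: MSE, RMSE = sqrt(MSE), R², adjusted R²."""
    y, yhat = _validate_pair(y, yhat)
    n = y.size
    mse = float(np.mean((y - yhat) ** 2))
    r2 = r_squared(y, yhat)
    return {
        "mse": mse,
        "rmse": rmse_from_mse(mse),
        "r2": r2,
        "ar": adjusted_r2(r2, n, p),
        "n": n,
        "p": p,
    }
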