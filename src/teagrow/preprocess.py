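"""NDVI reconstruction and soil-feature engineering.

Turns raw sensor logs and a per-epoch NDVI series into the aligned epoch
table the growth models consume:

* Savitzky–Golay smoothing with optional upper-envelope (max-value)
  selection to repair cloud-induced NDVI drops;
* window means of soil temperature (ST, °C), moisture content (SMC, %)
  and electrical conductivity (SEC, μs/cm) over the days preceding each
  satellite epoch;
* cumulative exposure features SST/SSMC/SSEC — running sums of positive
  daily values from season start, analogous to growing degree days;
* min–max normalization and a Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "sg_filter",
    "MinMaxParams",
    "normalize",
    "denormalize",
    "daily_means",
    "aggregate_to_epochs",
    "cumulative_features",
    "build_epoch_table",
    "correlation_matrix",
]

SOIL_COLS = ("st", "smc", "sec")
CUMULATIVE_COLS = ("sst", "ssmc", "ssec")


class PreprocessError(ValueError):
    pass


class MissingEpochError(PreprocessError):
    """No sensor readings fall inside an epoch's averaging window."""

    def __init__(self, epochs):
        self.epochs = list(epochs)
        super().__init__(f"no soil readings in the window of epochs: {self.epochs}")


# ---------------------------------------------------------------------------
# Savitzky–Golay reconstruction


def sg_filter(values, window: int = 5, order: int = 2, envelope: bool = True) -> np.ndarray:
    """Savitzky–Golay smoothing with optional upper-envelope selection.

    Each output point is the value at the window centre of the
    least-squares polynomial of degree ``order`` fitted to the
    ``window`` surrounding points — equivalently a fixed convolution
    with the S–G weights. Edges are handled by mirror padding (reflection
    without repeating the edge sample).

    With ``envelope=True`` each smoothed value is replaced by
    ``max(smoothed, original)``. Vegetation indices only drop abruptly
    through cloud or sensor artefacts, so the upper envelope of the
    smooth fit and the raw series is the standard reconstruction.

    Parameters
    ----------
    values : 1-D array-like
    window : odd int, window length (default 5)
    order : int, polynomial degree, must be < window (default 2)
    envelope : take the pointwise maximum with the raw series
    """
    y = np.asarray(values, dtype=float).ravel()
    if window % 2 == 0 or window < 1:
        raise PreprocessError(f"window must be odd and positive, got {window}")
    if order >= window:
        raise PreprocessError(f"order ({order}) must be < window ({window})")
    if y.size < window:
        raise PreprocessError(f"series length {y.size} shorter than window {window}")
    smoothed = savgol_filter(y, window_length=window, polyorder=order, mode="mirror")
    if envelope:
        return np.maximum(smoothed, y)
    return smoothed


# ---------------------------------------------------------------------------
# Normalization


@dataclass(frozen=True)
class MinMaxParams:
    """Retained scaling parameters so a normalization can be inverted."""

    vmin: float
    vmax: float

    @property
    def span(self) -> float:
        return self.vmax - self.vmin


def normalize(values, params: MinMaxParams | None = None):
    """Min–max scale to [0, 1]; returns ``(scaled, params)``.

    Pass ``params`` to reuse a previously fitted scaling (e.g. apply the
    training-split scaling to held-out data). A constant sequence cannot
    be scaled and raises.
    """
    x = np.asarray(values, dtype=float)
    if params is None:
        vmin, vmax = float(np.min(x)), float(np.max(x))
        if vmax <= vmin:
            raise PreprocessError("cannot normalize a constant sequence (max == min)")
        params = MinMaxParams(vmin, vmax)
    return (x - params.vmin) / params.span, params


def denormalize(scaled, params: MinMaxParams) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * params.span + params.vmin


# ---------------------------------------------------------------------------
# Epoch aggregation


def _as_timestamped(soil: pd.DataFrame) -> pd.DataFrame:
    if "timestamp" not in soil.columns:
        raise PreprocessError("soil series needs a 'timestamp' column")
    out = soil.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    if not out["timestamp"].is_monotonic_increasing:
        out = out.sort_values("timestamp")
    return out


def daily_means(soil: pd.DataFrame) -> pd.DataFrame:
    """Calendar-day means of ST/SMC/SEC, indexed by date (naive local time)."""
    s = _as_timestamped(soil)
    grouped = s.groupby(s["timestamp"].dt.normalize())[list(SOIL_COLS)].mean()
    grouped.index.name = "date"
    return grouped


def aggregate_to_epochs(
    soil: pd.DataFrame,
    epoch_dates: Sequence,
    window_days: int = 5,
) -> pd.DataFrame:
    """Mean ST/SMC/SEC over the ``window_days`` preceding each epoch.

    The averaging window is the half-open interval
    ``[epoch - window_days, epoch)``: the days leading up to (and not
    including) the satellite revisit date, matching a 5-day revisit
    cadence. Epochs whose window contains no readings raise
    :class:`MissingEpochError` listing them.
    """
    if window_days < 1:
        raise PreprocessError("window_days must be a positive integer")
    s = _as_timestamped(soil)
    ts = s["timestamp"].to_numpy()
    epochs = pd.to_datetime(pd.Index(epoch_dates)).normalize()
    rows, missing = [], []
    for epoch in epochs:
        lo = epoch - pd.Timedelta(days=window_days)
        mask = (ts >= lo.to_datetime64()) & (ts < epoch.to_datetime64())
        if not mask.any():
            missing.append(epoch.date())
            rows.append([np.nan] * len(SOIL_COLS))
        else:
            rows.append(s.loc[mask, list(SOIL_COLS)].mean().to_list())
    if missing:
        raise MissingEpochError(missing)
    out = pd.DataFrame(rows, columns=list(SOIL_COLS))
    out.insert(0, "date", epochs)
    return out


def cumulative_features(
    daily: pd.DataFrame,
    epoch_dates: Sequence,
    season_start=None,
) -> pd.DataFrame:
    """Cumulative SST/SSMC/SSEC at each epoch date.

    For each variable, days with a daily mean above 0 contribute their
    value to a running sum starting at ``season_start`` (default: the
    first day of the daily table); days at or below 0 contribute
    nothing. The sum at an epoch includes that epoch's own day. This is
    the growing-degree-day construction generalised to moisture and
    conductivity.
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise PreprocessError("daily table must be indexed by date (DatetimeIndex)")
    daily = daily.sort_index()
    start = pd.Timestamp(season_start) if season_start is not None else daily.index[0]
    epochs = pd.to_datetime(pd.Index(epoch_dates)).normalize()
    if (epochs < start).any():
        bad = [d.date() for d in epochs[epochs < start]]
        raise PreprocessError(f"epochs before season start {start.date()}: {bad}")
    sub = daily.loc[daily.index >= start, list(SOIL_COLS)]
    positive = sub.where(sub > 0.0, 0.0)
    running = positive.cumsum()
    # value at each epoch = last running sum at or before the epoch day
    aligned = running.reindex(running.index.union(epochs)).ffill().fillna(0.0).loc[epochs]
    out = pd.DataFrame(
        {new: aligned[old].to_numpy() for new, old in zip(CUMULATIVE_COLS, SOIL_COLS)}
    )
    out.insert(0, "date", epochs)
    return out


def build_epoch_table(
    soil: pd.DataFrame,
    ndvi: pd.DataFrame,
    window_days: int = 5,
    sg_window: int = 5,
    sg_order: int = 2,
    envelope: bool = True,
    season_start=None,
) -> pd.DataFrame:
    """Assemble the aligned per-epoch feature table.

    Columns: date, st, smc, sec (window means), sst, ssmc, ssec
    (cumulative), ndvi_raw, ndvi_filtered.
    """
    if not {"date", "ndvi"}.issubset(ndvi.columns):
        raise PreprocessError("ndvi table needs 'date' and 'ndvi' columns")
    epochs = pd.to_datetime(ndvi["date"])
    inst = aggregate_to_epochs(soil, epochs, window_days=window_days)
    cum = cumulative_features(daily_means(soil), epochs, season_start=season_start)
    table = inst.merge(cum, on="date")
    table["ndvi_raw"] = np.asarray(ndvi["ndvi"], dtype=float)
    table["ndvi_filtered"] = sg_filter(
        table["ndvi_raw"].to_numpy(), window=sg_window, order=sg_order, envelope=envelope
    )
    return table


# ---------------------------------------------------------------------------
# Correlation analysis


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix over the requested columns.

    Symmetric with a unit diagonal. A zero-variance column makes the
    correlation undefined and raises, naming the column.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(table) < 3:
        raise PreprocessError("correlation needs at least 3 complete rows")
    sub = table[cols].astype(float)
    stds = sub.std(ddof=0)
    degenerate = stds[stds == 0.0].index.tolist()
    if degenerate:
        raise PreprocessError(f"zero-variance column(s): {degenerate}")
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
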