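"""Synthetic soil-sensor and NDVI data with known ground truth.

The study system is a subtropical tea plantation instrumented with
buried soil probes (10-minute cadence) and observed by a 5-day-revisit
multispectral satellite (72 NDVI epochs per year). The real records are
not public, so this module generates series with the same statistical
structure and — crucially — a *known* growth response, enabling
parameter-recovery tests of the whole downstream pipeline.

The generative model:

* Soil temperature (ST, °C) follows an annual sinusoid (winter ≈ 13 °C,
  summer ≈ 28 °C, annual mean ≈ 20.5 °C as in a subtropical monsoon
  climate) plus a diurnal ripple and Gaussian sensor noise.
* Soil moisture (SMC, %) and conductivity (SEC, μs/cm) follow annual
  sinusoids in anti-phase with temperature (wet, salt-rich topsoil in
  the cool season), plus noise. All readings are clipped to the
  instrument ranges: ST ∈ [−40, 80] °C, SMC ∈ [0, 100] %,
  SEC ∈ [0, 5000] μs/cm.
* NDVI at each epoch is a cubic response to a *cumulative* soil
  feature (running positive-day sum, rescaled by a fixed reference
  scale), plus observation noise and sporadic cloud-induced negative
  shocks, clipped to [−1, 1].

Cloud distortion is modelled as additive negative drops rather than
missingness, because that is how cloud contamination presents in real
NDVI series: precipitous dips, not gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from . import preprocess

__all__ = [
    "SimConfig",
    "TruthParams",
    "default_truth",
    "compute_ndvi",
    "epoch_dates",
    "smooth_soil_signals",
    "simulate_soil_series",
    "simulate_ndvi_series",
]

log = logging.getLogger(__name__)

# MEC20-class probe ranges
ST_RANGE = (-40.0, 80.0)
SMC_RANGE = (0.0, 100.0)
SEC_RANGE = (0.0, 5000.0)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """One simulated site-year.

    Defaults reproduce the deployment the analysis assumes: a calendar
    year of 10-minute probe readings and 72 NDVI epochs at a 5-day
    satellite revisit. Seasonal amplitudes keep winter soil temperature
    near 13 °C and summer near 28 °C.
    """

    start_date: date = date(2020, 1, 1)
    end_date: date = date(2020, 12, 31)
    sensor_interval_minutes: float = 10.0
    epoch_interval_days: int = 5
    n_epochs: int = 72
    noise_sd_ndvi: float = 0.02
    cloud_drop_prob: float = 0.08
    cloud_drop_depth: float = 0.3
    seed: int = 0
    n_nodes: int = 1  # >1 simulates several probes averaged into one series

    # seasonal structure (annual sinusoid; phase day = coldest day of year)
    st_mean: float = 20.5
    st_amplitude: float = 7.5
    st_phase_day: int = 15
    st_diurnal_amplitude: float = 1.0
    st_noise_sd: float = 0.2
    smc_mean: float = 25.0
    smc_amplitude: float = 8.0
    smc_phase_day: int = 45  # wettest topsoil lags the coldest day
    smc_noise_sd: float = 0.5
    sec_mean: float = 120.0
    sec_amplitude: float = 60.0
    sec_phase_day: int = 5
    sec_noise_sd: float = 3.0

    def __post_init__(self):
        span_days = (self.end_date - self.start_date).days + 1
        if span_days < self.epoch_interval_days:
            raise ConfigError("date range shorter than one epoch interval")
        if self.n_epochs * self.epoch_interval_days > span_days:
            raise ConfigError(
                f"{self.n_epochs} epochs x {self.epoch_interval_days} d "
                f"exceed the {span_days}-day date range"
            )
        if self.sensor_interval_minutes <= 0:
            raise ConfigError("sensor_interval_minutes must be positive")
        if self.epoch_interval_days < 1 or self.n_epochs < 1:
            raise ConfigError("epoch_interval_days and n_epochs must be positive")
        if not 0.0 <= self.cloud_drop_prob <= 1.0:
            raise ConfigError("cloud_drop_prob must be in [0, 1]")
        if self.noise_sd_ndvi < 0 or self.cloud_drop_depth < 0:
            raise ConfigError("noise and drop depth must be nonnegative")
        if self.n_nodes < 1:
            raise ConfigError("n_nodes must be >= 1")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth NDVI response used by the generator.

    Each cumulative feature (SST, SSMC, SSEC) carries a cubic response
    ``c0 + c1 s + c2 s² + c3 s³`` on its *scaled* value
    ``s = feature / scale``, with fixed reference scales roughly equal
    to the year-end cumulative totals so that s spans ≈ [0, 1]. The
    ternary response is a degree-3 polynomial in the three scaled
    features without cross terms (10 coefficients, intercept first).
    ``response`` selects which response actually generates NDVI.
    """

    sst: tuple[float, ...] = (0.15, 1.9, -1.6, 0.4)
    ssmc: tuple[float, ...] = (0.15, 1.9, -1.6, 0.4)
    ssec: tuple[float, ...] = (0.15, 1.9, -1.6, 0.4)
    # basis: 1, s1, s2, s3, s1^2, s2^2, s3^2, s1^3, s2^3, s3^3
    ternary: tuple[float, ...] = (
        0.15, 0.65, 0.6, 0.65, -0.55, -0.5, -0.55, 0.15, 0.1, 0.15,
    )
    sst_scale: float = 7500.0
    ssmc_scale: float = 9500.0
    ssec_scale: float = 45000.0
    response: str = "sst"

    def __post_init__(self):
        if self.response not in ("sst", "ssmc", "ssec", "ternary"):
            raise ConfigError(f"unknown response {self.response!r}")
        for name in ("sst", "ssmc", "ssec"):
            if len(getattr(self, name)) != 4:
                raise ConfigError(f"{name} response needs 4 cubic coefficients")
        if len(self.ternary) != 10:
            raise ConfigError("ternary response needs 10 coefficients")

    def scaled(self, sst, ssmc, ssec):
        return (
            np.asarray(sst, float) / self.sst_scale,
            np.asarray(ssmc, float) / self.ssmc_scale,
            np.asarray(ssec, float) / self.ssec_scale,
        )

    def evaluate(self, sst, ssmc, ssec) -> np.ndarray:
        """Noise-free NDVI response at the given cumulative features."""
        s1, s2, s3 = self.scaled(sst, ssmc, ssec)
        if self.response == "ternary":
            c = self.ternary
            return (
                c[0]
                + c[1] * s1 + c[2] * s2 + c[3] * s3
                + c[4] * s1**2 + c[5] * s2**2 + c[6] * s3**2
                + c[7] * s1**3 + c[8] * s2**3 + c[9] * s3**3
            )
        s = {"sst": s1, "ssmc": s2, "ssec": s3}[self.response]
        coef = getattr(self, self.response)
        return coef[0] + coef[1] * s + coef[2] * s**2 + coef[3] * s**3


def default_truth() -> TruthParams:
    return TruthParams()


def compute_ndvi(ir, red):
    """NDVI = (IR − R)/(IR + R) from infrared and red band values.

    Defined for nonnegative bands with a positive sum; lies in [−1, 1].
    """
    ir = np.asarray(ir, dtype=float)
    red = np.asarray(red, dtype=float)
    total = ir + red
    if np.any(total <= 0):
        raise ValueError("NDVI undefined: ir + red must be positive")
    result = (ir - red) / total
    return float(result) if result.ndim == 0 else result


def epoch_dates(config: SimConfig) -> pd.DatetimeIndex:
    """Satellite revisit dates: start + k·interval for k = 1..n_epochs."""
    start = pd.Timestamp(config.start_date)
    return pd.DatetimeIndex(
        [start + pd.Timedelta(days=config.epoch_interval_days * k)
         for k in range(1, config.n_epochs + 1)]
    )


def _time_grid(config: SimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date) + pd.Timedelta(days=1)
    step = pd.Timedelta(minutes=config.sensor_interval_minutes)
    return pd.date_range(start, end, freq=step, inclusive="left")


def smooth_soil_signals(config: SimConfig, timestamps: pd.DatetimeIndex) -> pd.DataFrame:
    """Deterministic seasonal + diurnal component of the three soil signals."""
    doy = timestamps.dayofyear.to_numpy(float)
    hour = (
        timestamps.hour.to_numpy(float)
        + timestamps.minute.to_numpy(float) / 60.0
        + timestamps.second.to_numpy(float) / 3600.0
    )
    def annual(phase_day):
        return np.cos(2 * np.pi * (doy - phase_day) / 365.25)

    diurnal = np.sin(2 * np.pi * hour / 24.0)
    st = (config.st_mean - config.st_amplitude * annual(config.st_phase_day)
          + config.st_diurnal_amplitude * diurnal)
    smc = config.smc_mean + config.smc_amplitude * annual(config.smc_phase_day)
    sec = config.sec_mean + config.sec_amplitude * annual(config.sec_phase_day)
    return pd.DataFrame({"timestamp": timestamps, "st": st, "smc": smc, "sec": sec})


def simulate_soil_series(config: SimConfig) -> pd.DataFrame:
    """Simulate one year of probe readings (columns timestamp, st, smc, sec).

    With ``n_nodes > 1`` several probes sharing the smooth signal but
    with independent noise are averaged into a single pooled series.
    Readings are clipped to the instrument ranges. Deterministic under
    a fixed seed.
    """
    rng = np.random.default_rng([0, config.seed])
    grid = _time_grid(config)
    smooth = smooth_soil_signals(config, grid)
    n = len(grid)
    out = smooth.copy()
    for col, sd in (("st", config.st_noise_sd),
                    ("smc", config.smc_noise_sd),
                    ("sec", config.sec_noise_sd)):
        if sd > 0:
            noise = rng.normal(0.0, sd, size=(config.n_nodes, n)).mean(axis=0)
            out[col] = out[col] + noise
    out["st"] = out["st"].clip(*ST_RANGE)
    out["smc"] = out["smc"].clip(*SMC_RANGE)
    out["sec"] = out["sec"].clip(*SEC_RANGE)
    return out


def simulate_ndvi_series(
    soil: pd.DataFrame,
    truth: TruthParams,
    config: SimConfig,
) -> pd.DataFrame:
    """Per-epoch NDVI from the ground-truth response to cumulative features.

    For each revisit date the generator computes the cumulative positive-
    day features of the supplied soil series (exactly as the downstream
    pipeline does), evaluates the truth response, then adds Gaussian
    observation noise and — with probability ``cloud_drop_prob`` per
    epoch — an additional negative shock of ``cloud_drop_depth``
    emulating cloud contamination. Values are clipped to [−1, 1].

    Returns a frame with columns ``date``, ``ndvi`` (observed) and
    ``ndvi_true`` (noise-free response, for recovery tests).
    """
    epochs = epoch_dates(config)
    daily = preprocess.daily_means(soil)
    if daily.index[0] > epochs[0] or daily.index[-1] < epochs[-1]:
        raise ConfigError("soil series does not cover all epoch dates")
    cum = preprocess.cumulative_features(daily, epochs)
    clean = truth.evaluate(cum["sst"], cum["ssmc"], cum["ssec"])
    overshoot = np.max(np.abs(clean)) - 1.0
    if overshoot > 1e-9:
        warnings.warn(
            f"truth response leaves [-1, 1] by {overshoot:.3g} before clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng([1, config.seed])
    noisy = np.asarray(clean, float).copy()
    if config.noise_sd_ndvi > 0:
        noisy = noisy + rng.normal(0.0, config.noise_sd_ndvi, size=noisy.shape)
    else:
        rng.normal(0.0, 1.0, size=noisy.shape)  # keep draw stream aligned
    drops = rng.random(noisy.shape) < config.cloud_drop_prob
    noisy = noisy - drops * config.cloud_drop_depth
    log.debug("simulated %d NDVI epochs, %d cloud drops", noisy.size, int(drops.sum()))
    return pd.DataFrame(
        {"date": epochs, "ndvi": np.clip(noisy, -1.0, 1.0), "ndvi_true": clean}
    )
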