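"""NDVI reconstruction, epoch aggregation, cumulative features, correlation."""

import numpy as np
import pandas as pd
import pytest

from teagrow import preprocess
from teagrow.preprocess import (
    MissingEpochError,
    PreprocessError,
    aggregate_to_epochs,
    correlation_matrix,
    cumulative_features,
    daily_means,
    denormalize,
    normalize,
    sg_filter,
)


def sg_oracle(y, window, order):
    """Independent per-window polynomial least-squares oracle.

    Mirror-pads the series, fits a degree-``order`` polynomial to each
    centred window by least squares and evaluates it at the centre.
    """
    half = window // 2
    padded = np.concatenate([y[1:half + 1][::-1], y, y[-half - 1:-1][::-1]])
    t = np.arange(-half, half + 1)
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        seg = padded[i:i + window]
        coef = np.polynomial.polynomial.polyfit(t, seg, order)
        out[i] = coef[0]  # polynomial value at the window centre t=0
    return out


class TestSgFilter:
    def test_constant_series_preserved(self):
        y = np.full(20, 0.37)
        np.testing.assert_allclose(sg_filter(y, envelope=False), y)

    def test_order_window_minus_one_is_identity(self, rng):
        y = rng.random(30)
        np.testing.assert_allclose(sg_filter(y, window=5, order=4, envelope=False), y,
                                   atol=1e-12)

    def test_matches_per_window_least_squares_oracle(self, rng):
        y = rng.random(72)
        ours = sg_filter(y, window=5, order=2, envelope=False)
        np.testing.assert_allclose(ours, sg_oracle(y, 5, 2), atol=1e-10)

    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_weights_reproduce_polynomials_up_to_fitted_order(self, degree):
        """The convolution weights pass monomials of degree ≤ order through
        unchanged wherever the window does not touch the (mirrored) edges."""
        t = np.linspace(0, 1, 40)
        y = t**degree
        out = sg_filter(y, window=5, order=2, envelope=False)
        np.testing.assert_allclose(out[2:-2], y[2:-2], atol=1e-12)

    def test_mirror_padding_preserves_constants_at_edges(self):
        y = np.full(12, 0.6)
        out = sg_filter(y, window=5, order=2, envelope=False)
        np.testing.assert_allclose(out, y, atol=1e-14)

    def test_envelope_never_decreases_any_value(self, rng):
        y = rng.random(72)
        assert np.all(sg_filter(y, envelope=True) >= y - 1e-15)

    def test_envelope_lifts_an_isolated_drop(self):
        y = np.full(15, 0.8)
        y[7] = 0.2  # cloud-style negative shock
        out = sg_filter(y, envelope=True)
        assert out[7] > 0.2

    @pytest.mark.parametrize(
        "window, order, n, match",
        [(4, 2, 20, "odd"), (5, 5, 20, "order"), (5, 2, 3, "shorter")],
    )
    def test_parameter_errors(self, window, order, n, match):
        with pytest.raises(PreprocessError, match=match):
            sg_filter(np.zeros(n), window=window, order=order)


class TestNormalize:
    def test_analytic_example(self):
        scaled, params = normalize([2.0, 4.0, 6.0])
        np.testing.assert_allclose(scaled, [0.0, 0.5, 1.0])
        assert (params.vmin, params.vmax) == (2.0, 6.0)

    def test_round_trip(self, rng):
        x = rng.normal(5, 3, 50)
        scaled, params = normalize(x)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        np.testing.assert_allclose(denormalize(scaled, params), x, atol=1e-12)

    def test_reused_params_apply_same_scaling(self):
        _, params = normalize([0.0, 10.0])
        scaled, _ = normalize([5.0, 20.0], params)
        np.testing.assert_allclose(scaled, [0.5, 2.0])

    def test_constant_sequence_rejected(self):
        with pytest.raises(PreprocessError, match="constant"):
            normalize([3.0, 3.0, 3.0])


def _soil_frame(timestamps, st):
    return pd.DataFrame(
        {"timestamp": timestamps, "st": st, "smc": np.full(len(st), 20.0),
         "sec": np.full(len(st), 80.0)}
    )


class TestAggregateToEpochs:
    def test_constant_window_mean(self):
        ts = pd.date_range("2020-01-01", "2020-01-10 23:50", freq="10min")
        soil = _soil_frame(ts, np.full(len(ts), 7.5))
        out = aggregate_to_epochs(soil, [pd.Timestamp("2020-01-06")], window_days=5)
        assert out.loc[0, "st"] == pytest.approx(7.5)

    def test_linear_trend_gives_midpoint_value(self):
        ts = pd.date_range("2020-01-01", "2020-01-10 23:59", freq="1min")
        hours = (ts - ts[0]).total_seconds() / 3600.0
        soil = _soil_frame(ts, 2.0 + 0.25 * hours)
        epoch = pd.Timestamp("2020-01-06")
        out = aggregate_to_epochs(soil, [epoch], window_days=5)
        mid_hours = (pd.Timestamp("2020-01-03 12:00") - ts[0]).total_seconds() / 3600
        expected = 2.0 + 0.25 * (mid_hours - 0.5 / 60)  # half-open window, 1-min grid
        assert out.loc[0, "st"] == pytest.approx(expected, abs=1e-9)

    def test_readings_outside_window_raise(self):
        ts = pd.date_range("2020-02-01", periods=100, freq="10min")
        soil = _soil_frame(ts, np.ones(100))
        with pytest.raises(MissingEpochError) as err:
            aggregate_to_epochs(soil, [pd.Timestamp("2020-01-06")], window_days=5)
        assert err.value.epochs == [pd.Timestamp("2020-01-06").date()]

    def test_cadence_invariance_for_daily_constant_signal(self):
        # same day-level signal sampled at 10 and 30 minutes
        values = {}
        for freq in ("10min", "30min"):
            ts = pd.date_range("2020-01-01", "2020-01-10 23:59", freq=freq)
            day_value = ts.dayofyear.to_numpy(float)
            soil = _soil_frame(ts, day_value)
            out = aggregate_to_epochs(soil, [pd.Timestamp("2020-01-06")], window_days=5)
            values[freq] = out.loc[0, "st"]
        assert values["10min"] == pytest.approx(values["30min"], abs=1e-9)


class TestCumulativeFeatures:
    def _daily(self, st_values, start="2020-01-01"):
        idx = pd.date_range(start, periods=len(st_values), freq="D")
        return pd.DataFrame(
            {"st": st_values, "smc": st_values, "sec": st_values}, index=idx
        )

    def test_positive_day_rule_by_hand(self):
        daily = self._daily([5.0, -2.0, 3.0])
        out = cumulative_features(daily, daily.index)
        np.testing.assert_allclose(out["sst"], [5.0, 5.0, 8.0])

    def test_all_negative_days_sum_to_zero(self):
        daily = self._daily([-1.0, -5.0, -0.5])
        out = cumulative_features(daily, daily.index)
        assert (out[["sst", "ssmc", "ssec"]] == 0.0).all().all()

    def test_nonnegative_inputs_give_nondecreasing_series(self, rng):
        daily = self._daily(rng.random(40) * 10)
        out = cumulative_features(daily, daily.index)
        for col in ("sst", "ssmc", "ssec"):
            assert (np.diff(out[col]) >= 0).all()

    def test_additive_over_consecutive_ranges(self, rng):
        values = rng.normal(2, 5, 60)
        daily = self._daily(values)
        full = cumulative_features(daily, [daily.index[29], daily.index[59]])
        first = cumulative_features(daily.iloc[:30], [daily.index[29]])
        second = cumulative_features(daily.iloc[30:], [daily.index[59]])
        assert full.loc[1, "sst"] == pytest.approx(
            first.loc[0, "sst"] + second.loc[0, "sst"]
        )

    def test_epoch_before_season_start_rejected(self):
        daily = self._daily([1.0, 2.0, 3.0], start="2020-03-01")
        with pytest.raises(PreprocessError, match="season start"):
            cumulative_features(daily, [pd.Timestamp("2020-02-01")])


class TestCorrelationMatrix:
    def test_self_correlation_and_anticorrelation(self):
        x = np.linspace(0, 1, 30)
        table = pd.DataFrame({"x": x, "y": -x, "z": x**2})
        corr = correlation_matrix(table)
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "y"] == pytest.approx(-1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_zero_variance_column_named_in_error(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(PreprocessError, match="flat"):
            correlation_matrix(table)

    def test_too_few_rows_rejected(self):
        with pytest.raises(PreprocessError, match="3"):
            correlation_matrix(pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}))

    def test_generator_sign_pattern(self, epoch_table):
        """NDVI correlates + with ST and cumulative features, − with SMC/SEC."""
        corr = correlation_matrix(
            epoch_table, ["ndvi_filtered", "st", "smc", "sec", "sst", "ssmc", "ssec"]
        )
        row = corr.loc["ndvi_filtered"]
        assert row["st"] > 0 and row["sst"] > 0 and row["ssmc"] > 0 and row["ssec"] > 0
        assert row["smc"] < 0 and row["sec"] < 0


class TestBuildEpochTable:
    def test_columns_and_row_count(self, epoch_table):
        assert list(epoch_table.columns) == [
            "date", "st", "smc", "sec", "sst", "ssmc", "ssec",
            "ndvi_raw", "ndvi_filtered",
        ]
        assert len(epoch_table) == 72

    def test_cumulative_columns_nondecreasing(self, epoch_table):
        for col in ("sst", "ssmc", "ssec"):
            assert (np.diff(epoch_table[col]) >= 0).all()

    def test_daily_means_calendar_grouping(self, soil):
        daily = daily_means(soil)
        assert len(daily) == 366  # leap study year
        assert daily.index.is_monotonic_increasing
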