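"""Tests for logger analytics: daily summaries, heating rates, exposure
band durations and spike detection."""

import numpy as np
import pandas as pd
import pytest

from thermaltol import (
    LoggerGeneratorConfig,
    LoggerSeries,
    SpikeConfig,
    daily_summaries,
    detect_spikes,
    exposure_durations,
    heating_rate,
    simulate_logger,
)


def make_series(times, temps, site_id="s", interval=None):
    df = pd.DataFrame({"timestamp": pd.to_datetime(times), "temp_c": temps})
    return LoggerSeries(site_id=site_id, data=df, nominal_interval_min=interval)


def hourly_day(temps, day="2023-05-10"):
    times = pd.date_range(day, periods=len(temps), freq="h")
    return pd.DataFrame({"timestamp": times, "temp_c": temps})


class TestLoggerSeries:
    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            make_series(["2023-05-10 02:00", "2023-05-10 01:00"], [30.0, 30.0])

    def test_sanity_band_enforced(self):
        with pytest.raises(ValueError, match="sanity band"):
            make_series(["2023-05-10 01:00", "2023-05-10 02:00"], [30.0, 75.0])

    def test_interval_inferred_from_median_gap(self):
        s = make_series(
            ["2023-05-10 00:00", "2023-05-10 01:00", "2023-05-10 02:00"],
            [30.0, 30.5, 31.0],
        )
        assert s.nominal_interval_min == 60.0


class TestDailySummaries:
    def test_constant_day(self):
        s = make_series(
            pd.date_range("2023-05-10", periods=24, freq="h"), [30.0] * 24
        )
        out = daily_summaries(s)
        row = out.iloc[0]
        assert row["mean_temp_c"] == row["min_temp_c"] == row["max_temp_c"] == 30.0
        assert row["heating_rate_c_per_min"] == 0.0

    def test_sinusoid_extremes_round_trip(self):
        # diel cosine with dawn minimum 28.2 °C and afternoon maximum 35.2 °C
        cfg = LoggerGeneratorConfig(
            daily_mean=31.7, diel_amplitude=3.5, obs_noise_sd=0.0, n_days=2, seed=0
        )
        out = daily_summaries(simulate_logger(cfg))
        assert out["min_temp_c"].iloc[0] == pytest.approx(28.2, abs=1e-9)
        assert out["max_temp_c"].iloc[0] == pytest.approx(35.2, abs=1e-9)

    def test_single_sample_day_excluded_with_warning(self):
        times = list(pd.date_range("2023-05-10", periods=24, freq="h")) + [
            pd.Timestamp("2023-05-11 09:00")
        ]
        s = make_series(times, [30.0] * 24 + [31.0])
        with pytest.warns(UserWarning, match="single sample"):
            out = daily_summaries(s)
        assert list(out["date"].astype(str)) == ["2023-05-10"]

    def test_partial_day_flagged(self):
        times = pd.date_range("2023-05-10", periods=30, freq="h")
        s = make_series(times, np.linspace(29, 33, 30))
        out = daily_summaries(s)
        by_date = out.set_index(out["date"].astype(str))
        assert not by_date.loc["2023-05-10", "partial"]
        assert by_date.loc["2023-05-11", "partial"]  # only 6 of 24 samples

    def test_empty_series_empty_result(self):
        s = make_series([], [])
        assert daily_summaries(s).empty

    def test_max_bounds_every_sample_and_idempotent(self):
        cfg = LoggerGeneratorConfig(n_days=3, seed=4)
        series = simulate_logger(cfg)
        out = daily_summaries(series)
        for _, row in out.iterrows():
            day = series.data[series.data["timestamp"].dt.date == row["date"]]
            assert row["max_temp_c"] >= day["temp_c"].max() - 1e-12
        pd.testing.assert_frame_equal(out, daily_summaries(series))


class TestHeatingRate:
    def test_hand_example(self):
        # dawn minimum 28.0 °C at 06:00, maximum 33.6 °C at 14:00 -> 5.6/480
        temps = (
            [29.0, 28.8, 28.6, 28.4, 28.3, 28.1, 28.0]
            + list(np.linspace(28.7, 33.6, 8))
            + [33.0] * 9
        )
        day = hourly_day(temps)
        assert int(day["temp_c"].idxmin()) == 6
        assert heating_rate(day) == pytest.approx(5.6 / 480, abs=5e-4)

    def test_flat_day_zero(self):
        assert heating_rate(hourly_day([30.0] * 24)) == 0.0

    def test_max_before_anchor_undefined(self):
        temps = [35.0] + [30.0 - 0.1 * i for i in range(23)]
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(heating_rate(hourly_day(temps)))

    def test_generator_round_trip_target_rate(self):
        # dawn-min to peak of a cosine: mean rate 2A/720 °C/min; build A for 0.05
        amp = 0.05 * 720 / 2
        cfg = LoggerGeneratorConfig(
            daily_mean=30.0, diel_amplitude=amp, obs_noise_sd=0.0, n_days=2, seed=0
        )
        day = simulate_logger(cfg).data
        day = day[day["timestamp"].dt.date == day["timestamp"].dt.date.iloc[0]]
        assert heating_rate(day) == pytest.approx(0.05, abs=0.005)

    def test_fixed_policy(self):
        temps = [28.0] * 7 + list(np.linspace(28.5, 34.0, 8)) + [33.0] * 9
        day = hourly_day(temps)
        r_fixed = heating_rate(day, sunrise_policy="fixed", fixed_time="06:00")
        assert r_fixed == pytest.approx((34.0 - 28.0) / (14 - 6) / 60, abs=5e-4)


class TestExposureDurations:
    def test_all_below_bands_zero(self):
        s = make_series(pd.date_range("2023-05-10", periods=24, freq="h"), [30.0] * 24)
        res = exposure_durations(s)
        assert (res.per_day["minutes"] == 0).all()

    def test_linear_segment_midpoint_crossing(self):
        s = make_series(["2023-05-10 10:00", "2023-05-10 11:00"], [31.0, 33.0])
        res = exposure_durations(s)
        in_band = res.per_day.set_index(["band_lo", "band_hi"])["minutes"]
        assert in_band[(32.0, 33.0)] == pytest.approx(30.0, abs=1e-9)

    def test_stepped_day_construction(self):
        # 34.5 °C step over 10:00-12:00 between 33.5 °C shoulders: crossings
        # of the 34 °C edge fall exactly at half-hours, 120 min in [34, 35)
        temps = [33.5] * 10 + [34.5, 34.5] + [33.5] * 12
        s = make_series(pd.date_range("2023-05-10", periods=24, freq="h"), temps)
        res = exposure_durations(s)
        in_band = res.per_day.set_index(["band_lo", "band_hi"])["minutes"]
        assert in_band[(34.0, 35.0)] == pytest.approx(120.0, abs=2.0)

    def test_conservation_of_total_span(self):
        cfg = LoggerGeneratorConfig(n_days=2, seed=3)
        s = simulate_logger(cfg)
        bands = [(float(t), float(t + 1)) for t in range(20, 45)]
        res = exposure_durations(s, bands=bands)
        total = res.per_day.groupby("date")["minutes"].sum()
        # full days span 1440 min except the last (ends at 23:00)
        assert total.iloc[0] == pytest.approx(1440.0, abs=1e-6)

    def test_invariant_under_refinement(self):
        s1 = make_series(["2023-05-10 10:00", "2023-05-10 12:00"], [31.0, 35.0])
        mid = 33.0  # linear midpoint at 11:00
        s2 = make_series(
            ["2023-05-10 10:00", "2023-05-10 11:00", "2023-05-10 12:00"],
            [31.0, mid, 35.0],
        )
        r1 = exposure_durations(s1).per_day["minutes"].to_numpy()
        r2 = exposure_durations(s2).per_day["minutes"].to_numpy()
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_overlapping_bands_rejected(self):
        s = make_series(["2023-05-10 10:00", "2023-05-10 11:00"], [30.0, 31.0])
        with pytest.raises(ValueError, match="non-overlapping"):
            exposure_durations(s, bands=[(32.0, 34.0), (33.0, 35.0)])

    def test_half_open_band_for_constant_segment(self):
        s = make_series(["2023-05-10 10:00", "2023-05-10 11:00"], [33.0, 33.0])
        res = exposure_durations(s, bands=[(32.0, 33.0), (33.0, 34.0)])
        in_band = res.per_day.set_index(["band_lo", "band_hi"])["minutes"]
        assert in_band[(32.0, 33.0)] == 0.0
        assert in_band[(33.0, 34.0)] == 60.0


class TestDetectSpikes:
    def spiked_series(self, excess=1.0, duration=60.0, noise=0.0, seed=5):
        cfg = LoggerGeneratorConfig(
            obs_noise_sd=noise,
            n_days=7,
            seed=seed,
            spike=SpikeConfig(day=3, start_hour=13.5, excess_c=excess,
                              duration_min=duration),
        )
        return simulate_logger(cfg)

    def test_injected_event_recovered(self):
        events = detect_spikes(self.spiked_series(), delta=1.0)
        assert len(events) == 1
        ev = events.iloc[0]
        assert abs(ev["duration_min"] - 60.0) <= 60.0  # within one sampling interval
        assert ev["peak_excess_c"] == pytest.approx(1.0, abs=1e-6)
        assert ev["onset"].date().isoformat() == "2023-05-11"

    def test_no_injection_no_events(self):
        cfg = LoggerGeneratorConfig(obs_noise_sd=0.0, n_days=7, seed=5)
        assert detect_spikes(simulate_logger(cfg), delta=1.0).empty

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            detect_spikes(self.spiked_series(), delta=0.0)

    def test_too_few_days_rejected(self):
        cfg = LoggerGeneratorConfig(obs_noise_sd=0.0, n_days=2, seed=5)
        with pytest.raises(ValueError, match="baseline undefined"):
            detect_spikes(simulate_logger(cfg), delta=1.0)
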