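"""Temperature-logger analytics for habitat thermal regimes.

Works on HOBO-style logger exports (timestamp, °C) at nominally hourly
cadence: daily summaries, dawn-to-peak heating rates, exact time-in-band
exposure durations under linear interpolation, and detection of transient
warm anomalies against an hour-of-day baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoggerSeries",
    "ExposureResult",
    "daily_summaries",
    "heating_rate",
    "exposure_durations",
    "detect_spikes",
    "DEFAULT_BANDS",
]

# Half-open [lo, hi) °C bands over the ecologically critical range.
DEFAULT_BANDS = [(32.0, 33.0), (33.0, 34.0), (34.0, 35.0), (35.0, 36.0)]


@dataclass
class LoggerSeries:
    """Timestamped water temperatures for one site.

    ``data`` holds columns ``timestamp`` (datetime64, strictly increasing)
    and ``temp_c``. ``nominal_interval_min`` is the logger's programmed
    cadence; inferred from the median sampling gap when not given.
    """

    site_id: str
    data: pd.DataFrame
    nominal_interval_min: float | None = None

    def __post_init__(self) -> None:
        df = self.data
        if not {"timestamp", "temp_c"} <= set(df.columns):
            raise ValueError("LoggerSeries data needs 'timestamp' and 'temp_c' columns")
        df = df[["timestamp", "temp_c"]].copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        if len(df) > 1 and not df["timestamp"].is_monotonic_increasing:
            raise ValueError(f"site {self.site_id}: timestamps must be increasing")
        if df["timestamp"].duplicated().any():
            raise ValueError(f"site {self.site_id}: duplicate timestamps")
        t = df["temp_c"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError(f"site {self.site_id}: non-finite temperatures")
        if np.any((t < -5.0) | (t > 60.0)):
            raise ValueError(
                f"site {self.site_id}: temperatures outside the -5..60 °C sanity band"
            )
        self.data = df.reset_index(drop=True)
        if self.nominal_interval_min is None and len(df) > 1:
            gaps = df["timestamp"].diff().dropna().dt.total_seconds() / 60.0
            self.nominal_interval_min = float(np.median(gaps))

    @classmethod
    def from_csv(cls, path, site_id: str | None = None) -> "list[LoggerSeries] | LoggerSeries":
        """Read `logger.csv` (site_id, timestamp, temp_c); one series per site."""
        df = pd.read_csv(path)
        missing = {"site_id", "timestamp", "temp_c"} - set(df.columns)
        if missing:
            raise KeyError(f"logger table missing columns: {', '.join(sorted(missing))}")
        if site_id is not None:
            return cls(site_id, df[df["site_id"] == site_id])
        return [cls(str(s), g) for s, g in df.groupby("site_id", sort=True)]

    def __len__(self) -> int:
        return len(self.data)


def _minutes_of_day(ts: pd.Series) -> np.ndarray:
    return (
        ts.dt.hour.to_numpy() * 60.0
        + ts.dt.minute.to_numpy()
        + ts.dt.second.to_numpy() / 60.0
    )


def heating_rate(day: pd.DataFrame, sunrise_policy: str = "dawn_min", fixed_time: str = "06:00"):
    """Dawn-to-peak heating rate for one day of samples, °C/min.

    (T_max − T_anchor) / minutes elapsed, where the anchor approximates
    sunrise. True sunrise times are not in logger data, so the default
    ``dawn_min`` policy anchors at the time of the day's minimum temperature
    restricted to 00:00–12:00 (the dawn minimum, the observable proxy closest
    to sunrise); ``fixed`` anchors at a clock time (default 06:00) for
    sensitivity checks. Rounded to 3 decimals, the resolution at which
    habitat rates (~0.003–0.066 °C/min) are meaningfully distinct.

    Returns NaN (with a warning) when the maximum occurs at or before the
    anchor.
    """
    ts = pd.to_datetime(day["timestamp"])
    temps = day["temp_c"].to_numpy(dtype=float)
    mins = _minutes_of_day(ts)
    if sunrise_policy == "dawn_min":
        morning = mins < 720.0
        if not morning.any():
            warnings.warn("no morning samples: heating rate undefined", stacklevel=2)
            return float("nan")
        i_anchor = int(np.flatnonzero(morning)[np.argmin(temps[morning])])
    elif sunrise_policy == "fixed":
        h, m = (int(x) for x in fixed_time.split(":"))
        target = h * 60.0 + m
        i_anchor = int(np.argmin(np.abs(mins - target)))
    else:
        raise ValueError(f"unknown sunrise_policy {sunrise_policy!r}")
    i_max = int(np.argmax(temps))
    if temps[i_max] == temps[i_anchor]:
        return 0.0  # no warming after the anchor (flat or cooling day)
    dt_min = mins[i_max] - mins[i_anchor]
    if dt_min <= 0:
        warnings.warn(
            "daily maximum at or before the sunrise anchor: heating rate undefined",
            stacklevel=2,
        )
        return float("nan")
    return round(float((temps[i_max] - temps[i_anchor]) / dt_min), 3)


def daily_summaries(
    series: LoggerSeries,
    sunrise_policy: str = "dawn_min",
    partial_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-civil-day summary: mean/min/max with times, heating rate, coverage.

    Days with fewer than two samples are dropped (with a warning); days with
    under ``partial_threshold`` of the nominal sample count are kept but
    flagged ``partial`` so cross-day means can exclude them.
    """
    df = series.data
    if df.empty:
        return pd.DataFrame(
            columns=[
                "site_id", "date", "mean_temp_c", "min_temp_c", "max_temp_c",
                "time_of_min", "time_of_max", "heating_rate_c_per_min",
                "n_samples", "partial",
            ]
        )
    expected = 1440.0 / series.nominal_interval_min if series.nominal_interval_min else None
    rows = []
    for date, day in df.groupby(df["timestamp"].dt.date):
        if len(day) < 2:
            warnings.warn(
                f"site {series.site_id} {date}: single sample, day excluded",
                stacklevel=2,
            )
            continue
        temps = day["temp_c"].to_numpy(dtype=float)
        i_min, i_max = int(np.argmin(temps)), int(np.argmax(temps))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rate = heating_rate(day, sunrise_policy=sunrise_policy)
        rows.append(
            {
                "site_id": series.site_id,
                "date": date,
                "mean_temp_c": float(temps.mean()),
                "min_temp_c": float(temps[i_min]),
                "max_temp_c": float(temps[i_max]),
                "time_of_min": day["timestamp"].iloc[i_min].time(),
                "time_of_max": day["timestamp"].iloc[i_max].time(),
                "heating_rate_c_per_min": rate,
                "n_samples": len(day),
                "partial": bool(expected and len(day) < partial_threshold * expected),
            }
        )
    return pd.DataFrame(rows)


def _segment_band_minutes(t0, t1, temp0, temp1, lo, hi) -> float:
    """Minutes a linear segment spends in [lo, hi); exact crossing times."""
    dt = t1 - t0
    if temp0 == temp1:
        return dt if lo <= temp0 < hi else 0.0
    tmin, tmax = min(temp0, temp1), max(temp0, temp1)
    overlap = min(hi, tmax) - max(lo, tmin)
    if overlap <= 0:
        return 0.0
    return dt * overlap / (tmax - tmin)


@dataclass
class ExposureResult:
    """Per-day time-in-band minutes plus across-day mean ± sd per band."""

    per_day: pd.DataFrame  # site_id, date, band_lo, band_hi, minutes
    summary: pd.DataFrame  # site_id, band_lo, band_hi, mean_minutes, sd_minutes, n_days


def exposure_durations(series: LoggerSeries, bands=None) -> ExposureResult:
    """Daily minutes spent in each temperature band.

    Temperature is linear between samples, so band-crossing times are solved
    exactly per segment; segments spanning midnight are split at the day
    boundary. Bands are half-open [lo, hi), must be ascending and
    non-overlapping (default 1 °C steps over 32–36 °C).
    """
    if bands is None:
        bands = DEFAULT_BANDS
    bands = [(float(lo), float(hi)) for lo, hi in bands]
    for lo, hi in bands:
        if hi <= lo:
            raise ValueError(f"band ({lo}, {hi}) is empty or inverted")
    for (_, hi_a), (lo_b, _) in zip(bands, bands[1:]):
        if lo_b < hi_a:
            raise ValueError("bands must be ascending and non-overlapping")

    df = series.data
    ts = df["timestamp"]
    t_min = ts.dt.normalize().iloc[0] if len(df) else None
    times = ((ts - t_min).dt.total_seconds() / 60.0).to_numpy() if len(df) else np.array([])
    temps = df["temp_c"].to_numpy(dtype=float)

    # split segments at civil-day boundaries (multiples of 1440 min)
    acc: dict[tuple, float] = {}
    for i in range(len(times) - 1):
        a, b = times[i], times[i + 1]
        ta, tb = temps[i], temps[i + 1]
        cut = np.floor(a / 1440.0) * 1440.0 + 1440.0
        seg_start, temp_start = a, ta
        while cut < b:
            temp_cut = ta + (tb - ta) * (cut - a) / (b - a)
            _accumulate(acc, series.site_id, t_min, seg_start, cut, temp_start, temp_cut, bands)
            seg_start, temp_start = cut, temp_cut
            cut += 1440.0
        _accumulate(acc, series.site_id, t_min, seg_start, b, temp_start, tb, bands)

    dates = sorted({k[1] for k in acc}) if acc else []
    rows = [
        {
            "site_id": series.site_id,
            "date": date,
            "band_lo": lo,
            "band_hi": hi,
            "minutes": acc.get((series.site_id, date, lo, hi), 0.0),
        }
        for date in dates
        for lo, hi in bands
    ]
    per_day = pd.DataFrame(rows, columns=["site_id", "date", "band_lo", "band_hi", "minutes"])
    if per_day.empty:
        summary = pd.DataFrame(
            columns=["site_id", "band_lo", "band_hi", "mean_minutes", "sd_minutes", "n_days"]
        )
    else:
        summary = (
            per_day.groupby(["site_id", "band_lo", "band_hi"], as_index=False)["minutes"]
            .agg(mean_minutes="mean", sd_minutes="std", n_days="count")
        )
        summary["sd_minutes"] = summary["sd_minutes"].fillna(0.0)
    return ExposureResult(per_day=per_day, summary=summary)


def _accumulate(acc, site_id, t0_ref, a, b, ta, tb, bands):
    if b <= a:
        return
    date = (t0_ref + pd.Timedelta(minutes=float(a))).date()
    for lo, hi in bands:
        m = _segment_band_minutes(a, b, ta, tb, lo, hi)
        if m:
            key = (site_id, date, lo, hi)
            acc[key] = acc.get(key, 0.0) + m
        else:
            acc.setdefault((site_id, date, lo, hi), 0.0)


def detect_spikes(
    series: LoggerSeries, delta: float = 1.0, window: float = 60.0
) -> pd.DataFrame:
    """Flag transient warm anomalies against an hour-of-day baseline.

    The baseline for each sample is the median temperature at the same clock
    time across all *other* days (so a one-off release of hot water stands
    out against the site's usual diel cycle). Consecutive samples with excess
    >= ``delta`` °C form one event; the default delta of 1.0 °C matches the
    magnitude of anomaly this detector is meant for.

    Returns a DataFrame with onset, end, duration_min (last-minus-first
    exceeding sample plus one sampling interval), peak_excess_c, n_samples.
    """
    if delta <= 0:
        raise ValueError("delta must be positive; delta=0 would flag all noise")
    df = series.data
    span_min = (
        (df["timestamp"].iloc[-1] - df["timestamp"].iloc[0]).total_seconds() / 60.0
        if len(df) > 1
        else 0.0
    )
    if span_min < window:
        raise ValueError(f"series spans {span_min:.0f} min < window {window:.0f} min")
    dates = df["timestamp"].dt.date
    if dates.nunique() < 3:
        raise ValueError("baseline undefined: need at least 3 days of data")

    clock = _minutes_of_day(df["timestamp"])
    temps = df["temp_c"].to_numpy(dtype=float)
    day_codes = pd.factorize(dates)[0]
    excess = np.empty(len(df))
    for c in np.unique(clock):
        at = clock == c
        for d in np.unique(day_codes[at]):
            here = at & (day_codes == d)
            others = temps[at & (day_codes != d)]
            baseline = np.median(others) if len(others) else np.nan
            excess[here] = temps[here] - baseline

    # tiny slack so an excursion of exactly delta is not lost to roundoff
    exceeding = excess >= delta - 1e-9
    interval = series.nominal_interval_min or 0.0
    events = []
    i = 0
    while i < len(df):
        if exceeding[i]:
            j = i
            while j + 1 < len(df) and exceeding[j + 1]:
                j += 1
            dur = (
                df["timestamp"].iloc[j] - df["timestamp"].iloc[i]
            ).total_seconds() / 60.0 + interval
            events.append(
                {
                    "site_id": series.site_id,
                    "onset": df["timestamp"].iloc[i],
                    "end": df["timestamp"].iloc[j],
                    "duration_min": dur,
                    "peak_excess_c": float(np.nanmax(excess[i : j + 1])),
                    "n_samples": j - i + 1,
                }
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(
        events,
        columns=["site_id", "onset", "end", "duration_min", "peak_excess_c", "n_samples"],
    )
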