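"""Synthetic assay and logger generators.

These emulate the two data streams the analysis consumes: individual-level
dynamic CTmax assay records with between-fish tolerance heterogeneity, and
diel water-temperature logger traces with optional transient warm spikes.
Defaults describe a geothermally heated tropical stream in its hot season
(daily mean ~31.7 °C swinging ±3.5 °C, hourly logging) and ramping assays at
0.42 ± 0.06 °C/min — the conditions the downstream models assume.

Between-fish variation is placed on the static limit ``t_static`` rather
than on ``z``: a single heterogeneity parameter keeps fits identifiable, and
individual knockdown spreads inform only a location shift of the TDT curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .field import LoggerSeries
from .tdt import TDTParameters, dynamic_knockdown

__all__ = [
    "AssayGeneratorConfig",
    "SpikeConfig",
    "LoggerGeneratorConfig",
    "simulate_assay",
    "simulate_logger",
    "trial_summaries_from_records",
]

RATE_FLOOR = 0.05  # °C/min; ramps slower than this are not credible assays


@dataclass
class AssayGeneratorConfig:
    """Configuration for one species × oxygen batch of ramping trials.

    ``z_true``/``t_static_true`` define the generating TDT curve;
    ``between_fish_sd`` is the SD of each fish's individual static limit.
    Each trial draws its own realised heating rate from a normal with SD
    ``rate_jitter_sd`` truncated at 0.05 °C/min.
    """

    species: str = "P. sulphuraria"
    oxygen: str = "hypoxic"
    z_true: float = 5.58
    t_static_true: float = 43.437
    between_fish_sd: float = 0.8
    heating_rate: float = 0.42
    rate_jitter_sd: float = 0.06
    start_temp: float = 30.0
    n_fish: int = 15
    n_trials: int = 3
    direction: str = "heat"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.between_fish_sd < 0:
            raise ValueError("between_fish_sd must be >= 0")
        if self.heating_rate <= 0:
            raise ValueError("heating_rate must be > 0")
        if self.n_fish < 1 or self.n_trials < 1:
            raise ValueError("n_fish and n_trials must be >= 1")


def _truncated_normal(rng, loc, scale, lower, size):
    """Normal draws truncated below at ``lower`` (resampling rejection)."""
    if scale == 0:
        return np.full(size, max(loc, lower))
    out = rng.normal(loc, scale, size)
    while True:
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(loc, scale, int(bad.sum()))


def simulate_assay(
    config: AssayGeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ramping-assay records for one species × oxygen batch.

    Each fish carries an individual static limit drawn from
    Normal(t_static_true, between_fish_sd); its knockdown temperature is the
    closed-form ramp solution at the trial's realised heating rate.

    Returns ``(records, trials)``: individual rows shaped like `assays.csv`
    (plus the trial's realised rate) and the per-trial summaries shaped like
    `trials.csv`. Deterministic under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    for j in range(config.n_trials):
        rate = float(
            _truncated_normal(
                rng, config.heating_rate, config.rate_jitter_sd, RATE_FLOOR, 1
            )[0]
        )
        t_statics = rng.normal(config.t_static_true, config.between_fish_sd, config.n_fish)
        trial_id = f"{config.species}-{config.oxygen}-T{j + 1}"
        for k, ts_i in enumerate(t_statics):
            params = TDTParameters(z=config.z_true, t_static=float(ts_i))
            kd = dynamic_knockdown(params, config.start_temp, rate)
            records.append(
                {
                    "fish_id": f"{trial_id}-F{k + 1}",
                    "species": config.species,
                    "oxygen": config.oxygen,
                    "trial_id": trial_id,
                    "direction": config.direction,
                    "knockdown_temp_c": kd,
                    "standard_length_mm": float(rng.normal(20.0, 2.5)),
                    "collection_temp_c": config.start_temp,
                    "heating_rate_c_per_min": rate,
                }
            )
    records = pd.DataFrame(records)
    trials = trial_summaries_from_records(records)
    return records, trials


def trial_summaries_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse individual assay records to `trials.csv`-shaped summaries."""
    return (
        records.groupby(["trial_id", "species", "oxygen"], as_index=False)
        .agg(
            heating_rate_c_per_min=("heating_rate_c_per_min", "mean"),
            start_temp_c=("collection_temp_c", "mean"),
            mean_knockdown_c=("knockdown_temp_c", "mean"),
            n_fish=("fish_id", "size"),
        )
        .sort_values("trial_id")
        .reset_index(drop=True)
    )


@dataclass
class SpikeConfig:
    """A transient warm anomaly riding on the diel cycle."""

    day: int = 3  # 0-based day index
    start_hour: float = 13.5
    excess_c: float = 1.0
    duration_min: float = 60.0


@dataclass
class LoggerGeneratorConfig:
    """Configuration for one site's diel temperature trace.

    Temperature follows a single-harmonic cosine,
    ``daily_mean + diel_amplitude*cos(2π(t − time_of_max)/24 h)`` plus
    Gaussian observation noise, sampled every ``sampling_interval_min``.
    Defaults give the dry-season daily range 28.2–35.2 °C peaking
    mid-afternoon, logged hourly.
    """

    site_id: str = "site_5"
    daily_mean: float = 31.7
    diel_amplitude: float = 3.5
    time_of_max: float = 15.0  # clock hours
    obs_noise_sd: float = 0.1
    sampling_interval_min: float = 60.0
    n_days: int = 14
    start: str = "2023-05-08 00:00"
    spike: SpikeConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diel_amplitude < 0:
            raise ValueError("diel_amplitude must be >= 0")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be > 0")


def simulate_logger(
    config: LoggerGeneratorConfig, rng: np.random.Generator | None = None
) -> LoggerSeries:
    """Simulate a logger export for one site. Deterministic under the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.n_days * 1440.0 / config.sampling_interval_min))
    minutes = np.arange(n) * config.sampling_interval_min
    temps = config.daily_mean + config.diel_amplitude * np.cos(
        2.0 * np.pi * (minutes - config.time_of_max * 60.0) / 1440.0
    )
    if config.obs_noise_sd > 0:
        temps = temps + rng.normal(0.0, config.obs_noise_sd, n)
    if config.spike is not None:
        s = config.spike
        onset = s.day * 1440.0 + s.start_hour * 60.0
        in_spike = (minutes >= onset) & (minutes < onset + s.duration_min)
        temps = temps + np.where(in_spike, s.excess_c, 0.0)
    timestamps = pd.Timestamp(config.start) + pd.to_timedelta(minutes, unit="m")
    df = pd.DataFrame({"timestamp": timestamps, "temp_c": temps})
    return LoggerSeries(
        site_id=config.site_id,
        data=df,
        nominal_interval_min=config.sampling_interval_min,
    )
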