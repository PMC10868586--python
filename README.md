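# thermaltol

Thermal death time (TDT) modelling of ectotherm heat tolerance, habitat
temperature-logger analytics, and thermal safety margins.

`thermaltol` is written for thermal ecologists and physiologists who run
dynamic CTmax assays — fish (or other ectotherms) warmed at a fixed ramp rate
until they lose organised locomotion — and want to relate those laboratory
knockdown temperatures to the much slower warming their animals experience in
the wild. It was developed around extremophile poeciliids (sulfur mollies and
widemouth gambusia) living in a geothermally heated, sulfidic, hypoxic spring
system, but nothing in it is specific to that system.

## The model

The TDT curve links a constant stress temperature *T* to the time it can be
endured before knockdown:

```
log10(t_tol / t_ref) = (t_static − T) / z
```

* **z** — heat-sensitivity coefficient (°C per decade of time): warming by
  *z* °C divides tolerable time by ten.
* **t_static** — the constant temperature tolerated for exactly the reference
  duration *t_ref* (1 min by default), i.e. the "1-minute CTmax".

Under a time-varying trajectory *T(t)*, heat injury accumulates at rate
`1 / t_tol(T(t))` and knockdown occurs when the integral reaches 1. For a
linear ramp at rate *r* from *T₀* this gives the closed-form knockdown
temperature

```
Tk = t_static + z · log10( r·ln10·t_ref / z + 10^((T₀ − t_static)/z) )
```

Fitting (z, t_static) to trial-level (rate, mean knockdown) pairs by
nonlinear least squares lets you predict CTmax at habitat heating rates
(~0.003–0.066 °C/min, dawn to afternoon peak) and the tolerable duration of
ecologically critical temperatures (32–36 °C), to compare against what
temperature loggers actually record.

The package also provides trial-blocked marginal means and a permutation
test of the species × oxygen interaction in 2×2 assay designs, tolerance
breadth (CTmax − CTmin) and safety margin (CTmax − T_max,habitat)
calculators, logger-series analytics (daily summaries, dawn-to-peak heating
rates, exact time-in-band exposure durations, transient-spike detection),
and synthetic generators for both data streams.

## Worked example

Fit a TDT curve to four simulated winter-acclimated trials (ramps from 26 °C
at 0.2–0.5 °C/min, 15 fish per trial, 0.8 °C between-fish SD), then ask what
the curve implies for a slow habitat ramp:

```python
import numpy as np
import pandas as pd
from thermaltol import (AssayGeneratorConfig, ThermalDeathTime,
                        safety_margin, simulate_assay)
from thermaltol.simulate import trial_summaries_from_records

rng = np.random.default_rng(42)
frames = []
for rate in (0.2, 0.32, 0.42, 0.5):
    cfg = AssayGeneratorConfig(z_true=5.58, t_static_true=43.437,
                               heating_rate=rate, rate_jitter_sd=0.0,
                               start_temp=26.0, n_trials=1, n_fish=15)
    rec, _ = simulate_assay(cfg, rng=rng)
    rec["trial_id"] = f"r{rate}"
    frames.append(rec)
trials = trial_summaries_from_records(pd.concat(frames, ignore_index=True))

res = ThermalDeathTime.from_dataframe(trials).fit()
print(res.summary())
print("CTmax at a habitat rate of 0.01 °C/min from 28 °C:",
      f"{res.predict_ctmax(0.01, 28.0):.2f} °C")
print("Tolerable time at 33 °C:", f"{res.tolerable_time(33.0):.1f} min")
```

Output:

```
Thermal Death Time model
==========================================================
species: P. sulphuraria                 trials: 4
oxygen:  hypoxic                        t_ref: 1 min
----------------------------------------------------------
                  coef     std err
z               4.8484      0.5031
t_static       42.4442      0.6170
----------------------------------------------------------
RSS 0.0439196   rate spread 0.300 °C/min

CTmax at a habitat rate of 0.01 °C/min from 28 °C: 31.60 °C
Tolerable time at 33 °C: 88.7 min
```

Read: with four noisy trials the estimated heat sensitivity is ẑ ≈ 4.85
(truth 5.58 — z is genuinely hard to pin down from a 0.3 °C/min rate spread,
which is why the standard error is ~0.5). At a realistic habitat warming
rate of 0.01 °C/min the fitted curve predicts knockdown near 31.6 °C —
several degrees *below* the lab CTmax at 0.42 °C/min, because slow ramps
give injury far longer to accumulate — and 33 °C water is tolerable for
roughly 89 minutes, less than warm sites can sustain on a dry-season
afternoon.

The same pipeline is scriptable from a shell:

```sh
thermaltol report --seed 11 --out-dir out/
```

which chains simulate → fit → predict → exposure → margins → compare and
writes `trials.csv`, `tdt_fit.yaml`, `daily_summary.csv`, `exposure.csv`,
`events.csv`, `predicted_ctmax.csv`, `tolerable_times.csv`,
`cell_means.csv`, `margins.csv` and `verdicts.csv` (site × band × species
rows marked `EXCEEDS` where observed mean daily exposure outruns the
predicted tolerable duration).

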