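# Methods

## The thermal death time model

`thermaltol` treats heat knockdown as the endpoint of cumulative injury.
The tolerance–time (thermal death time, TDT) curve

    log10(t_tol / t_ref) = (t_static − T) / z

says that a constant exposure at temperature `T` is tolerable for `t_tol`
minutes; `z` (°C) is the temperature increment that divides tolerable time
by ten, and `t_static` (°C) is the constant temperature tolerable for
exactly the reference duration `t_ref`. Under a time-varying trajectory
`T(t)` injury accumulates at rate `1 / t_tol(T(t))` and knockdown occurs at
accumulated injury 1. The model's assumptions, in decreasing order of
consequence:

* **Injury is additive and memoryless.** No repair during the exposure, no
  hardening response; rate depends only on the current temperature. This is
  the standard dynamic–static conversion assumption and is what makes the
  linear-ramp closed form exact:

      Tk = t_static + z·log10( r·ln10·t_ref/z + 10^((T0 − t_static)/z) )

* **All-or-none endpoint.** Knockdown, not graded survival fractions.
* **One curve per group.** `z` and `t_static` are shared by all fish in a
  species × oxygen cell; individual variation enters (in the simulator) only
  as a location shift of `t_static`.

The start-temperature term `10^((T0 − t_static)/z)` is retained by default.
It matters precisely where habitat predictions live: at 0.003 °C/min a ramp
spends many hours at intermediate temperatures and dropping the term
(`drop_start_term=True`, provided for cross-checks against formulations
that assume `T0 ≪ t_static`) biases predicted knockdown upward.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `z` | °C per log10(min) | fitted | 2–8 typical for fishes; >20 flagged (near-vertical curve) |
| `t_static` | °C | fitted | warned outside 20–50 °C |
| `t_ref` | min | 1 | makes `t_static` the "1-minute CTmax"; the common anchoring convention. Configurable; all tolerable times scale linearly with it |

## Estimation

`fit_tdt` (wrapped by `ThermalDeathTime.fit()`) minimises the sum of squared
differences between each trial's mean knockdown temperature and the ramp
closed form at its heating rate. Trials — not fish — are the data points:
fish ramped together share one realised heating rate, so replicates within a
trial are a single measurement of the (rate, knockdown) relation. Least
squares on the closed form is the only estimator identifiable from such
pairs alone.

Numerical choices:

* Deterministic multi-start Nelder–Mead from z₀ ∈ {3, 5, 7} with
  t_static₀ = max knockdown + 2 °C; `xatol` 1e-10, `fatol` 1e-12; best of
  three kept. Reproducible without seeds; recovers noiseless truth to
  <1e-4.
* `z` is identified only by heating-rate variation. All-equal rates raise;
  a spread under 0.05 °C/min (the lab-trial jitter scale) flags the fit
  ill-conditioned, and such fits should be read as order-of-magnitude only.
* Standard errors come from the Gauss–Newton approximation
  s²(JᵀJ)⁻¹ with a central-difference Jacobian; with 3–4 trials and 2
  parameters they are indicative, not inferential.
* Injury integration uses the exact exponential closed form per linear
  segment; composite Simpson at 0.01-min resolution is available as a
  cross-check (`method="quadrature"`) and agrees to ~1e-6 relative.

## Logger analytics

* **Days** are civil local days in the input's own clock; no timezone
  arithmetic. Days with <2 samples are dropped; days with <75% of the
  nominal sample count are flagged `partial` and excluded from cross-day
  means (but kept for event detection).
* **Heating rate** is (T_max − T_anchor)/Δt from a sunrise proxy to the
  daily maximum. True sunrise is not in logger data, so the default anchor
  is the dawn minimum (coolest sample in 00:00–12:00); a fixed-clock anchor
  (default 06:00) is available for sensitivity checks. A day whose maximum
  equals the anchor temperature has rate 0; a warmer maximum *before* the
  anchor leaves the rate undefined (NaN + warning). Rates are reported to 3
  decimals — the resolution at which habitat rates (0.003–0.066 °C/min) are
  distinct.
* **Exposure durations** interpolate temperature linearly between samples
  and solve band crossings exactly per segment, splitting segments at
  midnight; durations are therefore invariant under resampling of a linear
  segment. Bands are half-open [lo, hi), default 1 °C steps over 32–36 °C.
* **Spike detection** scores each sample against the median temperature at
  the same clock time on all *other* days (needs ≥3 days), so a one-off
  warm release stands out against the site's usual diel cycle. Consecutive
  samples with excess ≥ δ (default 1.0 °C, with 1e-9 slack so an excursion
  of exactly δ is not lost to roundoff) form one event; duration is
  last-minus-first exceeding sample plus one sampling interval, so a
  60-min excursion logged hourly is recovered as 60 min when it covers one
  sample and 120 when it straddles two.

## Assay statistics

Cell summaries of the 2×2 species × oxygen design are **trial-blocked**:
the cell mean is the unweighted mean of trial means, with the pooled-fish
mean and individual extremes reported alongside. The interaction is tested
by permutation: the statistic is the difference-in-differences of blocked
cell means, and the null permutes oxygen labels across trials within each
species (trials are exchangeable within species under the null);
p = (1 + #{|null| ≥ |obs|})/(n_perm + 1). The test is exact under the null
up to permutation-sampling noise — type-I error 0.054 at α = 0.05 over 1000
simulations.

**Known limitation.** When the oxygen effect is concentrated in one species
(one cell shifted, the other species flat), the shifted species' label
permutations reproduce its own main effect in the null distribution, and
with 3 trials/cell (C(6,3) = 20 arrangements per species) the attainable
p-value plateaus near 0.05 — power for a 2 °C one-cell shift is only ~0.5
regardless of noise level. Power quoted for the test (≥0.8, measured ≈0.96)
refers to a *pure* interaction of the same 2 °C contrast (cell shifts
±0.5 °C, no main effects). With unbalanced interaction patterns, more
trials per cell — not more permutations — is what buys power.

Safety margins (CTmax − T_max,habitat) and tolerance breadths
(CTmax − CTmin) are reported to one decimal, rounded half away from zero
(11.45 → 11.5), matching the convention of published margin tables. Breadth
is computed from the means as supplied; breadths published from unrounded
internal means will differ in the last digit and are not reconciled.

## Synthetic data

`simulate_assay` draws each fish's static limit from
Normal(t_static_true, between_fish_sd) and knocks it down with the ramp
closed form at the trial's realised rate, itself drawn from
Normal(rate, 0.06) truncated at 0.05 °C/min. Defaults describe ramping
assays at 0.42 °C/min started at the collection temperature (30 °C hot
season, 26 °C cool season), 15 fish × 3 trials, between-fish SD 0.8 °C. The
species presets (z 5.58 / t_static 43.44 °C; z 4.19 / 43.07 °C) were
back-solved once so a 0.42 °C/min ramp from 26 °C reproduces cool-season
knockdown means of 39.2 and 40.4 °C respectively.

`simulate_logger` is a single-harmonic cosine,
mean + A·cos(2π(t − t_max)/24 h) + Normal(0, σ), hourly by default, with an
optional additive square spike. Defaults (mean 31.7 °C, A 3.5 °C, peak at
15:00, σ 0.1 °C) give the dry-season daily range 28.2–35.2 °C; the default
spike is +1 °C for 60 min. The dawn-minimum-to-peak heating rate of the
noiseless cosine is exactly 2A/720 °C/min (0.0097 for the default
amplitude), which the logger analytics recover within sampling error.

What the generators deliberately do **not** emulate — and hence what green
tests do not establish about real data: asymmetric diel profiles (real warm
pools heat faster than they cool), weather-driven day-to-day variance and
autocorrelation, logger drift and gaps, multi-site spatial correlation,
acclimation shifts between seasons within one fit, oxygen dynamics, and any
covariance between a fish's size and its thermal limit. Conclusions about a
real system still require its own logger files and assay tables.

## Degenerate inputs and tie-breaks

* `tolerable_time` is defined for any finite temperature; cold inputs give
  astronomically long (finite) times, returned as-is.
* Constant-temperature segments inside `injury_integral` short-circuit the
  closed form (slope → 0 limit) to avoid 0/0.
* In exposure comparison, observed = predicted is **not** an exceedance
  (strict inequality; conservative toward the null).
* Constant segments sitting exactly on a band edge belong to the band whose
  lower edge they touch (half-open convention).
* CSV floats are written at 4 decimals; one-decimal presentation rounding
  is applied only in human-facing report text.

## Problem sizes

The shipped test-and-acceptance configuration uses 3–4 trials × 15 fish per
fit, 7–14-day hourly logger series, a 5×5×3 (z, rate, start) grid for the
closed-form-vs-quadrature equivalence check, 100 replicate fits for noisy
recovery, and 1000 simulations × 999 permutations for test calibration —
sizes at which every Monte-Carlo check is stable across seeds while the
whole suite runs in about a minute.
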