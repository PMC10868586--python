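"""Thermal death time (TDT) model core.

The TDT framework relates a constant stress temperature ``T`` to the time an
animal endures it before losing organised locomotion (knockdown):

    log10(t_tol / t_ref) = (t_static - T) / z

``z`` is the heat-sensitivity coefficient (°C per decade of time: warming by
``z`` divides tolerable time by ten) and ``t_static`` is the constant
temperature tolerated for exactly the reference duration ``t_ref`` (1 min by
default, making ``t_static`` the "1-minute CTmax").

Under a time-varying temperature trajectory, heat injury accumulates at rate
``1 / t_tol(T(t))``; knockdown occurs when the accumulated injury reaches 1.
For a linear ramp at rate ``r`` from ``T0`` this integral has a closed form,
giving the knockdown temperature of a dynamic (ramping) CTmax assay:

    Tk = t_static + z * log10( r * ln(10) * t_ref / z + 10**((T0 - t_static)/z) )

Fitting ``(z, t_static)`` to trial-level (heating rate, mean knockdown
temperature) pairs inverts this relation, allowing predictions of knockdown
temperature at the much slower heating rates animals meet in their habitat
and of tolerable exposure durations at ecologically relevant temperatures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

LN10 = math.log(10.0)

__all__ = [
    "TDTParameters",
    "TrialSummary",
    "TDTFit",
    "tolerable_time",
    "injury_integral",
    "dynamic_knockdown",
    "static_limit_for_knockdown",
    "fit_tdt",
    "predict_ctmax_at_rate",
]


@dataclass(frozen=True)
class TDTParameters:
    """TDT curve parameters.

    Parameters
    ----------
    z : float
        Heat-sensitivity coefficient, °C per log10(minute). Warming by ``z``
        °C divides tolerable exposure time by ten. Must be positive; values
        above 20 are flagged as suspicious (near-vertical TDT curve).
    t_static : float
        Static thermal limit, °C: the constant temperature producing
        knockdown at exactly ``t_ref`` minutes. Values outside the 20–50 °C
        band plausible for fishes trigger a warning, not an error.
    t_ref : float
        Reference duration in minutes (default 1).
    """

    z: float
    t_static: float
    t_ref: float = 1.0

    def __post_init__(self) -> None:
        if not (self.z > 0):
            raise ValueError(f"z must be positive, got {self.z}")
        if not (self.t_ref > 0):
            raise ValueError(f"t_ref must be positive, got {self.t_ref}")
        if not math.isfinite(self.t_static):
            raise ValueError(f"t_static must be finite, got {self.t_static}")
        if not 20.0 <= self.t_static <= 50.0:
            warnings.warn(
                f"t_static={self.t_static:.2f} °C is outside the 20-50 °C "
                "plausibility band for fishes",
                stacklevel=2,
            )
        if self.z > 20.0:
            warnings.warn(
                f"z={self.z:.2f} is suspiciously large (near-vertical TDT "
                "curve; tolerable time almost insensitive to temperature)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TrialSummary:
    """One dynamic CTmax trial collapsed to its mean: the unit of TDT fitting.

    Replicate fish ramped together share a single heating rate, so a trial
    contributes one (rate, knockdown) data point.
    """

    trial_id: str
    species: str
    oxygen: str
    heating_rate: float
    start_temp: float
    mean_knockdown_temp: float
    n_fish: int = 1

    def __post_init__(self) -> None:
        if not self.heating_rate > 0:
            raise ValueError(
                f"trial {self.trial_id}: heating_rate must be > 0, "
                f"got {self.heating_rate}"
            )
        if not self.mean_knockdown_temp > self.start_temp:
            raise ValueError(
                f"trial {self.trial_id}: mean_knockdown_temp "
                f"({self.mean_knockdown_temp}) must exceed start_temp "
                f"({self.start_temp})"
            )
        if self.n_fish < 1:
            raise ValueError(f"trial {self.trial_id}: n_fish must be >= 1")


def tolerable_time(params: TDTParameters, temp):
    """Tolerable exposure duration (minutes) at a constant temperature.

    ``t_ref * 10**((t_static - temp)/z)``; strictly decreasing in ``temp``.
    Defined for any finite temperature — values for cool temperatures can be
    astronomically large and are returned as-is.

    ``temp`` may be a scalar or array.
    """
    temp = np.asarray(temp, dtype=float)
    out = params.t_ref * np.power(10.0, (params.t_static - temp) / params.z)
    return float(out) if out.ndim == 0 else out


def _segment_injury(params: TDTParameters, t0, t1, temp0, temp1) -> float:
    """Exact injury over one linear temperature segment.

    With T(t) linear, ∫ dt / t_tol(T(t)) integrates in closed form:
    (z / (m ln10 t_ref)) * (10**((T1-Ts)/z) - 10**((T0-Ts)/z)) for slope
    m != 0, and Δt/t_tol(T0) for a flat segment.
    """
    dt = t1 - t0
    z, ts, tref = params.z, params.t_static, params.t_ref
    if temp1 == temp0:
        return dt * 10.0 ** ((temp0 - ts) / z) / tref
    m = (temp1 - temp0) / dt
    return (z / (m * LN10 * tref)) * (
        10.0 ** ((temp1 - ts) / z) - 10.0 ** ((temp0 - ts) / z)
    )


def injury_integral(params: TDTParameters, trajectory, method: str = "closed") -> float:
    """Accumulated heat injury along a temperature trajectory.

    Injury is the dimensionless integral of the instantaneous damage rate
    ``1 / tolerable_time(T(t))``; knockdown corresponds to injury = 1.
    Temperature is interpolated linearly between samples.

    Parameters
    ----------
    trajectory : array-like, shape (n, 2)
        Time-ordered (minute, °C) samples; n >= 2, strictly increasing times.
    method : {'closed', 'quadrature'}
        'closed' evaluates the exact exponential closed form per linear
        segment (default). 'quadrature' applies composite Simpson's rule at
        0.01-minute resolution to the linearly interpolated trajectory — a
        cross-check path, and the one to extend for genuinely non-linear
        trajectories.

    Returns
    -------
    float
        Accumulated injury; additive over concatenated trajectories.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2 or traj.shape[0] < 2:
        raise ValueError("trajectory must be an (n, 2) array with n >= 2")
    times, temps = traj[:, 0], traj[:, 1]
    if not np.all(np.diff(times) > 0):
        raise ValueError("trajectory times must be strictly increasing")
    if method == "closed":
        return float(
            sum(
                _segment_injury(params, times[i], times[i + 1], temps[i], temps[i + 1])
                for i in range(len(times) - 1)
            )
        )
    if method == "quadrature":
        from scipy.integrate import simpson

        total = 0.0
        for i in range(len(times) - 1):
            n = max(int(math.ceil((times[i + 1] - times[i]) / 0.01)), 2)
            if n % 2:  # Simpson needs an even interval count
                n += 1
            tt = np.linspace(times[i], times[i + 1], n + 1)
            temp = np.interp(tt, times, temps)
            rate = 10.0 ** ((temp - params.t_static) / params.z) / params.t_ref
            total += simpson(rate, x=tt)
        return float(total)
    raise ValueError(f"unknown method {method!r}")


def dynamic_knockdown(
    params: TDTParameters,
    start_temp: float,
    heating_rate: float,
    drop_start_term: bool = False,
) -> float:
    """Knockdown temperature of a linear ramp at ``heating_rate`` °C/min.

    Solves the ramp injury equation in closed form:

        Tk = t_static + z*log10( r*ln10*t_ref/z + 10**((start - t_static)/z) )

    Strictly increasing in ``heating_rate`` and in ``start_temp``.

    ``drop_start_term`` omits the start-temperature term, matching
    formulations that assume the ramp starts far below ``t_static``; kept as
    a cross-checking option only.
    """
    if not heating_rate > 0:
        raise ValueError(f"heating_rate must be > 0, got {heating_rate}")
    z, ts, tref = params.z, params.t_static, params.t_ref
    if start_temp >= ts:
        warnings.warn(
            f"start_temp={start_temp} already at/above t_static={ts}: injury "
            "rate exceeds 1/t_ref before the ramp begins",
            stacklevel=2,
        )
    arg = heating_rate * LN10 * tref / z
    if not drop_start_term:
        arg += 10.0 ** ((start_temp - ts) / z)
    return ts + z * math.log10(arg)


def static_limit_for_knockdown(
    z: float,
    knockdown_temp: float,
    start_temp: float,
    heating_rate: float,
    t_ref: float = 1.0,
) -> float:
    """Static limit t_static implied by one dynamic trial at a known z.

    Inverts :func:`dynamic_knockdown`; handy for configuring simulations that
    must reproduce an observed ramp outcome.
    """
    if not heating_rate > 0:
        raise ValueError("heating_rate must be > 0")
    numer = heating_rate * LN10 * t_ref / z
    denom = 10.0 ** (knockdown_temp / z) - 10.0 ** (start_temp / z)
    if denom <= 0:
        raise ValueError("knockdown_temp must exceed start_temp")
    return -z * math.log10(numer / denom)


def predict_ctmax_at_rate(
    params: TDTParameters, site_rate: float, site_start: float
) -> float:
    """Predicted CTmax under a habitat heating rate.

    Thin alias of :func:`dynamic_knockdown` taking site-derived inputs (a
    site's sunrise-to-peak heating rate and dawn temperature), for
    report-shaped tables of predicted CTmax per site.
    """
    return dynamic_knockdown(params, site_start, site_rate)


@dataclass
class TDTFit:
    """Outcome of :func:`fit_tdt`: parameters plus fit diagnostics."""

    params: TDTParameters
    residuals: np.ndarray
    rss: float
    n_trials: int
    bse: tuple[float, float]  # approximate SEs of (z, t_static)
    rate_spread: float
    warnings: list[str] = field(default_factory=list)

    @property
    def z(self) -> float:
        return self.params.z

    @property
    def t_static(self) -> float:
        return self.params.t_static


def _predicted_knockdowns(z, t_static, rates, starts, t_ref):
    arg = rates * LN10 * t_ref / z + 10.0 ** ((starts - t_static) / z)
    return t_static + z * np.log10(arg)


def fit_tdt(
    trials,
    start_temp_policy=None,
    t_ref: float = 1.0,
) -> TDTFit:
    """Estimate (z, t_static) from trial-level ramp outcomes by least squares.

    Minimises the sum of squared differences between each trial's mean
    knockdown temperature and the closed-form ramp knockdown at its heating
    rate. Trial means are the data points: replicate fish within a trial
    share one heating rate, so a trial is a single measurement.

    z is identified only by variation in heating rate; all-equal rates raise,
    and a spread below 0.05 °C/min flags the fit as ill-conditioned.

    Parameters
    ----------
    trials : sequence of TrialSummary
        At least 2 trials spanning at least 2 distinct heating rates.
    start_temp_policy : None, float, or callable
        None uses each trial's own start_temp; a float overrides all trials;
        a callable maps a TrialSummary to a start temperature.
    t_ref : float
        Reference duration (minutes) anchoring t_static.

    Returns
    -------
    TDTFit
        Fitted parameters, per-trial residuals, RSS, approximate standard
        errors and warnings.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to fit a TDT curve")
    rates = np.array([t.heating_rate for t in trials], dtype=float)
    obs = np.array([t.mean_knockdown_temp for t in trials], dtype=float)
    if start_temp_policy is None:
        starts = np.array([t.start_temp for t in trials], dtype=float)
    elif callable(start_temp_policy):
        starts = np.array([start_temp_policy(t) for t in trials], dtype=float)
    else:
        starts = np.full(len(trials), float(start_temp_policy))

    spread = float(rates.max() - rates.min())
    if spread == 0.0:
        raise ValueError(
            "z unidentifiable from a single heating rate: all trials share "
            f"rate {rates[0]:.3g} °C/min"
        )
    fit_warnings: list[str] = []
    if spread < 0.05:
        fit_warnings.append(
            f"heating-rate spread {spread:.4f} °C/min < 0.05: z is "
            "ill-conditioned; interpret with care"
        )

    def rss_of(x):
        z, ts = x
        if z <= 0.05:
            return 1e12 + (0.05 - z) * 1e12
        pred = _predicted_knockdowns(z, ts, rates, starts, t_ref)
        r = obs - pred
        return float(r @ r)

    # Deterministic multi-start direct search: reproducible without seeds.
    best = None
    for z0 in (3.0, 5.0, 7.0):
        x0 = np.array([z0, obs.max() + 2.0])
        res = optimize.minimize(
            rss_of,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    z_hat, ts_hat = best.x
    pred = _predicted_knockdowns(z_hat, ts_hat, rates, starts, t_ref)
    resid = obs - pred
    rss = float(resid @ resid)

    # Gauss-Newton covariance from a numerical Jacobian of the predictions.
    eps = 1e-6
    jac = np.empty((len(trials), 2))
    jac[:, 0] = (
        _predicted_knockdowns(z_hat + eps, ts_hat, rates, starts, t_ref)
        - _predicted_knockdowns(z_hat - eps, ts_hat, rates, starts, t_ref)
    ) / (2 * eps)
    jac[:, 1] = (
        _predicted_knockdowns(z_hat, ts_hat + eps, rates, starts, t_ref)
        - _predicted_knockdowns(z_hat, ts_hat - eps, rates, starts, t_ref)
    ) / (2 * eps)
    dof = max(len(trials) - 2, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
        bse = (float(np.sqrt(abs(cov[0, 0]))), float(np.sqrt(abs(cov[1, 1]))))
    except np.linalg.LinAlgError:
        bse = (float("nan"), float("nan"))
        fit_warnings.append("singular Jacobian: standard errors unavailable")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        params = TDTParameters(z=z_hat, t_static=ts_hat, t_ref=t_ref)
    fit_warnings.extend(str(w.message) for w in caught)

    return TDTFit(
        params=params,
        residuals=resid,
        rss=rss,
        n_trials=len(trials),
        bse=bse,
        rate_spread=spread,
        warnings=fit_warnings,
    )
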