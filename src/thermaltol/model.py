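"""Model/results interface over the TDT core.

`ThermalDeathTime` is constructed from trial-level ramp data (a DataFrame,
CSV, or `TrialSummary` objects); its `fit()` returns a
`ThermalDeathTimeResults` carrying the estimates, approximate standard
errors, residual diagnostics and prediction methods, in the style of
statsmodels model/results pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import tdt
from .tdt import TDTParameters, TrialSummary

__all__ = ["ThermalDeathTime", "ThermalDeathTimeResults"]

TRIAL_COLUMNS = [
    "trial_id",
    "species",
    "oxygen",
    "heating_rate_c_per_min",
    "start_temp_c",
    "mean_knockdown_c",
    "n_fish",
]


class ThermalDeathTime:
    """Thermal death time model for dynamic (ramping) CTmax trials.

    Each trial contributes one data point: its heating rate and the mean
    knockdown temperature of the fish ramped together. The model predicts
    knockdown via the closed-form ramp solution of cumulative heat injury,
    and `fit` estimates the heat-sensitivity coefficient ``z`` and the static
    limit ``t_static`` (the constant temperature tolerated for exactly
    ``t_ref`` minutes) by nonlinear least squares.

    Parameters
    ----------
    trials : sequence of TrialSummary
    t_ref : float
        Reference duration in minutes anchoring ``t_static`` (default 1).

    Examples
    --------
    >>> model = ThermalDeathTime.from_csv("trials.csv")      # doctest: +SKIP
    >>> res = model.fit()                                    # doctest: +SKIP
    >>> res.predict_ctmax(heating_rate=0.01, start_temp=28)  # doctest: +SKIP
    """

    def __init__(self, trials, t_ref: float = 1.0):
        self.trials = list(trials)
        self.t_ref = float(t_ref)
        if not self.trials:
            raise ValueError("no trials supplied")
        self.species = sorted({t.species for t in self.trials})
        self.oxygen = sorted({t.oxygen for t in self.trials})

    @classmethod
    def from_trials(cls, trials, t_ref: float = 1.0) -> "ThermalDeathTime":
        return cls(trials, t_ref=t_ref)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        species: str | None = None,
        oxygen: str | None = None,
        t_ref: float = 1.0,
    ) -> "ThermalDeathTime":
        """Build from a trials table (columns as in ``trials.csv``).

        Optional ``species``/``oxygen`` filters select one experimental cell.
        """
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise KeyError(f"trials table missing columns: {', '.join(missing)}")
        if species is not None:
            df = df[df["species"] == species]
        if oxygen is not None:
            df = df[df["oxygen"] == oxygen]
        if df.empty:
            raise ValueError(
                f"no trials left after selecting species={species!r}, "
                f"oxygen={oxygen!r}"
            )
        trials = [
            TrialSummary(
                trial_id=str(r.trial_id),
                species=str(r.species),
                oxygen=str(r.oxygen),
                heating_rate=float(r.heating_rate_c_per_min),
                start_temp=float(r.start_temp_c),
                mean_knockdown_temp=float(r.mean_knockdown_c),
                n_fish=int(r.n_fish),
            )
            for r in df.itertuples()
        ]
        return cls(trials, t_ref=t_ref)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ThermalDeathTime":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def fit(self, start_temp_policy=None) -> "ThermalDeathTimeResults":
        """Fit (z, t_static) by least squares on trial knockdown temperatures."""
        fit = tdt.fit_tdt(self.trials, start_temp_policy=start_temp_policy, t_ref=self.t_ref)
        return ThermalDeathTimeResults(self, fit)


class ThermalDeathTimeResults:
    """Fitted TDT curve: estimates, uncertainties and predictions."""

    def __init__(self, model: ThermalDeathTime, fit: tdt.TDTFit):
        self.model = model
        self._fit = fit
        self.params: TDTParameters = fit.params
        self.z = fit.params.z
        self.t_static = fit.params.t_static
        self.t_ref = fit.params.t_ref
        self.bse = {"z": fit.bse[0], "t_static": fit.bse[1]}
        self.resid = fit.residuals
        self.rss = fit.rss
        self.n_trials = fit.n_trials
        self.warnings = list(fit.warnings)

    # -- predictions -------------------------------------------------------
    def predict_ctmax(self, heating_rate, start_temp) -> float:
        """Knockdown temperature of a ramp at the given rate and start."""
        return tdt.predict_ctmax_at_rate(self.params, heating_rate, start_temp)

    def tolerable_time(self, temp):
        """Tolerable constant-temperature exposure, minutes."""
        return tdt.tolerable_time(self.params, temp)

    def injury(self, trajectory, method: str = "closed") -> float:
        """Accumulated injury along an arbitrary (minute, °C) trajectory."""
        return tdt.injury_integral(self.params, trajectory, method=method)

    def predict_table(self, rates, start_temp, label: str | None = None) -> pd.DataFrame:
        """Predicted CTmax per heating rate, report-shaped."""
        rows = [
            {
                "label": label or "+".join(self.model.species),
                "heating_rate_c_per_min": float(r),
                "start_temp_c": float(start_temp),
                "predicted_ctmax_c": self.predict_ctmax(float(r), start_temp),
            }
            for r in rates
        ]
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------
    def to_dict(self) -> dict:
        species = self.model.species[0] if len(self.model.species) == 1 else self.model.species
        oxygen = self.model.oxygen[0] if len(self.model.oxygen) == 1 else self.model.oxygen
        return {
            "species": species,
            "oxygen": oxygen,
            "z": round(float(self.z), 4),
            "t_static": round(float(self.t_static), 4),
            "t_ref_min": float(self.t_ref),
            "rss": round(float(self.rss), 6),
            "n_trials": int(self.n_trials),
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Thermal Death Time model",
            "=" * 58,
            f"species: {', '.join(self.model.species):<30} trials: {self.n_trials}",
            f"oxygen:  {', '.join(self.model.oxygen):<30} t_ref: {self.t_ref:g} min",
            "-" * 58,
            f"{'':12}{'coef':>10}{'std err':>12}",
            f"{'z':12}{self.z:>10.4f}{self.bse['z']:>12.4f}",
            f"{'t_static':12}{self.t_static:>10.4f}{self.bse['t_static']:>12.4f}",
            "-" * 58,
            f"RSS {self.rss:.6g}   rate spread {self._fit.rate_spread:.3f} °C/min",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ThermalDeathTimeResults z={self.z:.3f} t_static={self.t_static:.3f} "
            f"n_trials={self.n_trials}>"
        )

    # -- plotting ----------------------------------------------------------
    def plot_tdt_curve(self, temps=None, ax=None):
        """Plot the fitted tolerance-time curve (log-minutes vs °C)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if temps is None:
            temps = np.linspace(self.t_static - 15, self.t_static + 2, 200)
        ax.semilogy(temps, self.tolerable_time(temps))
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("tolerable time (min)")
        ax.set_title(f"TDT curve  z={self.z:.2f}, t_static={self.t_static:.1f} °C")
        return ax
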