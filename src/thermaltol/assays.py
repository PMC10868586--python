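"""Assay-level summaries and comparisons.

Trial-blocked marginal means for the species × oxygen design, a permutation
test of the species × oxygen interaction (trials as the exchangeable unit),
tolerance breadth (CTmax − CTmin), and thermal safety margins (CTmax minus
the maximum habitat temperature experienced).

Fish ramped together in one trial are not independent; trials are, so every
statistic here first collapses records to trial means and treats the trial
as the blocking/permutation unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ASSAY_COLUMNS",
    "read_assays",
    "marginal_means",
    "interaction_permutation_test",
    "PermutationTestResult",
    "tolerance_breadth",
    "safety_margin",
    "round_half_away",
]

ASSAY_COLUMNS = [
    "fish_id",
    "species",
    "oxygen",
    "trial_id",
    "direction",
    "knockdown_temp_c",
    "standard_length_mm",
    "collection_temp_c",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 11.45 → 11.5, −11.45 → −11.5).

    Python's builtin round is banker's rounding; printed-style one-decimal
    margins need the away-from-zero convention.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def read_assays(path) -> pd.DataFrame:
    """Read `assays.csv` and validate columns and knockdown directions."""
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"assay table missing columns: {', '.join(missing)}")
    return validate_assays(df)


def validate_assays(df: pd.DataFrame) -> pd.DataFrame:
    heat = df["direction"] == "heat"
    cold = df["direction"] == "cold"
    bad_heat = heat & (df["knockdown_temp_c"] <= df["collection_temp_c"])
    bad_cold = cold & (df["knockdown_temp_c"] >= df["collection_temp_c"])
    if bad_heat.any() or bad_cold.any():
        n = int(bad_heat.sum() + bad_cold.sum())
        raise ValueError(
            f"{n} records violate knockdown-vs-collection ordering "
            "(heat knockdowns must exceed, cold fall below, collection temp)"
        )
    return df


def _trial_means(df: pd.DataFrame, factors) -> pd.DataFrame:
    return (
        df.groupby([*factors, "trial_id"], as_index=False)["knockdown_temp_c"]
        .mean()
        .rename(columns={"knockdown_temp_c": "trial_mean_c"})
    )


def marginal_means(
    records: pd.DataFrame, factors=("species", "oxygen")
) -> pd.DataFrame:
    """Cell means of the factorial design, trial as the blocking unit.

    Per cell the blocked mean is the unweighted mean of trial means — the
    estimated-marginal-mean analogue when trials are the random blocks — and
    the pooled mean over individual fish is reported alongside, with the
    individual min/max. Every cell of the factor cross must be populated.
    """
    factors = list(factors)
    levels = [sorted(records[f].unique()) for f in factors]
    grid = pd.MultiIndex.from_product(levels, names=factors)
    present = set(map(tuple, records[factors].drop_duplicates().itertuples(index=False)))
    for cell in grid:
        if tuple(cell) not in present:
            name = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise ValueError(f"empty design cell: {name}")

    tm = _trial_means(records, factors)
    blocked = tm.groupby(factors, as_index=False)["trial_mean_c"].mean().rename(
        columns={"trial_mean_c": "mean_blocked_c"}
    )
    pooled = records.groupby(factors, as_index=False).agg(
        mean_pooled_c=("knockdown_temp_c", "mean"),
        min_c=("knockdown_temp_c", "min"),
        max_c=("knockdown_temp_c", "max"),
        n_fish=("knockdown_temp_c", "size"),
        n_trials=("trial_id", "nunique"),
    )
    return blocked.merge(pooled, on=factors).sort_values(factors).reset_index(drop=True)


@dataclass(frozen=True)
class PermutationTestResult:
    observed_contrast: float
    p_value: float
    n_perm: int
    null_contrasts: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PermutationTestResult(observed={self.observed_contrast:.4f}, "
            f"p={self.p_value:.4f}, n_perm={self.n_perm})"
        )


def interaction_permutation_test(
    records: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test of the species × oxygen interaction on trial means.

    The observed statistic is the difference-in-differences of trial-blocked
    cell means, (A:oxy1 − A:oxy0) − (B:oxy1 − B:oxy0) with species and oxygen
    levels taken in sorted order. The null distribution permutes oxygen
    labels across trials *within* each species — trials are exchangeable
    under the no-interaction-or-oxygen-effect null within a species — and the
    p-value uses the add-one rule p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1).

    Requires the full 2 × 2 design populated with at least 2 trials per
    species. Deterministic under ``seed``.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    species = sorted(records["species"].unique())
    oxygens = sorted(records["oxygen"].unique())
    if len(species) != 2 or len(oxygens) != 2:
        raise ValueError(
            f"need a 2x2 species x oxygen design, got {len(species)} species "
            f"x {len(oxygens)} oxygen levels"
        )
    tm = _trial_means(records, ["species", "oxygen"])
    for sp in species:
        sub = tm[tm["species"] == sp]
        if len(sub) < 2 or sub["oxygen"].nunique() < 2:
            raise ValueError(
                f"no permutation support: species {sp!r} needs >=2 trials "
                "covering both oxygen levels"
            )

    rng = np.random.default_rng(seed)

    def did(groups):
        # groups: per species, (values, oxygen-one-hot) arrays
        diffs = []
        for vals, is1 in groups:
            diffs.append(vals[is1].mean() - vals[~is1].mean())
        return diffs[0] - diffs[1]

    groups = []
    for sp in species:
        sub = tm[tm["species"] == sp]
        vals = sub["trial_mean_c"].to_numpy(dtype=float)
        is1 = (sub["oxygen"] == oxygens[1]).to_numpy()
        groups.append((vals, is1))
    observed = did(groups)

    # vectorised null: permute the oxygen indicator within each species
    null = np.zeros(n_perm)
    for sign, (vals, is1) in zip((1.0, -1.0), groups):
        n = len(vals)
        n1 = int(is1.sum())
        # random permutation per row via argsort of uniforms
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted_vals = vals[order]
        mean1 = permuted_vals[:, :n1].mean(axis=1)
        mean0 = permuted_vals[:, n1:].mean(axis=1)
        null += sign * (mean1 - mean0)

    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationTestResult(
        observed_contrast=float(observed),
        p_value=float(p),
        n_perm=int(n_perm),
        null_contrasts=null,
    )


def tolerance_breadth(ctmax_mean: float, ctmin_mean: float) -> float:
    """Tolerance breadth CTmax − CTmin (°C), one decimal.

    Computed from the supplied means as given; no attempt to reconcile with
    breadths derived from differently rounded inputs.
    """
    if not ctmax_mean > ctmin_mean:
        raise ValueError(
            f"ctmax_mean ({ctmax_mean}) must exceed ctmin_mean ({ctmin_mean})"
        )
    return round_half_away(ctmax_mean - ctmin_mean, 1)


def safety_margin(ctmax: float, t_max_habitat: float) -> float:
    """Thermal safety margin CTmax − T_max_habitat (°C), one decimal.

    Negative margins are meaningful: the habitat maximum already overlaps
    the animal's critical limit.
    """
    if not (np.isfinite(ctmax) and np.isfinite(t_max_habitat)):
        raise ValueError("ctmax and t_max_habitat must be finite")
    return round_half_away(ctmax - t_max_habitat, 1)
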