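import numpy as np
import pandas as pd
import pytest

from thermaltol import (
    AssayGeneratorConfig,
    TDTParameters,
    TrialSummary,
    dynamic_knockdown,
    simulate_assay,
)


@pytest.fixture
def molly_params() -> TDTParameters:
    """TDT curve typical of a warm-adapted poeciliid."""
    return TDTParameters(z=5.58, t_static=43.437)


@pytest.fixture
def gambusia_params() -> TDTParameters:
    return TDTParameters(z=4.19, t_static=43.067)


def noiseless_trials(params: TDTParameters, rates, start_temp=26.0):
    """Trial summaries generated exactly from the ramp closed form."""
    return [
        TrialSummary(
            trial_id=f"T{i}",
            species="sp",
            oxygen="normoxic",
            heating_rate=r,
            start_temp=start_temp,
            mean_knockdown_temp=dynamic_knockdown(params, start_temp, r),
            n_fish=10,
        )
        for i, r in enumerate(rates)
    ]


@pytest.fixture
def three_rate_trials(molly_params):
    return noiseless_trials(molly_params, [0.2, 0.4, 0.5])


def factorial_records(
    rng: np.random.Generator,
    cell_shifts: dict[tuple[str, str], float],
    base_t_static: float = 43.0,
    n_trials: int = 3,
    n_fish: int = 15,
    between_fish_sd: float = 0.8,
    rate_jitter_sd: float = 0.06,
) -> pd.DataFrame:
    """Assay records for a species x oxygen design with given cell shifts."""
    frames = []
    for (species, oxygen), shift in cell_shifts.items():
        cfg = AssayGeneratorConfig(
            species=species,
            oxygen=oxygen,
            z_true=5.0,
            t_static_true=base_t_static + shift,
            between_fish_sd=between_fish_sd,
            n_fish=n_fish,
            n_trials=n_trials,
            rate_jitter_sd=rate_jitter_sd,
        )
        rec, _ = simulate_assay(cfg, rng=rng)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def null_cell_shifts() -> dict:
    """2x2 design with species main effect but no interaction."""
    return {
        ("A", "hypoxic"): 0.5,
        ("A", "normoxic"): 0.5,
        ("B", "hypoxic"): 0.0,
        ("B", "normoxic"): 0.0,
    }


def pure_interaction_shifts(contrast: float) -> dict:
    """2x2 design whose interaction contrast is ``contrast`` with zero main effects."""
    q = contrast / 4.0
    return {
        ("A", "hypoxic"): q,
        ("A", "normoxic"): -q,
        ("B", "hypoxic"): -q,
        ("B", "normoxic"): q,
    }
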