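"""Readers and writers for the pipeline's delimited-text interfaces.

All tabular interchange is headered CSV; fit reports are YAML. Floats in
machine-facing CSVs keep 4 decimals; one-decimal presentation rounding is
applied only in human-facing report text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "write_csv",
    "write_fit_yaml",
    "read_fit_yaml",
]


def write_csv(df: pd.DataFrame, path, float_decimals: int = 4) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{float_decimals}f")
    return path


def write_fit_yaml(fits: list[dict], path) -> Path:
    """Write one or more fit blocks {species, oxygen, z, t_static, ...}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump({"fits": fits}, fh, sort_keys=False)
    return path


def read_fit_yaml(path) -> list[dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "fits" not in doc:
        raise ValueError(f"{path}: not a fit report (missing 'fits' key)")
    return doc["fits"]
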