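"""Flat-file contracts: delimited text tables and YAML configuration."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .domain import SHOPPER_COLUMNS, STORE_COLUMNS
from .errors import ConfigurationError, DataError
from .synthetic import SimConfig

__all__ = [
    "write_table",
    "read_shoppers",
    "read_stores",
    "load_sim_config",
    "save_sim_config",
]


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as UTF-8 CSV with a header row and '.' decimals."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def _require(df: pd.DataFrame, columns, what: str, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} table {path} missing columns: {', '.join(missing)}")


def read_shoppers(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    required = [c for c in SHOPPER_COLUMNS if c not in ("bg_x_mi", "bg_y_mi", "chosen_store_id")]
    _require(df, required, "shopper", path)
    if "chosen_store_id" in df.columns:
        df["chosen_store_id"] = df["chosen_store_id"].astype("Int64")
    else:
        df["chosen_store_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def read_stores(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    _require(df, STORE_COLUMNS, "store", path)
    return df


def load_sim_config(path) -> SimConfig:
    """Load a flat key/value YAML file of SimConfig fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"simulation config {path} must be a flat mapping")
    return SimConfig.from_dict(raw)


def save_sim_config(config: SimConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    import dataclasses

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    return path
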