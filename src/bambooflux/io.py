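"""Reading and writing the pipeline's delimited-text formats.

All on-disk formats are plain CSV: half-hourly records with an ISO-8601
``timestamp`` column and empty fields for missing values, a companion truth
file (same index, true RE/GEP/NEE and daily alpha/Pmax), a daily LAI series
and YAML run configuration.  Floats are written at 10 significant digits so
that identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .records import validate_records

__all__ = [
    "read_half_hourly",
    "write_half_hourly",
    "read_lai",
    "write_lai",
    "load_config",
    "write_table",
]

FLOAT_FORMAT = "%.10g"


def write_half_hourly(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, float_format=FLOAT_FORMAT, index_label="timestamp")


def read_half_hourly(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    validate_records(records)
    return records


def write_lai(lai: pd.Series, path: str | Path) -> None:
    lai.rename("lai").to_csv(path, float_format=FLOAT_FORMAT, index_label="date")


def read_lai(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, parse_dates=["date"], index_col="date")
    return frame["lai"]


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write an output table deterministically (fixed float format)."""
    table.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
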