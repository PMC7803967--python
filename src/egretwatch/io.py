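"""Readers and writers for the package's plain-text interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

DETECTION_COLUMNS = ["timestamp_iso", "species", "x_min", "y_min", "x_max", "y_max", "score"]


def write_detections_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Detection records as CSV with ISO timestamps (0-based half-open boxes)."""
    out = records.copy()
    out.insert(0, "timestamp_iso", pd.DatetimeIndex(out.pop("timestamp")).strftime("%Y-%m-%dT%H:%M:%S"))
    out[DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df.pop("timestamp_iso"))
    return df[["timestamp", "species", "x_min", "y_min", "x_max", "y_max", "score"]]


def write_weather_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_ledger(ledger: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)


def read_ledger(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
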