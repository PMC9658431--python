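"""Delimited time-series I/O and run configuration.

All tables are comma-separated with a header row and an ISO 8601 local
timestamp in the first column (greenhouse-local clock; no timezone
math).  Run configuration is a single YAML file in which every model
parameter default can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import ModelParams, SiteParams

__all__ = ["RunConfig", "read_timeseries", "write_timeseries", "read_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a simulation run needs beyond the input tables."""

    site: SiteParams = field(default_factory=SiteParams)
    params: ModelParams = field(default_factory=ModelParams)
    senescence_onset: str | None = None
    path_window: tuple = (9, 16)
    output_dir: str = "."


def read_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"site", "model", "senescence_onset", "path_window", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    site = SiteParams(**raw.get("site", {}))
    params = ModelParams(**raw.get("model", {}))
    window = tuple(raw.get("path_window", (9, 16)))
    return RunConfig(
        site=site,
        params=params,
        senescence_onset=raw.get("senescence_onset"),
        path_window=window,
        output_dir=raw.get("output_dir", "."),
    )


def read_timeseries(
    path,
    required: tuple = (),
    timestamp_column: str | None = None,
) -> pd.DataFrame:
    """Read, validate and sort a timestamped CSV table.

    The first column (or ``timestamp_column``) must parse as ISO 8601;
    unparseable or duplicated timestamps raise with the offending data
    row number (1-based, excluding the header).  Rows are sorted by
    timestamp; hourly gaps are recorded in ``df.attrs['gaps']``.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    ts_col = timestamp_column or df.columns[0]
    if ts_col not in df.columns:
        raise ValueError(f"{path}: unknown timestamp column '{ts_col}'")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")

    ts = pd.to_datetime(df[ts_col], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(ts.index[ts.isna()][0]) + 1
        raise ValueError(
            f"{path}: unparseable timestamp at data row {row}: {df[ts_col].iloc[row - 1]!r}"
        )
    if ts.duplicated().any():
        row = int(ts.index[ts.duplicated()][0]) + 1
        raise ValueError(f"{path}: duplicate timestamp at data row {row}: {ts.iloc[row - 1]}")

    df = df.drop(columns=[ts_col]).set_index(pd.DatetimeIndex(ts, name="timestamp"))
    df = df.sort_index()
    deltas = df.index.to_series().diff().dropna()
    modal = deltas.mode()
    gaps = []
    if len(modal):
        gaps = [str(t) for t in df.index[1:][(deltas > modal.iloc[0]).to_numpy()]]
    df.attrs["gaps"] = gaps
    return df


def write_timeseries(df: pd.DataFrame, path) -> None:
    """Write a timestamped table in the schema :func:`read_timeseries` reads."""
    out = df.copy()
    out.index.name = "timestamp"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S", float_format="%.9g")
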