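"""Plain-text schemas for recordings, event logs, feature and result tables.

One directory per takeover episode: a ``meta.json`` with the event identity
and TOR anchors, plus one CSV per channel (``<channel>.csv`` with columns
``time_s,value``; UTF-8, '.' decimal).  Missing samples are empty value
cells on disk and explicit masks in memory; readers never impute.  All
round-trips are lossless on valid data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .features import FEATURE_COLUMNS
from .recording import CHANNEL_NAMES, Channel, MultiChannelRecording
from .synthetic import SyntheticDataset

logger = logging.getLogger("tostab.io")

_FLOAT_FMT = "%.17g"  # full double precision: round-trips are lossless


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def write_recording(recording: MultiChannelRecording, path) -> None:
    """One CSV per channel plus ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "event_id": recording.event_id,
        "tor_time_s": recording.tor_time,
        "availability_end_s": recording.availability_end,
        "channels": sorted(recording.channels),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    for name, ch in recording.channels.items():
        values = np.where(ch.missing, np.nan, ch.values)
        df = pd.DataFrame({"time_s": ch.time, "value": values})
        df.to_csv(path / f"{name}.csv", index=False, float_format=_FLOAT_FMT,
                  na_rep="")


def read_recording(path, required: tuple[str, ...] = CHANNEL_NAMES) -> MultiChannelRecording:
    """Load a recording directory; empty channels are accepted (and logged),
    missing mandatory channels raise a schema error naming the channel."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"{path}: meta.json not found")
    meta = json.loads(meta_path.read_text())
    channels: dict[str, Channel] = {}
    for csv_path in sorted(path.glob("*.csv")):
        name = csv_path.stem
        df = pd.read_csv(csv_path, float_precision="round_trip")
        if "time_s" not in df.columns or "value" not in df.columns:
            raise SchemaError(f"{csv_path}: expected columns time_s,value")
        extra = [c for c in df.columns if c not in ("time_s", "value")]
        if extra:
            logger.warning("%s: ignoring extra columns %s", csv_path, extra)
        values = df["value"].to_numpy(dtype=float)
        missing = np.isnan(values)
        if len(df) == 0:
            logger.info("%s: channel file has zero rows", csv_path)
        try:
            channels[name] = Channel(df["time_s"].to_numpy(dtype=float),
                                     values, missing)
        except DataError as err:
            raise DataError(f"{csv_path}: {err}") from err
    for name in required:
        if name not in channels:
            raise SchemaError(f"{path}: mandatory channel '{name}' is missing")
    rec = MultiChannelRecording(
        event_id=str(meta["event_id"]),
        tor_time=float(meta["tor_time_s"]),
        availability_end=float(meta["availability_end_s"]),
        channels=channels,
    )
    return rec


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Dataset directory: ``events.csv``, ``ground_truth.csv`` and one
    recording directory per event."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.event_log().to_csv(path / "events.csv", index=False,
                               float_format=_FLOAT_FMT)
    if dataset.ground_truth is not None:
        gt = dataset.ground_truth
        rows = [
            {"variable": name,
             "stabilization_time_s": v.time,
             "stabilized_within_horizon": int(v.stabilized_within_horizon)}
            for name, v in gt.variables.items()
        ]
        pd.DataFrame(rows).to_csv(path / "ground_truth.csv", index=False,
                                  float_format=_FLOAT_FMT)
    for event, rec in zip(dataset.events, dataset.recordings):
        write_recording(rec, path / event.event_id)


# ---------------------------------------------------------------------------
# feature and result tables
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Long-form feature CSV with the stable column order
    (event_id, driver_id, variable, window_start_s, window_len_s, value,
    is_missing); missing values are empty cells with is_missing = 1."""
    out = table.reindex(columns=list(FEATURE_COLUMNS)).copy()
    out["is_missing"] = out["is_missing"].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"event_id": str, "driver_id": str, "variable": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    missing_cols = set(FEATURE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    df["is_missing"] = df["is_missing"].astype(float).astype(bool)
    for col in ("window_start_s", "window_len_s", "value"):
        df[col] = df[col].astype(float)
    df["driver_id"] = df["driver_id"].fillna("")
    return df[list(FEATURE_COLUMNS)]


def write_results_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
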