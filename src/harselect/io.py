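"""CSV interchange for sensor recordings, annotations and feature tables.

Sensor CSV columns (SI units, header mandatory):
``t, ax, ay, az, gx, gy, gz, lx, ly, lz, wx, wy, wz, label`` — raw
acceleration (a*), gravity (g*), linear acceleration (l*), gyroscope (w*).
Annotation CSV: ``label, start_s, end_s``.  Script CSV: ``label, duration``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SensorRecording

SENSOR_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz",
                  "lx", "ly", "lz", "wx", "wy", "wz", "label"]


def write_recording_csv(recording: SensorRecording, path) -> None:
    recording.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_recording_csv(path, participant_id: str | None = None) -> SensorRecording:
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sensor CSV lacks columns: {missing}")
    return SensorRecording(
        participant_id=participant_id or "unknown",
        t=df["t"].to_numpy(dtype=float),
        accel_raw=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gravity=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        accel_linear=df[["lx", "ly", "lz"]].to_numpy(dtype=float),
        gyro=df[["wx", "wy", "wz"]].to_numpy(dtype=float),
        label=df["label"].to_numpy(dtype=object),
    )


def write_annotations_csv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False, float_format="%.9g")


def read_annotations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("label", "start_s", "end_s") if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV lacks columns: {missing}")
    return df


def write_feature_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_feature_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
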