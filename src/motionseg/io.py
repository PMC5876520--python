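"""CSV dialects for IMU recordings, per-sample labels and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ImuStream
from .pipeline import SegmentationResult

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_segmentation_csv",
    "read_segmentation_csv",
    "write_manifest",
    "read_manifest",
]

IMU_COLUMNS = ["frame", "ax", "ay", "az", "gx", "gy", "gz"]


def read_imu_csv(path: str | Path) -> ImuStream:
    """Read one recording.  Columns: frame, ax, ay, az, gx, gy, gz.

    An optional leading comment line ``# rate_hz=... accel_units=...``
    declares metadata; defaults are 100 Hz and g.
    """
    path = Path(path)
    rate, units = 100.0, "g"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "rate_hz":
                        rate = float(v)
                    elif k == "accel_units":
                        units = v
            header_line = 1
        else:
            header_line = 0
    try:
        df = pd.read_csv(path, skiprows=header_line)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in IMU_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            lines = (df.index[bad] + header_line + 2).tolist()[:5]
            raise ValueError(f"{path}: non-numeric or missing {col!r} at line(s) {lines}")
    return ImuStream(
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        rate_hz=rate,
        accel_units=units,
    )


def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([np.arange(len(stream)), stream.accel, stream.gyro]),
        columns=IMU_COLUMNS,
    )
    df["frame"] = df["frame"].astype(int)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={stream.rate_hz:g} accel_units={stream.accel_units}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_labels_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("frame", "state_index"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("frame")
    if not (df["frame"].to_numpy() == np.arange(len(df))).all():
        raise ValueError(f"{path}: frames must be contiguous from 0")
    return df["state_index"].to_numpy(np.int64)


def write_labels_csv(labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"frame": np.arange(len(labels)), "state_index": labels}).to_csv(
        path, index=False
    )


def write_segmentation_csv(results: dict[str, SegmentationResult | None],
                           path: str | Path) -> None:
    rows = []
    for rid, res in sorted(results.items()):
        if res is None:
            continue
        for lab, b in zip(res.boundary_labels, res.boundary_indices):
            rows.append({"recording_id": rid, "boundary_label": lab,
                         "frame_index": int(b), "probability": res.score})
    pd.DataFrame(rows, columns=["recording_id", "boundary_label",
                                "frame_index", "probability"]).to_csv(path, index=False)


def read_segmentation_csv(path: str | Path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, int]] = {}
    for rid, grp in df.groupby("recording_id"):
        out[str(rid)] = dict(zip(grp["boundary_label"], grp["frame_index"].astype(int)))
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
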