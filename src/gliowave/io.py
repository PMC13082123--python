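"""CSV loaders/writers for traces, ROI tables and screen plates."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import TraceMatrix

logger = logging.getLogger("gliowave.io")

__all__ = ["load_traces_csv", "write_traces_csv", "load_roi_csv",
           "load_plate_csv"]

PLATE_COLUMNS = ["plate_id", "well_id", "condition", "readout", "value",
                 "is_negative_control"]


def load_traces_csv(path: str | Path, expected_frame_rate: float | None = None,
                    missing: str = "reject") -> TraceMatrix:
    """Load a trace CSV: first column ``time_s``, one column per cell.

    The frame rate is inferred from the ``time_s`` spacing; if
    ``expected_frame_rate`` is given and differs by more than 1%, loading
    fails.  Missing values are rejected by default, or linearly interpolated
    with ``missing="interpolate"``.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("trace CSV must start with a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace CSV needs at least 2 frames")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("time_s must be strictly increasing")
    frame_rate = 1.0 / float(np.median(dt))
    if np.abs(dt - np.median(dt)).max() > 0.01 * np.median(dt):
        raise ValueError("time_s spacing is not uniform (>1% deviation)")
    if (expected_frame_rate is not None
            and abs(frame_rate - expected_frame_rate) > 0.01 * expected_frame_rate):
        raise ValueError(
            f"frame rate inferred from time_s ({frame_rate:.3f} Hz) differs "
            f"from configured rate ({expected_frame_rate:.3f} Hz) by > 1%")
    values = df.drop(columns="time_s")
    if values.isna().any().any():
        if missing == "interpolate":
            values = values.interpolate(axis=0, limit_direction="both")
            logger.warning("missing trace values linearly interpolated")
        else:
            raise ValueError("trace CSV contains missing values")
    return TraceMatrix(values=values.to_numpy(dtype=float),
                       frame_rate=frame_rate,
                       cell_ids=[str(c) for c in values.columns])


def write_traces_csv(traces: TraceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(traces.values, columns=traces.cell_ids)
    df.insert(0, "time_s", traces.times_s)
    df.to_csv(path, index=False)


def load_roi_csv(path: str | Path) -> pd.DataFrame:
    """ROI centroid table: columns ``cell_id, x, y`` (μm)."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI CSV needs columns {sorted(required)}")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in ROI CSV")
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite ROI coordinates")
    return df


def load_plate_csv(path: str | Path) -> pd.DataFrame:
    """Screen plate table (one row per well × readout)."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns {sorted(missing)}")
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite plate values")
    return df
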