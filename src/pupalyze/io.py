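"""Readers and writers for event tables, traces, and movies.

Event tables are CSV with 0-based frames and half-open [onset, offset)
intervals.  External 1-based tables (closed onset..offset convention) are
converted on read with ``one_based=True``.  A ``column_map`` (dict or JSON
file path) renames foreign column headers onto the required schema, which
also covers externally deposited annotation tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .simulate import EVENT_COLUMNS

_FRAME_COLS = ("onset_frame", "offset_frame", "peak_frame")


def read_events(path, one_based: bool = False, column_map=None) -> pd.DataFrame:
    """Read and validate an event table.

    Checks the required columns and interval monotonicity, reporting
    offending row numbers.  With ``one_based`` the frames are shifted to
    0-based and the closed offset converted to half-open.
    """
    df = pd.read_csv(path, keep_default_na=False)
    if column_map is not None:
        if isinstance(column_map, (str, Path)):
            with open(column_map) as fh:
                column_map = json.load(fh)
        df = df.rename(columns=column_map)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if one_based:
        for c in _FRAME_COLS:
            df[c] = df[c] - 1
        df["offset_frame"] = df["offset_frame"] + 1  # closed -> half-open
    bad = df.index[df["offset_frame"] <= df["onset_frame"]].tolist()
    if bad:
        raise ValidationError(f"offset <= onset at rows {bad[:20]}")
    neg = df.index[df["onset_frame"] < 0].tolist()
    if neg:
        raise ValidationError(f"negative onset frames at rows {neg[:20]}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def write_trace_csv(values: np.ndarray, path) -> None:
    pd.DataFrame({"frame": np.arange(len(values)), "value": values}).to_csv(
        path, index=False
    )


def read_trace_csv(path) -> np.ndarray:
    return pd.read_csv(path)["value"].to_numpy(float)


def write_traces_h5(traces: dict[tuple[str, str, str], np.ndarray], path, fps: float = 2.0) -> None:
    """Bundle per-cell traces into one HDF5 file (dataset per cell)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["fps"] = fps
        for (label, segment, side), values in traces.items():
            fh.create_dataset(f"{label}/{segment}/{side}", data=values)


def read_traces_h5(path) -> tuple[dict[tuple[str, str, str], np.ndarray], float]:
    traces: dict[tuple[str, str, str], np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        fps = float(fh.attrs.get("fps", 2.0))
        for label in fh:
            for segment in fh[label]:
                for side in fh[label][segment]:
                    traces[(label, segment, side)] = fh[label][segment][side][()]
    return traces, fps


def write_movie(stack: np.ndarray, path, fps: float = 2.0,
                orientation: str = "row0_anterior") -> None:
    """Write an (N, H, W) stack as multi-page TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack))
    meta = {
        "fps": fps,
        "orientation": orientation,
        "frame_shape": list(stack.shape[1:]),
        "n_frames": int(stack.shape[0]),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_movie(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if meta.get("orientation", "row0_anterior") != "row0_anterior":
        raise ValidationError(
            "movie orientation must be row0_anterior (row 0 = anterior)"
        )
    return stack, meta
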