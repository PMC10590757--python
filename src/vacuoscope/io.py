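"""Plain-text and TIFF input/output.

All tabular data are CSV with a header row; times are in minutes,
lengths in pixels or micrometers as labeled per column. Image stacks are
multi-page TIFF, one file per channel. Ground truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from ._util import require
from .ph_dynamics import CalibrationSeries
from .size_control import SizeRecord
from .traces import TraceSeries

FLOAT_FMT = "%.10g"


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for i, t in enumerate(tr.times):
            row = {"cell_id": tr.cell_id, "time_min": float(t)}
            for name, vals in tr.channels.items():
                row[f"ch_{name}"] = float(vals[i])
            rows.append(row)
    return pd.DataFrame(rows)


def write_traces_csv(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_traces_csv(path, annotations_path=None) -> list:
    df = pd.read_csv(path)
    require({"cell_id", "time_min"} <= set(df.columns), f"{path}: missing required columns")
    ch_cols = [c for c in df.columns if c.startswith("ch_")]
    events_by_cell = {}
    if annotations_path is not None and Path(annotations_path).exists():
        ann = pd.read_csv(annotations_path)
        for cell_id, sub in ann.groupby("cell_id"):
            events_by_cell[cell_id] = {
                str(ev): sorted(float(t) for t in g["time_min"])
                for ev, g in sub.groupby("event")
            }
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_min")
        traces.append(
            TraceSeries(
                cell_id=str(cell_id),
                times=sub["time_min"].to_numpy(),
                channels={c[3:]: sub[c].to_numpy() for c in ch_cols},
                events=events_by_cell.get(cell_id, {}),
            )
        )
    return traces


def write_annotations_csv(traces, path) -> None:
    rows = [
        {"cell_id": tr.cell_id, "event": ev, "time_min": float(t)}
        for tr in traces
        for ev, times in sorted(tr.events.items())
        for t in times
    ]
    pd.DataFrame(rows, columns=["cell_id", "event", "time_min"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_calibration_csv(series: CalibrationSeries, path) -> None:
    pd.DataFrame({"ph": series.ph, "ratio": series.ratio}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_calibration_csv(path) -> CalibrationSeries:
    df = pd.read_csv(path)
    require({"ph", "ratio"} <= set(df.columns), f"{path}: need ph and ratio columns")
    return CalibrationSeries(ph=df["ph"].to_numpy(), ratio=df["ratio"].to_numpy())


def write_sizes_csv(records, path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "l_birth_um": r.l_birth,
            "s_birth_um": r.s_birth,
            "l_bud_um": r.l_bud,
            "s_bud_um": r.s_bud,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sizes_csv(path, use_pi: bool = False) -> list:
    df = pd.read_csv(path)
    cols = {"cell_id", "l_birth_um", "s_birth_um", "l_bud_um", "s_bud_um"}
    require(cols <= set(df.columns), f"{path}: missing size columns")
    return [
        SizeRecord(
            cell_id=str(r.cell_id),
            l_birth=float(r.l_birth_um),
            s_birth=float(r.s_birth_um),
            l_bud=float(r.l_bud_um),
            s_bud=float(r.s_bud_um),
            use_pi=use_pi,
        )
        for r in df.itertuples()
    ]


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_tracks_csv(tracks, path) -> None:
    rows = [
        {
            "track_id": tr.track_id,
            "frame": d.frame,
            "x": d.x,
            "y": d.y,
            "radius": d.radius,
            "quality": d.quality,
        }
        for tr in tracks
        for d in tr.detections
    ]
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "radius", "quality"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
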