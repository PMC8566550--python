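"""CSV / JSON interfaces for traces, tracks, counts, and results.

Trace tables are long-format CSV with columns ``trace_id, genotype,
t_s`` and at least one of ``F`` / ``dff`` (optional ``F_bg``,
``excitation``).  Track tables carry ``track_id, genotype, t_s, x_px,
y_px``; chemotaxis count tables carry ``trial_id, genotype, n_air,
n_co2``.  Stimulus schedules are JSON objects mapping window names to
``{"start": s, "end": s}``.

All outputs are comma-separated UTF-8 with a header row and numeric
values at six significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import AvoidanceCount, Track
from .traces import TimeSeriesTrace, WindowSpec

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "read_track_table",
    "read_counts_table",
    "read_schedule",
    "write_results",
]

_TRACE_REQUIRED = {"trace_id", "genotype", "t_s"}
_TRACK_REQUIRED = {"track_id", "genotype", "t_s", "x_px", "y_px"}
_COUNTS_REQUIRED = {"trial_id", "genotype", "n_air", "n_co2"}


def _require_columns(df: pd.DataFrame, required: set[str], path: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def read_trace_table(path: str | Path) -> list[TimeSeriesTrace]:
    """Read a long-format trace CSV into validated traces.

    Enforces the uniform-sampling and monotone-time invariants; errors
    name the offending trace.
    """
    path = str(path)
    df = pd.read_csv(path)
    _require_columns(df, _TRACE_REQUIRED, path)
    if "F" not in df.columns and "dff" not in df.columns:
        raise ValueError(f"{path}: need an 'F' or 'dff' column")
    traces = []
    for trace_id, g in df.groupby("trace_id", sort=False):
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise ValueError(f"{path}: trace {trace_id!r} has duplicated timestamps")
        kwargs = {}
        if "F" in g.columns and g["F"].notna().all():
            kwargs["F"] = g["F"].to_numpy(dtype=float)
        if "dff" in g.columns and g["dff"].notna().all():
            kwargs["dff"] = g["dff"].to_numpy(dtype=float)
        if not kwargs:
            raise ValueError(f"{path}: trace {trace_id!r} has neither complete F nor dff")
        if "F_bg" in g.columns and g["F_bg"].notna().all():
            kwargs["F_bg"] = g["F_bg"].to_numpy(dtype=float)
        excitation = None
        if "excitation" in g.columns and g["excitation"].notna().any():
            excitation = float(g["excitation"].iloc[0])
        try:
            traces.append(
                TimeSeriesTrace(
                    trace_id=str(trace_id), t=t,
                    genotype=str(g["genotype"].iloc[0]),
                    excitation_intensity=excitation, **kwargs,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return traces


def write_trace_table(traces: list[TimeSeriesTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i in range(tr.t.size):
            row = {"trace_id": tr.trace_id, "genotype": tr.genotype,
                   "t_s": tr.t[i]}
            if tr.F is not None:
                row["F"] = tr.F[i]
            if tr.dff is not None:
                row["dff"] = tr.dff[i]
            if tr.F_bg is not None:
                row["F_bg"] = tr.F_bg[i]
            if tr.excitation_intensity is not None:
                row["excitation"] = tr.excitation_intensity
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_track_table(path: str | Path) -> list[Track]:
    path = str(path)
    df = pd.read_csv(path)
    _require_columns(df, _TRACK_REQUIRED, path)
    tracks = []
    for track_id, g in df.groupby("track_id", sort=False):
        try:
            tracks.append(
                Track(
                    track_id=str(track_id),
                    t=g["t_s"].to_numpy(dtype=float),
                    x=g["x_px"].to_numpy(dtype=float),
                    y=g["y_px"].to_numpy(dtype=float),
                    genotype=str(g["genotype"].iloc[0]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return tracks


def write_track_table(tracks: list[Track], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"track_id": tr.track_id, "genotype": tr.genotype,
             "t_s": tr.t, "x_px": tr.x, "y_px": tr.y}
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Chemotaxis endpoint counts; validates the AvoidanceCount invariants."""
    path = str(path)
    df = pd.read_csv(path)
    _require_columns(df, _COUNTS_REQUIRED, path)
    for _, row in df.iterrows():
        AvoidanceCount(int(row["n_air"]), int(row["n_co2"]))  # validates
    return df


def read_schedule(path: str | Path) -> dict[str, WindowSpec]:
    """Stimulus schedule JSON -> named half-open windows in seconds."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        name: WindowSpec(float(spec["start"]), float(spec["end"]))
        for name, spec in raw.items()
    }


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each named DataFrame as ``<outdir>/<name>.csv``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths.append(p)
    return paths
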