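"""CSV and PNG file formats for detection logs, series and results.

All timestamps are ISO-8601 local clock times (the photoperiod is
clock-anchored, so no timezone arithmetic is done).  Readers validate
headers and reject malformed rows with their line numbers; an unsorted
detection log is sorted on read with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from PIL import Image

from .layout import AntennaLayout
from .motion import Trajectory
from .rfid import DetectionLog, DisplacementSeries
from .chronostats import BinnedSeries, PeriodogramResult, WaveformResult
from .video import Frame

__all__ = [
    "write_detection_log",
    "read_detection_log",
    "write_displacement_series",
    "read_displacement_series",
    "write_trajectories",
    "read_trajectories",
    "write_binned_series",
    "write_periodogram",
    "write_waveform",
    "write_frame_png",
    "read_frame_png",
    "SchemaError",
]

logger = logging.getLogger("burrowtrack")


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _parse_times(df: pd.DataFrame, what: str) -> pd.Series:
    times = pd.to_datetime(df["time_iso"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise SchemaError(f"{what}: unparseable timestamp at line(s) {lines}")
    return times


# -- detection log ----------------------------------------------------------


def write_detection_log(log: DetectionLog, path) -> None:
    df = log.events.copy()
    df["time_iso"] = pd.DatetimeIndex(df.pop("time")).strftime("%Y-%m-%dT%H:%M:%S")
    df[["time_iso", "uid", "antenna_id"]].to_csv(path, index=False)


def read_detection_log(path, layout: AntennaLayout, cadence: float = 5.0) -> DetectionLog:
    df = pd.read_csv(path, dtype={"uid": str})
    _require_columns(df, ["time_iso", "uid", "antenna_id"], "detection log")
    times = _parse_times(df, "detection log")
    active = {a.id for a in layout.active_antennas}
    unknown = sorted(set(df["antenna_id"].astype(int)) - active)
    if unknown:
        raise SchemaError(f"detection log: unknown antenna id(s) {unknown}")
    events = pd.DataFrame(
        {"time": times, "uid": df["uid"], "antenna_id": df["antenna_id"].astype(int)}
    )
    if not events["time"].is_monotonic_increasing:
        logger.warning("detection log %s unsorted; sorting by time", path)
        events = events.sort_values(["time", "uid"], kind="stable").reset_index(drop=True)
    return DetectionLog(layout=layout, events=events, cadence=cadence)


# -- displacement series ----------------------------------------------------


def write_displacement_series(series_list: list[DisplacementSeries], path) -> None:
    frames = [s.to_frame() for s in series_list]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time", "uid", "displacement_cm"]
    )
    df["time_iso"] = pd.DatetimeIndex(df.pop("time")).strftime("%Y-%m-%dT%H:%M:%S")
    df[["time_iso", "uid", "displacement_cm"]].to_csv(path, index=False)


def read_displacement_series(path) -> list[DisplacementSeries]:
    df = pd.read_csv(path, dtype={"uid": str})
    _require_columns(df, ["time_iso", "uid", "displacement_cm"], "displacement series")
    times = _parse_times(df, "displacement series")
    df = df.assign(time=times)
    out = []
    for uid, g in df.groupby("uid", sort=True):
        g = g.sort_values("time", kind="stable")
        out.append(
            DisplacementSeries(
                animal_uid=uid,
                times=pd.DatetimeIndex(g["time"]),
                values=g["displacement_cm"].to_numpy(dtype=float),
            )
        )
    return out


# -- trajectories -----------------------------------------------------------


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    df = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    df["time_iso"] = pd.DatetimeIndex(df.pop("time")).strftime("%Y-%m-%dT%H:%M:%S")
    df[["time_iso", "uid", "x_cm", "y_cm", "state"]].to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path, dtype={"uid": str})
    _require_columns(df, ["time_iso", "uid", "x_cm", "y_cm", "state"], "trajectory file")
    times = _parse_times(df, "trajectory file")
    df = df.assign(time=times)
    out = []
    for uid, g in df.groupby("uid", sort=True):
        g = g.sort_values("time", kind="stable")
        t = pd.DatetimeIndex(g["time"])
        step = (t[1] - t[0]).total_seconds() if len(t) > 1 else 1.0
        out.append(
            Trajectory(
                animal_uid=uid,
                start_time=t[0],
                step_seconds=step,
                positions=g[["x_cm", "y_cm"]].to_numpy(dtype=float),
                states=g["state"].to_numpy(dtype=object),
            )
        )
    return out


# -- analysis results -------------------------------------------------------


def write_binned_series(binned: BinnedSeries, path) -> None:
    pd.DataFrame(
        {
            "time_iso": binned.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "value_cm": binned.values,
        }
    ).to_csv(path, index=False)


def write_periodogram(result: PeriodogramResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_waveform(result: WaveformResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


# -- frames -----------------------------------------------------------------


def write_frame_png(frame: Frame, path) -> None:
    Image.fromarray(frame.pixels, mode="L").save(path)


def read_frame_png(path, time, phase: str) -> Frame:
    px = np.asarray(Image.open(path).convert("L"))
    return Frame(pixels=px, time=pd.Timestamp(time), phase=phase)
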