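"""RFID reader model: trajectories -> detection logs -> displacement/occupancy.

The reader grid samples every animal's position once per 5-s sweep and
records which antenna the transponder answered to.  Position is then the
known antenna center, so displacement between ticks is the Euclidean
distance between antenna centers — zero while the animal stays inside
one antenna's quadrant.  This spatial quantization is the defining
property of the method: it under-reports within-quadrant motion relative
to video tracking of the same animal.

All controllers are idealized as sweeping simultaneously each tick;
intra-sweep latency is far below the 10-min analysis bins.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import AntennaLayout, LayoutError, nearest_antenna
from .motion import SHELTERED, Trajectory

__all__ = [
    "DetectionLog",
    "DisplacementSeries",
    "sample_detections",
    "displacement_from_detections",
    "occupancy_percentages",
    "burrow_occupancy",
]

DEFAULT_CADENCE = 5.0  # seconds between reader sweeps


@dataclass
class DetectionLog:
    """Time-ordered detection events (time, uid, antenna_id) plus layout.

    ``events`` columns: ``time`` (Timestamp), ``uid`` (str),
    ``antenna_id`` (int).  Multiple animals may share one antenna at one
    tick (anti-collision); per animal there is at most one event per tick.
    """

    layout: AntennaLayout
    events: pd.DataFrame
    cadence: float = DEFAULT_CADENCE

    def __post_init__(self) -> None:
        required = {"time", "uid", "antenna_id"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing column(s): {sorted(missing)}")
        if len(self.events) and not self.events["time"].is_monotonic_increasing:
            self.events = self.events.sort_values(
                ["time", "uid"], kind="stable"
            ).reset_index(drop=True)
        active = {a.id for a in self.layout.active_antennas}
        unknown = set(self.events["antenna_id"].unique()) - active
        if unknown:
            raise ValueError(f"unknown or inactive antenna id(s) in log: {sorted(unknown)}")

    @property
    def animal_uids(self) -> list[str]:
        return sorted(self.events["uid"].unique())


@dataclass(frozen=True)
class DisplacementSeries:
    """Per-interval movement magnitudes (cm) for one animal.

    ``times[i]`` stamps the *end* of interval ``i``; ``values[i]`` is the
    distance covered since the previous sample.
    """

    animal_uid: str
    times: pd.DatetimeIndex
    values: np.ndarray
    gap_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("displacement values must be >= 0")

    def total(self) -> float:
        return float(np.sum(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "uid": self.animal_uid, "displacement_cm": self.values}
        )


def sample_detections(
    trajectories: list[Trajectory],
    layout: AntennaLayout,
    cadence: float = DEFAULT_CADENCE,
    *,
    range_limited: bool = False,
) -> DetectionLog:
    """Sample trajectories at the reader cadence into a detection log.

    At each tick every animal's true position is quantized to its nearest
    active antenna.  In ``range_limited`` mode, ticks where the animal sits
    in a dead zone (farther than the field radius from every center) emit
    no event.
    """
    rows = []
    for traj in trajectories:
        stride = cadence / traj.step_seconds
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError(
                f"cadence {cadence}s is not a multiple of trajectory step "
                f"{traj.step_seconds}s"
            )
        stride = int(round(stride))
        idx = np.arange(0, len(traj.positions), stride)
        times = traj.times[idx]
        for t, p in zip(times, traj.positions[idx]):
            aid = nearest_antenna(layout, tuple(p), range_limited=range_limited)
            if aid is not None:
                rows.append((t, traj.animal_uid, aid))
    events = pd.DataFrame(rows, columns=["time", "uid", "antenna_id"])
    if len(events):
        events = events.sort_values(["time", "uid"], kind="stable").reset_index(drop=True)
    return DetectionLog(layout=layout, events=events, cadence=cadence)


def displacement_from_detections(log: DetectionLog) -> list[DisplacementSeries]:
    """Per-animal displacement between consecutive detections.

    Distance is between antenna centers (0 when the antenna is unchanged).
    Missing ticks (gaps) contribute a single bridging distance between the
    flanking antennas, flagged in ``gap_flags``.
    """
    centers = {a.id: np.asarray(a.center_xy) for a in log.layout.antennas}
    out = []
    tick = pd.to_timedelta(log.cadence, unit="s")
    for uid, g in log.events.groupby("uid", sort=True):
        g = g.sort_values("time", kind="stable")
        ids = g["antenna_id"].to_numpy()
        times = pd.DatetimeIndex(g["time"])
        if len(g) < 2:
            out.append(
                DisplacementSeries(
                    uid, times[1:], np.empty(0), gap_flags=np.empty(0, dtype=bool)
                )
            )
            continue
        xy = np.stack([centers[i] for i in ids])
        d = np.hypot(*(xy[1:] - xy[:-1]).T)
        gaps = (times[1:] - times[:-1]) > tick * 1.5
        out.append(DisplacementSeries(uid, times[1:], d, gap_flags=np.asarray(gaps)))
    return out


def occupancy_percentages(log: DetectionLog) -> dict[str, dict[int, float]]:
    """Percent of each animal's detections on each antenna (sums to 100)."""
    result: dict[str, dict[int, float]] = {}
    for uid, g in log.events.groupby("uid", sort=True):
        counts = g["antenna_id"].value_counts()
        total = counts.sum()
        result[uid] = {int(a): 100.0 * c / total for a, c in counts.items()}
    return result


def burrow_occupancy(
    log: DetectionLog,
    layout: AntennaLayout | None = None,
    *,
    min_ticks: int = 2,
) -> dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Burrow-occupancy intervals per animal, from interior-antenna runs.

    Maximal runs of consecutive ticks on ``burrow_interior`` antennas
    become (enter, exit) intervals; runs shorter than ``min_ticks`` are
    discarded as pass-throughs.  The exit time is the end of the last
    tick, so a run of n ticks spans ``n * cadence`` seconds.  This is
    the information video tracking cannot provide (the tag is invisible
    inside the burrow).
    """
    layout = layout or log.layout
    interior = {a.id for a in layout.antennas_with_role("burrow_interior")}
    if not interior:
        raise LayoutError("layout declares no burrow_interior antennas")
    tick = pd.to_timedelta(log.cadence, unit="s")
    result: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for uid, g in log.events.groupby("uid", sort=True):
        g = g.sort_values("time", kind="stable")
        times = pd.DatetimeIndex(g["time"])
        inside = g["antenna_id"].isin(interior).to_numpy()
        intervals = []
        run_start = None
        prev_t = None
        for t, inb in zip(times, inside):
            contiguous = prev_t is not None and (t - prev_t) <= tick * 1.5
            if inb:
                if run_start is None:
                    run_start = t
                elif not contiguous:  # gap splits the run
                    intervals.append((run_start, prev_t))
                    run_start = t
            elif run_start is not None:
                intervals.append((run_start, prev_t))
                run_start = None
            prev_t = t
        if run_start is not None:
            intervals.append((run_start, prev_t))
        result[uid] = [
            (s, e + tick)
            for s, e in intervals
            if (e - s) / tick + 1 >= min_ticks
        ]
    return result


def ground_truth_displacement(
    traj: Trajectory, cadence: float = DEFAULT_CADENCE
) -> DisplacementSeries:
    """Displacement series from true positions sampled at the reader cadence.

    The upper reference for the RFID-vs-video comparison: what a perfect
    tracker reading exact coordinates every tick would measure.
    """
    stride = int(round(cadence / traj.step_seconds))
    idx = np.arange(0, len(traj.positions), stride)
    xy = traj.positions[idx]
    d = np.hypot(*(xy[1:] - xy[:-1]).T)
    return DisplacementSeries(traj.animal_uid, traj.times[idx][1:], d)


def sheltered_intervals(
    traj: Trajectory,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Ground-truth sheltered intervals from a trajectory's state labels."""
    times = traj.times
    sheltered = traj.states == SHELTERED
    intervals = []
    start = None
    for i, s in enumerate(sheltered):
        if s and start is None:
            start = times[i]
        elif not s and start is not None:
            intervals.append((start, times[i - 1]))
            start = None
    if start is not None:
        intervals.append((start, times[-1]))
    return intervals
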