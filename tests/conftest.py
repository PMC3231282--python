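import numpy as np
import pandas as pd
import pytest

from burrowtrack.layout import build_default_layout
from burrowtrack.motion import (
    EMERGED,
    SHELTERED,
    BehaviourParams,
    PhotoperiodSchedule,
    Trajectory,
)
from burrowtrack.rfid import DisplacementSeries

T0 = pd.Timestamp("2024-01-01 00:00:00")


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def schedule():
    return PhotoperiodSchedule()


@pytest.fixture
def nocturnal_params():
    return BehaviourParams(animal_uid="a1")


def make_trajectory(positions, states=None, uid="a1", step_seconds=1.0, start=T0):
    """Hand-built trajectory from explicit positions (and optional states)."""
    positions = np.asarray(positions, dtype=float)
    if states is None:
        states = np.full(len(positions), EMERGED, dtype=object)
    return Trajectory(
        animal_uid=uid,
        start_time=start,
        step_seconds=step_seconds,
        positions=positions,
        states=np.asarray(states, dtype=object),
    )


def make_displacement(values, uid="a1", step_seconds=5.0, start=T0):
    """Displacement series with values stamped at interval ends."""
    values = np.asarray(values, dtype=float)
    times = start + pd.to_timedelta((np.arange(len(values)) + 1) * step_seconds, unit="s")
    return DisplacementSeries(animal_uid=uid, times=times, values=values)


def rectified_sinusoid_bins(period_hours=24.0, days=7, bin_minutes=10.0):
    """Deterministic rectified-sinusoid activity, already binned."""
    n = int(days * 24 * 60 / bin_minutes)
    tmin = np.arange(n) * bin_minutes
    return np.maximum(0.0, np.sin(2 * np.pi * tmin / (period_hours * 60.0)))


__all__ = [
    "make_trajectory",
    "make_displacement",
    "rectified_sinusoid_bins",
    "T0",
    "SHELTERED",
    "EMERGED",
]
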