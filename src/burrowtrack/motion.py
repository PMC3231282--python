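"""Synthetic ground-truth trajectories for tagged animals in the tank.

Each animal alternates between a *sheltered* state (resting at its home
burrow's interior point) and an *emerged* state (walking on the tank
floor), following a two-state continuous-time Markov chain whose
emergence rate depends on the photoperiod phase.  Emerged motion is a
correlated random walk — wrapped-normal turning angles, truncated-normal
step speeds — reflected at the tank walls.  A nocturnal preset (dark
emergence rate much larger than the light rate) reproduces the
burrow-emergence pattern of dark-active burrowing decapods such as the
Norway lobster: broad activity through the dark phase with the major
peak near lights-off.

The simulation step (default 1 s) is deliberately finer than the 5-s
RFID reader cadence so that reader quantization is a genuine downstream
effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .layout import TankGeometry

__all__ = [
    "PhotoperiodSchedule",
    "BehaviourParams",
    "Trajectory",
    "simulate_trajectory",
    "simulate_group",
    "nocturnal_preset",
    "SHELTERED",
    "EMERGED",
]

SHELTERED = "sheltered"
EMERGED = "emerged"


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """12L:12D laboratory photoperiod, clock-anchored.

    ``light_fraction`` ramps linearly over ``ramp_minutes`` around each
    transition (simulated dawn/dusk); set ``ramp_minutes=0`` for a square
    wave.
    """

    lights_on: str = "07:00"
    lights_off: str = "19:00"
    ramp_minutes: float = 30.0

    def _minutes(self, hhmm: str) -> float:
        h, m = hhmm.split(":")
        return 60.0 * int(h) + int(m)

    def light_fraction(self, seconds_of_day: float | np.ndarray) -> np.ndarray:
        """Illumination level in [0, 1] at a clock time (seconds past midnight)."""
        t = np.asarray(seconds_of_day, dtype=float) / 60.0  # minutes of day
        on, off = self._minutes(self.lights_on), self._minutes(self.lights_off)
        r = self.ramp_minutes
        if r <= 0:
            return ((t >= on) & (t < off)).astype(float)
        # ramp centred on each transition
        up = np.clip((t - (on - r / 2)) / r, 0.0, 1.0)
        down = np.clip(((off + r / 2) - t) / r, 0.0, 1.0)
        return np.minimum(up, down)

    def is_light(self, seconds_of_day: float) -> bool:
        return bool(self.light_fraction(seconds_of_day) >= 0.5)


@dataclass(frozen=True)
class BehaviourParams:
    """Per-animal behavioural parameters.

    Rates are per hour; speeds in cm/s.  These are illustrative synthetic
    presets — the statistical structure (nocturnality, inter-individual
    variability) is what matters, not the particular values.
    """

    animal_uid: str
    home_burrow: int = 0
    emergence_rate_light: float = 0.05
    emergence_rate_dark: float = 2.0
    retreat_rate: float = 1.0
    speed_mean: float = 2.0
    speed_sd: float = 0.8
    turning_concentration: float = 4.0
    activity_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.emergence_rate_light, self.emergence_rate_dark, self.retreat_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.activity_scale <= 0:
            raise ValueError("activity_scale must be > 0")
        if self.turning_concentration < 0:
            raise ValueError("turning_concentration must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Ground-truth positions and shelter states at a fixed step."""

    animal_uid: str
    start_time: pd.Timestamp
    step_seconds: float
    positions: np.ndarray  # (n, 2) cm
    states: np.ndarray  # (n,) of {sheltered, emerged}

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.states):
            raise ValueError("positions and states must have equal length")

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self.positions)) * self.step_seconds, unit="s"
        )

    def path_length(self) -> float:
        """Total travelled distance (cm) at the simulation step."""
        d = np.diff(self.positions, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "uid": self.animal_uid,
                "x_cm": self.positions[:, 0],
                "y_cm": self.positions[:, 1],
                "state": self.states,
            }
        )


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return v + lo


def simulate_trajectory(
    params: BehaviourParams,
    tank: TankGeometry,
    schedule: PhotoperiodSchedule,
    duration: float,
    seed: int,
    *,
    step_seconds: float = 1.0,
    start_time: str | pd.Timestamp = "2024-01-01 00:00:00",
) -> Trajectory:
    """Simulate one animal for ``duration`` seconds.

    Shelter switching is a two-state Markov chain discretized at
    ``step_seconds``: sheltered -> emerged at the phase-dependent
    emergence rate (linear interpolation between the light and dark
    rates by the photoperiod's light fraction), emerged -> sheltered at
    the retreat rate.  Identical ``(params, seed)`` give identical
    trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not tank.burrows:
        raise ValueError("tank has no burrows to shelter in")
    burrow = tank.burrows[params.home_burrow]
    rng = np.random.default_rng(seed)
    n = int(round(duration / step_seconds)) + 1
    start_time = pd.Timestamp(start_time)

    sec_of_day = (
        start_time.hour * 3600 + start_time.minute * 60 + start_time.second
        + np.arange(n) * step_seconds
    ) % 86400.0
    light = schedule.light_fraction(sec_of_day)
    dt_h = step_seconds / 3600.0
    # per-step switching probabilities
    p_retreat = 1.0 - math.exp(-params.retreat_rate * dt_h)

    positions = np.empty((n, 2))
    states = np.empty(n, dtype=object)
    interior = np.asarray(burrow.interior_xy, dtype=float)
    entrance = np.asarray(burrow.entrance_xy, dtype=float)

    pos = interior.copy()
    state = SHELTERED
    heading = rng.uniform(0, 2 * math.pi)
    turn_sd = (
        math.inf
        if params.turning_concentration == 0
        else 1.0 / math.sqrt(params.turning_concentration)
    )
    u = rng.random(n)  # switching draws, one per step
    turns = (
        rng.uniform(-math.pi, math.pi, n)
        if math.isinf(turn_sd)
        else rng.normal(0.0, turn_sd, n)
    )
    speeds = np.clip(rng.normal(params.speed_mean, params.speed_sd, n), 0.0, None)

    for i in range(n):
        positions[i] = pos
        states[i] = state
        if i == n - 1:
            break
        if state == SHELTERED:
            rate = (
                params.emergence_rate_light * light[i]
                + params.emergence_rate_dark * (1.0 - light[i])
            )
            if u[i] < 1.0 - math.exp(-rate * dt_h):
                state = EMERGED
                pos = entrance.copy()
                heading = rng.uniform(0, 2 * math.pi)
            # else stay put at the interior resting point
        else:
            if u[i] < p_retreat:
                state = SHELTERED
                pos = interior.copy()
            else:
                heading = (heading + turns[i]) % (2 * math.pi)
                step_len = speeds[i] * step_seconds * params.activity_scale
                x = pos[0] + step_len * math.cos(heading)
                y = pos[1] + step_len * math.sin(heading)
                pos = np.array(
                    [_reflect(x, 0.0, tank.length), _reflect(y, 0.0, tank.width)]
                )
    return Trajectory(
        animal_uid=params.animal_uid,
        start_time=start_time,
        step_seconds=step_seconds,
        positions=positions,
        states=states,
    )


def simulate_group(
    params_list: list[BehaviourParams],
    tank: TankGeometry,
    schedule: PhotoperiodSchedule,
    duration: float,
    seed: int,
    *,
    step_seconds: float = 1.0,
    start_time: str | pd.Timestamp = "2024-01-01 00:00:00",
    suppression: float = 1.0,
    subordinate_index: int | None = None,
    exclusive_occupancy: bool = False,
) -> list[Trajectory]:
    """Simulate a group of animals (independent; no collision model).

    With ``suppression < 1`` applied to ``subordinate_index``, that
    animal's emergence rates are multiplied by the suppression factor —
    a minimal stand-in for the dominance interactions that depress a
    subordinate's activity when several animals share the tank.

    Per-animal random streams are spawned deterministically from the
    master ``seed`` by animal index, so a group run reproduces the
    corresponding single-animal runs exactly.
    """
    if not params_list:
        raise ValueError("params_list must be non-empty")
    if not 0 < suppression <= 1.0:
        raise ValueError("suppression must be in (0, 1]")
    if exclusive_occupancy:
        homes = [p.home_burrow for p in params_list]
        if len(params_list) > len(tank.burrows) or len(set(homes)) != len(homes):
            raise ValueError(
                f"exclusive occupancy impossible: {len(params_list)} animals, "
                f"{len(tank.burrows)} burrows"
            )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(params_list)) % (2**31)
    out = []
    for i, p in enumerate(params_list):
        if subordinate_index is not None and i == subordinate_index:
            p = replace(
                p,
                emergence_rate_light=p.emergence_rate_light * suppression,
                emergence_rate_dark=p.emergence_rate_dark * suppression,
            )
        out.append(
            simulate_trajectory(
                p,
                tank,
                schedule,
                duration,
                int(child_seeds[i]),
                step_seconds=step_seconds,
                start_time=start_time,
            )
        )
    return out


def nocturnal_preset(
    uid: str,
    home_burrow: int = 0,
    *,
    activity_scale: float = 1.0,
) -> BehaviourParams:
    """Default nocturnal parameter set (dark emergence rate >> light rate)."""
    return BehaviourParams(animal_uid=uid, home_burrow=home_burrow, activity_scale=activity_scale)
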