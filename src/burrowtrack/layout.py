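"""Microcosm tank geometry and the RFID antenna network.

The laboratory tank is a 150 cm x 70 cm x 30 cm box with artificial burrows
dug into the substratum.  Below the tank floor sits a grid of 13.56 MHz RFID
antennas arranged in 7 columns x 6 rows (42 positions, numbered row-major
1..42), wired to six controllers of up to seven antennas each; five grid
positions are left unconnected so that 37 antennas are readable.  Each
antenna localizes any transponder inside its powering field; with the
chosen 3.0 cm tag the field covers a 6.0 cm tracking diameter.

Coordinates are continuous centimetres: origin at a tank corner, x along
the 150 cm side, y along the 70 cm side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "TankGeometry",
    "Burrow",
    "Antenna",
    "AntennaLayout",
    "build_default_layout",
    "nearest_antenna",
    "load_layout",
    "save_layout",
    "LayoutError",
]

GRID_COLS = 7
GRID_ROWS = 6
MAX_ANTENNAS_PER_CONTROLLER = 7


class LayoutError(ValueError):
    """Raised when a layout violates a structural invariant."""


@dataclass(frozen=True)
class Burrow:
    """An artificial burrow: an inclined tunnel descending from an entrance.

    ``interior_xy`` is the horizontal projection of the tunnel end, where a
    sheltered animal rests.  Defaults follow the physical microcosm: 25 cm
    tunnel at ~20 degrees inclination, 10 cm entrance and 7 cm tunnel
    diameter.
    """

    entrance_xy: tuple[float, float]
    interior_xy: tuple[float, float] | None = None
    tunnel_length: float = 25.0
    tunnel_inclination: float = 20.0
    entrance_diameter: float = 10.0
    tunnel_diameter: float = 7.0
    azimuth_deg: float = 0.0  # horizontal direction of the tunnel, from +x

    def __post_init__(self) -> None:
        if self.tunnel_length <= 0:
            raise LayoutError("tunnel_length must be > 0")
        if not 0 <= self.tunnel_inclination < 90:
            raise LayoutError("tunnel_inclination must be in [0, 90)")
        if self.interior_xy is None:
            # horizontal reach of the tunnel = L * cos(inclination)
            reach = self.tunnel_length * math.cos(math.radians(self.tunnel_inclination))
            a = math.radians(self.azimuth_deg)
            xy = (
                self.entrance_xy[0] + reach * math.cos(a),
                self.entrance_xy[1] + reach * math.sin(a),
            )
            object.__setattr__(self, "interior_xy", xy)


@dataclass(frozen=True)
class TankGeometry:
    length: float = 150.0  # cm, x extent
    width: float = 70.0  # cm, y extent
    depth: float = 30.0  # cm
    burrows: tuple[Burrow, ...] = ()

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.depth) <= 0:
            raise LayoutError("tank dimensions must be positive")
        for i, b in enumerate(self.burrows):
            if not self.contains(b.entrance_xy):
                raise LayoutError(f"burrow {i} entrance {b.entrance_xy} outside tank footprint")

    def contains(self, point: tuple[float, float]) -> bool:
        x, y = point
        return 0 <= x <= self.length and 0 <= y <= self.width


@dataclass(frozen=True)
class Antenna:
    """One grid antenna.  ``field_radius`` is half the 6.0 cm tracking diameter."""

    id: int
    center_xy: tuple[float, float]
    controller: int
    role: str = "grid"  # grid | burrow_entrance | burrow_interior
    active: bool = True
    field_radius: float = 3.0

    def __post_init__(self) -> None:
        if not 1 <= self.controller <= 6:
            raise LayoutError(f"antenna {self.id}: controller must be 1..6")
        if self.role not in ("grid", "burrow_entrance", "burrow_interior"):
            raise LayoutError(f"antenna {self.id}: unknown role {self.role!r}")
        if self.field_radius <= 0:
            raise LayoutError(f"antenna {self.id}: field_radius must be > 0")


@dataclass(frozen=True)
class AntennaLayout:
    tank: TankGeometry
    antennas: tuple[Antenna, ...]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.antennas]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LayoutError(f"duplicate antenna id(s): {dup}")
        for a in self.antennas:
            if not self.tank.contains(a.center_xy):
                raise LayoutError(f"antenna {a.id} center {a.center_xy} outside tank")
        for c, n in self.controller_counts.items():
            if n > MAX_ANTENNAS_PER_CONTROLLER:
                raise LayoutError(
                    f"controller C{c} has {n} active antennas "
                    f"(max {MAX_ANTENNAS_PER_CONTROLLER})"
                )

    @property
    def controller_counts(self) -> dict[int, int]:
        """Active antennas per controller."""
        counts: dict[int, int] = {}
        for a in self.antennas:
            if a.active:
                counts[a.controller] = counts.get(a.controller, 0) + 1
        return counts

    @property
    def active_antennas(self) -> tuple[Antenna, ...]:
        return tuple(a for a in self.antennas if a.active)

    def antenna(self, antenna_id: int) -> Antenna:
        for a in self.antennas:
            if a.id == antenna_id:
                return a
        raise KeyError(f"no antenna with id {antenna_id}")

    def antennas_with_role(self, role: str) -> tuple[Antenna, ...]:
        return tuple(a for a in self.antennas if a.active and a.role == role)


def _grid_centers(tank: TankGeometry) -> list[tuple[float, float]]:
    """Cell midpoints of the uniform 7x6 partition, row-major order."""
    dx = tank.length / GRID_COLS
    dy = tank.width / GRID_ROWS
    centers = []
    for row in range(GRID_ROWS):
        for col in range(GRID_COLS):
            centers.append(((col + 0.5) * dx, (row + 0.5) * dy))
    return centers


# Grid positions left unconnected in the default wiring: the highest-numbered
# 2 positions of controller C2 (row 2) and 3 of C3 (row 3), giving the
# documented active counts (7, 5, 4, 7, 7, 7).
DEFAULT_INACTIVE_IDS = frozenset({13, 14, 19, 20, 21})

# Default burrow placement: four burrows whose entrance and interior points
# fall on distinct, active antennas (tunnels run parallel to the x axis).
_DEFAULT_BURROW_SPECS = [
    # (entrance col, entrance row, azimuth toward interior)
    (1, 1, 180.0),
    (1, 4, 180.0),
    (5, 0, 0.0),
    (5, 5, 0.0),
]


def build_default_layout(
    *,
    all_active: bool = False,
    field_radius: float = 3.0,
) -> "AntennaLayout":
    """Build the default 7x6 antenna grid over the 150x70 cm tank.

    37 of the 42 grid positions are active (controllers C1..C6 drive
    7, 5, 4, 7, 7, 7 antennas); pass ``all_active=True`` to enable all 42.
    Four burrows annotate their nearest antennas with entrance/interior
    roles.  Position-to-antenna assignment mode (full-coverage Voronoi
    vs range-limited) is chosen per call in :func:`nearest_antenna`.
    """
    dx = 150.0 / GRID_COLS
    dy = 70.0 / GRID_ROWS
    burrows = tuple(
        Burrow(entrance_xy=((c + 0.5) * dx, (r + 0.5) * dy), azimuth_deg=az)
        for c, r, az in _DEFAULT_BURROW_SPECS
    )
    tank = TankGeometry(burrows=burrows)
    centers = _grid_centers(tank)

    roles = {i: "grid" for i in range(1, GRID_COLS * GRID_ROWS + 1)}
    for b in burrows:
        roles[_nearest_center_id(centers, b.entrance_xy)] = "burrow_entrance"
    for b in burrows:
        roles[_nearest_center_id(centers, b.interior_xy)] = "burrow_interior"

    antennas = []
    for i, c in enumerate(centers, start=1):
        controller = (i - 1) // GRID_COLS + 1  # one controller per row
        active = all_active or i not in DEFAULT_INACTIVE_IDS
        antennas.append(
            Antenna(
                id=i,
                center_xy=c,
                controller=controller,
                role=roles[i],
                active=active,
                field_radius=field_radius,
            )
        )
    return AntennaLayout(tank=tank, antennas=tuple(antennas))


def _nearest_center_id(centers: list[tuple[float, float]], point) -> int:
    d = [math.dist(c, point) for c in centers]
    return int(np.argmin(d)) + 1


def nearest_antenna(
    layout: AntennaLayout,
    point: tuple[float, float],
    *,
    range_limited: bool = False,
) -> int | None:
    """Antenna id whose center is closest to ``point`` (ties: lowest id).

    In ``range_limited`` mode, returns ``None`` (no detection) when the
    nearest center is farther than its field radius — the physical dead
    zone between antenna fields.  Points outside the tank are a domain
    error.
    """
    if not layout.tank.contains(point):
        raise LayoutError(f"point {point} outside tank footprint")
    best_id, best_d = None, math.inf
    for a in layout.active_antennas:
        d = math.dist(a.center_xy, point)
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and a.id < best_id):
            best_id, best_d = a.id, d
    if best_id is None:
        raise LayoutError("layout has no active antennas")
    if range_limited and best_d > layout.antenna(best_id).field_radius:
        return None
    return best_id


# ---------------------------------------------------------------------------
# YAML serialization


def save_layout(layout: AntennaLayout, path) -> None:
    tank = layout.tank
    doc = {
        "tank": {
            "length_cm": tank.length,
            "width_cm": tank.width,
            "depth_cm": tank.depth,
            "burrows": [
                {
                    "entrance_x_cm": b.entrance_xy[0],
                    "entrance_y_cm": b.entrance_xy[1],
                    "interior_x_cm": b.interior_xy[0],
                    "interior_y_cm": b.interior_xy[1],
                    "tunnel_length_cm": b.tunnel_length,
                    "tunnel_inclination_deg": b.tunnel_inclination,
                    "entrance_diameter_cm": b.entrance_diameter,
                    "tunnel_diameter_cm": b.tunnel_diameter,
                }
                for b in tank.burrows
            ],
        },
        "antennas": [
            {
                "id": a.id,
                "x_cm": a.center_xy[0],
                "y_cm": a.center_xy[1],
                "controller": a.controller,
                "role": a.role,
                "active": a.active,
                "field_radius_cm": a.field_radius,
            }
            for a in layout.antennas
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_layout(path) -> AntennaLayout:
    """Load a layout config; validation errors name the offending field."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "antennas" not in doc:
        raise LayoutError("layout config must contain an 'antennas' list")
    t = doc.get("tank", {}) or {}
    burrows = tuple(
        Burrow(
            entrance_xy=(float(b["entrance_x_cm"]), float(b["entrance_y_cm"])),
            interior_xy=(
                (float(b["interior_x_cm"]), float(b["interior_y_cm"]))
                if "interior_x_cm" in b
                else None
            ),
            tunnel_length=float(b.get("tunnel_length_cm", 25.0)),
            tunnel_inclination=float(b.get("tunnel_inclination_deg", 20.0)),
            entrance_diameter=float(b.get("entrance_diameter_cm", 10.0)),
            tunnel_diameter=float(b.get("tunnel_diameter_cm", 7.0)),
        )
        for b in t.get("burrows", []) or []
    )
    tank = TankGeometry(
        length=float(t.get("length_cm", 150.0)),
        width=float(t.get("width_cm", 70.0)),
        depth=float(t.get("depth_cm", 30.0)),
        burrows=burrows,
    )
    defaults = doc.get("defaults", {}) or {}
    antennas = []
    for rec in doc["antennas"]:
        try:
            antennas.append(
                Antenna(
                    id=int(rec["id"]),
                    center_xy=(float(rec["x_cm"]), float(rec["y_cm"])),
                    controller=int(rec["controller"]),
                    role=str(rec.get("role", "grid")),
                    active=bool(rec.get("active", True)),
                    field_radius=float(
                        rec.get("field_radius_cm", defaults.get("field_radius_cm", 3.0))
                    ),
                )
            )
        except KeyError as e:  # pragma: no cover - error message plumbing
            raise LayoutError(f"antenna record missing field {e}") from None
    return AntennaLayout(tank=tank, antennas=tuple(antennas))


def with_all_active(layout: AntennaLayout) -> AntennaLayout:
    """Copy of ``layout`` with every antenna enabled."""
    return AntennaLayout(
        tank=layout.tank,
        antennas=tuple(replace(a, active=True) for a in layout.antennas),
    )
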