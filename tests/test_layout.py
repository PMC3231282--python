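"""Tank geometry, antenna grid construction and position-to-antenna mapping."""

import math

import numpy as np
import pytest

from burrowtrack.layout import (
    Antenna,
    AntennaLayout,
    Burrow,
    LayoutError,
    TankGeometry,
    build_default_layout,
    load_layout,
    nearest_antenna,
    save_layout,
    with_all_active,
)


class TestDefaultLayout:
    def test_active_antenna_count(self, layout):
        assert len(layout.active_antennas) == 37

    def test_per_controller_counts(self, layout):
        assert layout.controller_counts == {1: 7, 2: 5, 3: 4, 4: 7, 5: 7, 6: 7}

    def test_all_positions_enabled_gives_42(self):
        full = build_default_layout(all_active=True)
        assert len(full.active_antennas) == 42
        assert [a.id for a in full.antennas] == list(range(1, 43))

    def test_inactive_positions_retained(self, layout):
        assert len(layout.antennas) == 42
        inactive = {a.id for a in layout.antennas if not a.active}
        assert inactive == {13, 14, 19, 20, 21}

    def test_grid_spacing_is_cell_midpoints(self, layout):
        a1 = layout.antenna(1)
        a2 = layout.antenna(2)
        a8 = layout.antenna(8)
        assert a1.center_xy == pytest.approx((150 / 14, 70 / 12))
        assert a2.center_xy[0] - a1.center_xy[0] == pytest.approx(150 / 7)
        assert a8.center_xy[1] - a1.center_xy[1] == pytest.approx(70 / 6)

    def test_burrow_roles_annotated(self, layout):
        entrances = {a.id for a in layout.antennas_with_role("burrow_entrance")}
        interiors = {a.id for a in layout.antennas_with_role("burrow_interior")}
        assert len(entrances) == len(layout.tank.burrows) == 4
        assert len(interiors) == 4
        assert not entrances & interiors

    def test_burrow_interior_from_inclined_tunnel(self):
        b = Burrow(entrance_xy=(50.0, 30.0), azimuth_deg=0.0)
        reach = 25.0 * math.cos(math.radians(20.0))
        assert b.interior_xy == pytest.approx((50.0 + reach, 30.0))


class TestInvariants:
    def test_tank_dimensions_positive(self):
        with pytest.raises(LayoutError):
            TankGeometry(length=-1)

    def test_burrow_entrance_inside_tank(self):
        with pytest.raises(LayoutError, match="outside"):
            TankGeometry(burrows=(Burrow(entrance_xy=(200.0, 10.0)),))

    def test_duplicate_ids_rejected(self, layout):
        a = layout.antennas[0]
        with pytest.raises(LayoutError, match="duplicate"):
            AntennaLayout(tank=layout.tank, antennas=(a, a))

    def test_controller_overload_rejected(self, layout):
        eight = tuple(
            Antenna(id=i, center_xy=(10.0 + i, 10.0), controller=1)
            for i in range(1, 9)
        )
        with pytest.raises(LayoutError, match="C1"):
            AntennaLayout(tank=layout.tank, antennas=eight)


class TestNearestAntenna:
    def test_own_center_maps_to_self(self, layout):
        # Voronoi property: the center of every active antenna maps to it
        for a in layout.active_antennas:
            assert nearest_antenna(layout, a.center_xy) == a.id

    def test_equidistant_tie_breaks_to_lower_id(self, layout):
        c8 = np.array(layout.antenna(8).center_xy)
        c9 = np.array(layout.antenna(9).center_xy)
        mid = tuple((c8 + c9) / 2)
        # brute-force scan confirms the tie before asserting the winner
        d = {a.id: math.dist(a.center_xy, mid) for a in layout.active_antennas}
        assert d[8] == pytest.approx(d[9])
        assert min(d, key=d.get) in (8, 9)
        assert nearest_antenna(layout, mid) == 8

    def test_point_outside_tank_is_domain_error(self, layout):
        with pytest.raises(LayoutError, match="outside"):
            nearest_antenna(layout, (-1.0, 5.0))

    def test_full_coverage_no_gaps(self, layout):
        rng = np.random.default_rng(42)
        pts = rng.uniform((0, 0), (150, 70), size=(200, 2))
        ids = {a.id for a in layout.active_antennas}
        for p in pts:
            assert nearest_antenna(layout, tuple(p)) in ids

    def test_range_limited_dead_zone(self, layout):
        # a cell corner is ~12 cm from the nearest center, beyond the
        # 3.0 cm field radius of every antenna
        corner = (150 / 7, 70 / 6)
        assert nearest_antenna(layout, corner, range_limited=True) is None
        center = layout.antenna(1).center_xy
        assert nearest_antenna(layout, center, range_limited=True) == 1


class TestConfigRoundTrip:
    def test_shipped_default_config_matches_built_layout(self, layout):
        from pathlib import Path

        shipped = Path(__file__).parent.parent / "examples" / "default_layout.yaml"
        loaded = load_layout(shipped)
        assert loaded.controller_counts == layout.controller_counts
        for a, b in zip(loaded.antennas, layout.antennas):
            assert (a.id, a.controller, a.role, a.active) == (
                b.id, b.controller, b.role, b.active
            )
            assert a.center_xy == pytest.approx(b.center_xy)

    def test_save_load_identity(self, layout, tmp_path):
        p = tmp_path / "layout.yaml"
        save_layout(layout, p)
        loaded = load_layout(p)
        assert loaded.controller_counts == layout.controller_counts
        for a, b in zip(loaded.antennas, layout.antennas):
            assert a.id == b.id and a.active == b.active and a.role == b.role
            assert a.center_xy == pytest.approx(b.center_xy)

    def test_all_active_round_trip(self, layout, tmp_path):
        p = tmp_path / "layout.yaml"
        save_layout(with_all_active(layout), p)
        assert len(load_layout(p).active_antennas) == 42

    def test_controller_overload_in_config_rejected(self, layout, tmp_path):
        import yaml

        p = tmp_path / "bad.yaml"
        doc = {
            "antennas": [
                {"id": i, "x_cm": 5.0 * i, "y_cm": 5.0, "controller": 1}
                for i in range(1, 9)
            ]
        }
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(LayoutError, match="C1"):
            load_layout(p)

    def test_duplicate_id_in_config_rejected(self, tmp_path):
        import yaml

        p = tmp_path / "dup.yaml"
        doc = {
            "antennas": [
                {"id": 5, "x_cm": 10.0, "y_cm": 5.0, "controller": 1},
                {"id": 5, "x_cm": 20.0, "y_cm": 5.0, "controller": 2},
            ]
        }
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(LayoutError, match="5"):
            load_layout(p)

    def test_antenna_outside_tank_rejected(self, tmp_path):
        import yaml

        p = tmp_path / "out.yaml"
        doc = {"antennas": [{"id": 1, "x_cm": 500.0, "y_cm": 5.0, "controller": 1}]}
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(LayoutError, match="outside"):
            load_layout(p)
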