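"""RFID reader model: quantization, displacement, occupancy."""

import numpy as np
import pandas as pd
import pytest

from burrowtrack.motion import BehaviourParams, simulate_trajectory
from burrowtrack.rfid import (
    DetectionLog,
    burrow_occupancy,
    displacement_from_detections,
    ground_truth_displacement,
    occupancy_percentages,
    sample_detections,
    sheltered_intervals,
)

from conftest import EMERGED, SHELTERED, T0, make_trajectory


def constant_trajectory(point, seconds=60, uid="a1"):
    return make_trajectory([point] * seconds, uid=uid)


class TestSampleDetections:
    def test_stationary_animal_detected_every_tick(self, layout):
        center = layout.antenna(12).center_xy
        traj = constant_trajectory(center, seconds=60)
        log = sample_detections([traj], layout)
        assert len(log.events) == 12
        assert (log.events["antenna_id"] == 12).all()

    def test_cadence_must_be_multiple_of_step(self, layout):
        traj = constant_trajectory(layout.antenna(1).center_xy)
        with pytest.raises(ValueError, match="multiple"):
            sample_detections([traj], layout, cadence=7.5)

    def test_anti_collision_two_animals_one_antenna(self, layout):
        c = layout.antenna(5).center_xy
        a = constant_trajectory(c, seconds=10, uid="a1")
        b = constant_trajectory((c[0] + 1.0, c[1]), seconds=10, uid="a2")
        log = sample_detections([a, b], layout)
        per_tick = log.events.groupby("time")["uid"].nunique()
        assert (per_tick == 2).all()
        assert (log.events["antenna_id"] == 5).all()

    def test_range_limited_dead_zone_emits_nothing(self, layout):
        corner = (150 / 7, 70 / 6)  # >3 cm from every center
        traj = constant_trajectory(corner)
        log = sample_detections([traj], layout, range_limited=True)
        assert len(log.events) == 0


class TestDisplacement:
    def test_same_antenna_gives_zero(self, layout):
        traj = constant_trajectory(layout.antenna(3).center_xy, seconds=30)
        log = sample_detections([traj], layout)
        series = displacement_from_detections(log)[0]
        assert series.total() == 0.0

    def test_adjacent_antennas_give_grid_spacing(self, layout):
        c1 = layout.antenna(1).center_xy
        c2 = layout.antenna(2).center_xy
        positions = [c1] * 6 + [c2] * 5
        traj = make_trajectory(positions)
        log = sample_detections([traj], layout)
        series = displacement_from_detections(log)[0]
        assert series.values.max() == pytest.approx(150 / 7)
        assert series.total() == pytest.approx(150 / 7)

    def test_empty_log_gives_empty_series(self, layout):
        log = DetectionLog(
            layout=layout,
            events=pd.DataFrame(columns=["time", "uid", "antenna_id"]),
        )
        assert displacement_from_detections(log) == []

    def test_gap_bridged_with_single_distance(self, layout):
        c1, c3 = layout.antenna(1).center_xy, layout.antenna(3).center_xy
        times = pd.to_datetime(["2024-01-01 00:00:00", "2024-01-01 00:00:25"])
        events = pd.DataFrame({"time": times, "uid": "a1", "antenna_id": [1, 3]})
        log = DetectionLog(layout=layout, events=events)
        series = displacement_from_detections(log)[0]
        assert len(series.values) == 1
        assert series.values[0] == pytest.approx(2 * 150 / 7)
        assert series.gap_flags[0]

    def test_quantization_error_bounded_by_cell_radii(self, layout, schedule):
        # per-interval error vs true inter-tick displacement is at most
        # the sum of the two Voronoi cell radii (half-diagonals here)
        p = BehaviourParams(animal_uid="a1", emergence_rate_dark=5.0,
                            emergence_rate_light=5.0, retreat_rate=0.5)
        traj = simulate_trajectory(p, layout.tank, schedule, 3600, seed=2)
        log = sample_detections([traj], layout)
        series = displacement_from_detections(log)[0]
        gt = ground_truth_displacement(traj)
        # effective per-antenna cell radii by brute-force grid assignment
        # (cells around the 5 inactive grid positions are enlarged)
        active = layout.active_antennas
        centers = np.array([a.center_xy for a in active])
        xs, ys = np.meshgrid(np.linspace(0, 150, 301), np.linspace(0, 70, 141))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        assign = d.argmin(axis=1)
        radius = {
            active[i].id: d[assign == i, i].max() for i in range(len(active))
        }
        ids = log.events["antenna_id"].to_numpy()
        bound = np.array(
            [radius[i] + radius[j] for i, j in zip(ids[:-1], ids[1:])]
        )
        err = np.abs(series.values - gt.values)
        assert (err <= bound + 1e-6).all()

    def test_rfid_underestimates_true_path_with_physical_fields(self, layout, schedule):
        # dead zones + within-quadrant motion make the reader lose distance
        p = BehaviourParams(animal_uid="a1", emergence_rate_dark=5.0,
                            emergence_rate_light=5.0, retreat_rate=0.5)
        traj = simulate_trajectory(p, layout.tank, schedule, 2 * 3600, seed=8)
        log = sample_detections([traj], layout, range_limited=True)
        rfid_total = displacement_from_detections(log)[0].total()
        gt_total = ground_truth_displacement(traj).total()
        assert rfid_total <= gt_total


class TestOccupancy:
    def test_stationary_animal_is_100_percent(self, layout):
        traj = constant_trajectory(layout.antenna(22).center_xy)
        occ = occupancy_percentages(sample_detections([traj], layout))
        assert occ["a1"] == {22: 100.0}

    def test_three_to_one_split(self, layout):
        c1, c2 = layout.antenna(1).center_xy, layout.antenna(2).center_xy
        positions = [c1] * 15 + [c2] * 5
        traj = make_trajectory(positions)
        occ = occupancy_percentages(sample_detections([traj], layout))["a1"]
        assert occ[1] == pytest.approx(75.0)
        assert occ[2] == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_percentages_sum_to_100(self, layout, schedule, seed):
        p = BehaviourParams(animal_uid="a1")
        traj = simulate_trajectory(p, layout.tank, schedule, 4 * 3600, seed=seed)
        occ = occupancy_percentages(sample_detections([traj], layout))
        assert sum(occ["a1"].values()) == pytest.approx(100.0, abs=1e-9)

    def test_invariant_to_event_order(self, layout, schedule):
        p = BehaviourParams(animal_uid="a1")
        traj = simulate_trajectory(p, layout.tank, schedule, 3600, seed=5)
        log = sample_detections([traj], layout)
        shuffled = log.events.sample(frac=1.0, random_state=0)
        log2 = DetectionLog(layout=layout, events=shuffled.reset_index(drop=True))
        assert occupancy_percentages(log) == occupancy_percentages(log2)


class TestBurrowOccupancy:
    def test_held_at_interior_antenna(self, layout):
        interior = layout.antennas_with_role("burrow_interior")[0]
        traj = constant_trajectory(interior.center_xy, seconds=500)
        log = sample_detections([traj], layout)
        intervals = burrow_occupancy(log, layout)["a1"]
        assert len(intervals) == 1
        start, end = intervals[0]
        assert (end - start).total_seconds() == 500.0

    def test_single_tick_touch_is_pass_through(self, layout):
        interior = layout.antennas_with_role("burrow_interior")[0].center_xy
        grid = layout.antenna(4).center_xy
        positions = [grid] * 5 + [interior] * 5 + [grid] * 5  # one tick inside
        traj = make_trajectory(positions)
        log = sample_detections([traj], layout)
        assert burrow_occupancy(log, layout)["a1"] == []

    def test_layout_without_interior_antennas_rejected(self, layout):
        from burrowtrack.layout import AntennaLayout
        from dataclasses import replace as drep

        bare = AntennaLayout(
            tank=layout.tank,
            antennas=tuple(drep(a, role="grid") for a in layout.antennas),
        )
        traj = constant_trajectory(layout.antenna(1).center_xy)
        log = sample_detections([traj], layout)
        with pytest.raises(Exception, match="burrow_interior"):
            burrow_occupancy(log, bare)

    def test_recovers_ground_truth_sheltered_time(self, layout):
        # hand-built trajectory: shelter, wander far from the burrow, shelter
        interior = layout.tank.burrows[0].interior_xy
        far = layout.antenna(25).center_xy
        positions = [interior] * 300 + [far] * 200 + [interior] * 400
        states = [SHELTERED] * 300 + [EMERGED] * 200 + [SHELTERED] * 400
        traj = make_trajectory(positions, states)
        log = sample_detections([traj], layout)
        recovered = burrow_occupancy(log, layout)["a1"]
        truth = sheltered_intervals(traj)
        assert len(recovered) == len(truth) == 2
        for (rs, re), (ts, te) in zip(recovered, truth):
            rec = (re - rs).total_seconds()
            true = (te - ts).total_seconds()
            # agreement within one reader cadence per transition
            assert abs(rec - true) <= 2 * log.cadence


class TestLogValidation:
    def test_unknown_antenna_rejected(self, layout):
        events = pd.DataFrame(
            {"time": [T0], "uid": ["a1"], "antenna_id": [99]}
        )
        with pytest.raises(ValueError, match="99"):
            DetectionLog(layout=layout, events=events)

    def test_inactive_antenna_rejected(self, layout):
        events = pd.DataFrame({"time": [T0], "uid": ["a1"], "antenna_id": [13]})
        with pytest.raises(ValueError, match="13"):
            DetectionLog(layout=layout, events=events)
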