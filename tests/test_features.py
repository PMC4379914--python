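"""The eleven behavioral markers: hand oracles and structural properties."""

import math

import numpy as np
import pytest

import locustphase as lp
from locustphase.features import MARKERS, BoutConfig

RAW = BoutConfig(speed_threshold=0.5, min_bout=1.0, smoothing_window=1)


def traj_from_x(xs, dt=1.0, y=15.0):
    xs = np.asarray(xs, dtype=float)
    pos = np.column_stack([xs, np.full_like(xs, y)])
    return lp.Trajectory(np.arange(len(xs)) * dt, pos)


def traj_from_xy(points, dt=1.0):
    pos = np.asarray(points, dtype=float)
    return lp.Trajectory(np.arange(len(pos)) * dt, pos)


class TestZoneOccupancy:
    def test_duration_inside_equals_recording_duration(self, zones):
        t = traj_from_x([1.0, 2.0, 3.0, 1.0], dt=0.5)
        assert lp.zone_duration(t, zones.stimulus_zone) == pytest.approx(t.duration)

    def test_duration_never_in_zone_is_zero(self, zones):
        t = traj_from_x([10.0, 11.0, 12.0])
        assert lp.zone_duration(t, zones.stimulus_zone) == 0.0

    def test_duration_hand_count(self, zones):
        # 10 samples at dt=0.5; samples 2..5 sit in the stimulus zone
        xs = [10, 10, 1, 2, 3, 4, 10, 10, 10, 10]
        t = traj_from_x(xs, dt=0.5)
        assert lp.zone_duration(t, zones.stimulus_zone) == pytest.approx(2.0)

    def test_entries_counting(self, zones):
        assert lp.zone_entries(traj_from_x([10, 11, 12]), zones.stimulus_zone) == 0
        # starting inside counts as one entry
        assert lp.zone_entries(traj_from_x([1, 2, 1]), zones.stimulus_zone) == 1
        # occupancy 0,1,1,0,1 -> 2 entries
        assert lp.zone_entries(traj_from_x([10, 1, 2, 10, 3]), zones.stimulus_zone) == 2

    def test_latency_conventions(self, geom, zones):
        assert lp.first_entry_latency(traj_from_x([1, 2, 3]), zones.stimulus_zone) == 0.0
        never = traj_from_x([10, 11, 12])
        assert lp.first_entry_latency(never, zones.stimulus_zone) == pytest.approx(
            never.duration
        )
        # first in-zone sample at index 7, dt=0.2 -> 1.4 s
        xs = [10] * 7 + [1, 1, 1]
        assert lp.first_entry_latency(
            traj_from_x(xs, dt=0.2), zones.stimulus_zone
        ) == pytest.approx(1.4)

    def test_duration_conservation(self, zones, make_uniform_trajectory):
        t = make_uniform_trajectory(0)
        total = (
            lp.zone_duration(t, zones.stimulus_zone)
            + lp.zone_duration(t, zones.opposite_zone)
            + lp.zone_duration(t, zones.middle)
        )
        assert total == pytest.approx(t.duration)


class TestPathAndBouts:
    def test_stationary_track_has_zero_length(self):
        assert lp.path_length(traj_from_x([5, 5, 5])) == 0.0

    def test_pythagorean_step(self):
        t = traj_from_xy([(0.0, 0.0), (3.0, 4.0)])
        assert lp.path_length(t) == pytest.approx(5.0)

    def test_two_step_hand_sum(self):
        t = traj_from_xy([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0)])
        assert lp.path_length(t) == pytest.approx(2.0)

    def test_no_bouts_below_threshold(self):
        t = traj_from_x([1.0, 1.1, 1.2, 1.3])
        assert lp.movement_bouts(t, RAW) == []

    def test_constant_fast_motion_is_one_full_bout(self):
        t = traj_from_x([1, 3, 5, 7, 9])
        bouts = lp.movement_bouts(t, RAW)
        assert bouts == [(0.0, 4.0)]

    def test_hand_segmented_speed_profile(self):
        # speeds 0,0,5,5,5,0 cm/s at dt=1; threshold 1, min_bout 2 -> one 3 s bout
        t = traj_from_x([1, 1, 1, 6, 11, 16, 16])
        cfg = BoutConfig(speed_threshold=1.0, min_bout=2.0, smoothing_window=1)
        bouts = lp.movement_bouts(t, cfg)
        assert len(bouts) == 1
        start, end = bouts[0]
        assert end - start == pytest.approx(3.0)

    def test_short_bursts_filtered_by_min_bout(self):
        t = traj_from_x([1, 6, 6, 6, 11, 11])
        cfg = BoutConfig(speed_threshold=1.0, min_bout=2.0, smoothing_window=1)
        assert lp.movement_bouts(t, cfg) == []


class TestDistanceAndAttraction:
    def test_distance_at_reference_point_is_zero(self, geom):
        sx, sy = geom.stimulus_wall_center
        t = traj_from_xy([(sx, sy), (sx, sy)])
        assert lp.mean_distance_to_stimulus(t, geom) == 0.0

    def test_collinear_distance(self, geom):
        t = traj_from_x([7.0, 7.0])
        assert lp.mean_distance_to_stimulus(t, geom) == pytest.approx(7.0)

    def test_mean_of_two_distances(self, geom):
        t = traj_from_x([2.0, 4.0])
        assert lp.mean_distance_to_stimulus(t, geom) == pytest.approx(3.0)

    def test_attraction_index_hand_cases(self, geom, zones):
        inside = traj_from_x([1.0] * 361, dt=1.0)
        assert lp.attraction_index(inside, zones) == pytest.approx(360.0)
        middle = traj_from_x([12.0] * 10)
        assert lp.attraction_index(middle, zones) == 0.0
        # 5 held intervals in stimulus, 2 in opposite at dt=1 -> AI = 3
        xs = [1, 1, 1, 1, 1, 24, 24, 12]
        assert lp.attraction_index(traj_from_x(xs), zones) == pytest.approx(3.0)


class TestComputeFeatures:
    def test_eleven_populated_fields(self, geom, make_uniform_trajectory):
        fv = lp.compute_features(make_uniform_trajectory(1), geom)
        d = fv.as_dict()
        assert tuple(d) == MARKERS
        assert all(np.isfinite(v) for v in d.values())

    def test_stationary_animal_in_middle(self, geom):
        t = traj_from_x([12.5] * 20, dt=0.5)
        fv = lp.compute_features(t, geom, RAW)
        assert fv.TDM == 0.0
        assert fv.FOM == 0 and fv.TDMV == 0.0
        assert fv.AI == 0.0
        assert fv.LFOISA == fv.LFOIOSA == t.duration

    def test_six_sample_crossing_track_matches_hand_computation(self, geom):
        # hand-built track crossing middle -> stimulus -> middle -> opposite/wall
        pts = [(12.5, 15.0), (5.0, 15.0), (4.0, 15.0), (10.0, 15.0), (20.0, 15.0), (24.0, 28.0)]
        t = traj_from_xy(pts, dt=1.0)
        fv = lp.compute_features(t, geom, RAW)
        assert fv.EFISA == 1
        assert fv.LFOISA == pytest.approx(1.0)
        assert fv.TDCW == pytest.approx(0.0)  # wall only reached at the final sample
        assert fv.EFCW == 1
        assert fv.EFIOSA == 1
        assert fv.LFOIOSA == pytest.approx(4.0)
        expected_mdtsg = (12.5 + 5.0 + 4.0 + 10.0 + 20.0 + math.hypot(24.0, 13.0)) / 6.0
        assert fv.MDTSG == pytest.approx(expected_mdtsg)
        expected_tdm = 7.5 + 1.0 + 6.0 + 10.0 + math.hypot(4.0, 13.0)
        assert fv.TDM == pytest.approx(expected_tdm)
        assert fv.FOM == 1 and fv.TDMV == pytest.approx(5.0)  # all steps fast
        assert fv.AI == pytest.approx(2.0 - 1.0)

    def test_feature_table_columns_and_order(self, geom, make_uniform_trajectory):
        trajs = [make_uniform_trajectory(i) for i in range(3)]
        table = lp.features_table(trajs, geom)
        assert list(table.columns) == ["animal_id", "arm_label", *MARKERS]
        assert len(table) == 3


class TestStructuralProperties:
    def test_conservation_and_mirror_symmetry_over_random_trajectories(
        self, geom, zones, make_uniform_trajectory
    ):
        for seed in range(200):
            t = make_uniform_trajectory(seed, n=60, dt=0.25)
            fv = lp.compute_features(t, geom, RAW)
            mid = lp.zone_duration(t, zones.middle)
            assert fv.AI == pytest.approx(
                lp.zone_duration(t, zones.stimulus_zone)
                - lp.zone_duration(t, zones.opposite_zone)
            )
            total = (
                lp.zone_duration(t, zones.stimulus_zone)
                + lp.zone_duration(t, zones.opposite_zone)
                + mid
            )
            assert total == pytest.approx(t.duration, abs=1e-9)

            mv = lp.compute_features(t.mirrored(geom), geom, RAW)
            assert mv.EFISA == fv.EFIOSA and mv.EFIOSA == fv.EFISA
            assert mv.LFOISA == pytest.approx(fv.LFOIOSA)
            assert mv.LFOIOSA == pytest.approx(fv.LFOISA)
            assert mv.AI == pytest.approx(-fv.AI)
            assert mv.TDM == pytest.approx(fv.TDM)
            assert mv.TDMV == pytest.approx(fv.TDMV)
            assert mv.FOM == fv.FOM
            assert mv.TDCW == pytest.approx(fv.TDCW)
            assert mv.EFCW == fv.EFCW

    def test_entry_latency_equivalence(self, geom, zones, make_uniform_trajectory):
        # an uncensored latency implies at least one entry; a zone never
        # entered is always censored to the full duration.  (The converse
        # has one boundary case: a first visit on the final sample yields a
        # latency numerically equal to the censoring value.)
        for seed in range(50):
            t = make_uniform_trajectory(seed, n=12, dt=0.5)
            fv = lp.compute_features(t, geom, RAW)
            stim_visited = bool(np.any(zones.stimulus_zone.mask(t.positions)))
            opp_visited = bool(np.any(zones.opposite_zone.mask(t.positions)))
            assert (fv.EFISA >= 1) == stim_visited
            assert (fv.EFIOSA >= 1) == opp_visited
            if fv.LFOISA < t.duration:
                assert fv.EFISA >= 1
            if not stim_visited:
                assert fv.LFOISA == t.duration
            if fv.LFOIOSA < t.duration:
                assert fv.EFIOSA >= 1
            if not opp_visited:
                assert fv.LFOIOSA == t.duration

    def test_bounds_invariants(self, geom, make_uniform_trajectory):
        for seed in range(20):
            t = make_uniform_trajectory(seed)
            fv = lp.compute_features(t, geom)
            assert 0 <= fv.TDMV <= t.duration + 1e-9
            assert -t.duration <= fv.AI <= t.duration
            assert fv.TDM >= 0 and fv.MDTSG >= 0
            if fv.TDM == 0:
                assert fv.TDMV == 0
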