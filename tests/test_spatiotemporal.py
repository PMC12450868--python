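"""Spatial/temporal parameters: zone scores, step geometry, tandem count,
speed, double support, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from vestigait import body_model as bm
from vestigait import preprocess as pp
from vestigait import spatiotemporal_metrics as sm
from vestigait import synthetic_gait as sg
from vestigait.trial_io import GaitEventTable, TrialRecord

from conftest import hs_draw, rotate_trial


def _com_path(y_profile, rate=100.0, speed=1.2):
    n = len(y_profile)
    t = np.arange(n) / rate
    pos = np.stack([speed * t, np.asarray(y_profile, float), np.ones(n)],
                   axis=1)
    return bm.ComTrajectory(pos, np.gradient(pos, axis=0) * rate, rate)


def _excursion(n, amp, at, width=60):
    y = np.zeros(n)
    y[at : at + width] = amp * np.sin(np.linspace(0, np.pi, width))
    return y


class TestComZoneScore:
    def test_inside_zone0_scores_zero(self):
        com = _com_path(0.05 * np.sin(np.linspace(0, 20, 800)))
        assert sm.com_zone_score(com) == 0.0

    def test_excursions_scored_by_outermost_zone(self):
        # two excursions peaking in zone 1 and one in zone 2, weights 1,2,3
        n = 1200
        y = (_excursion(n, 0.20, 100) + _excursion(n, -0.20, 400)
             + _excursion(n, 0.30, 800))
        score = sm.com_zone_score(_com_path(y))
        assert score == 2 * 1 + 1 * 2

    def test_boundary_scaling_contains_trajectory(self):
        n = 1200
        y = _excursion(n, 0.30, 800)
        wide = sm.ZoneSpec(boundaries=(1.524, 2.54, 3.81))
        assert sm.com_zone_score(_com_path(y), wide) == 0.0

    @given(b1=hst.floats(0.02, 0.2), g2=hst.floats(0.01, 0.3),
           g3=hst.floats(0.01, 0.3))
    @settings(max_examples=25, deadline=None)
    def test_zero_sway_walker_scores_zero_for_any_zones(self, b1, g2, g3):
        zones = sm.ZoneSpec(boundaries=(b1, b1 + g2, b1 + g2 + g3))
        com = _com_path(np.zeros(500))
        assert sm.com_zone_score(com, zones) == 0.0


def _heel_trial(ly, ry, rate=100.0):
    n = len(ly)
    t = np.arange(n) / rate
    mk = {
        "LHEE": np.stack([1.2 * t, np.asarray(ly, float), np.full(n, 0.03)],
                         axis=1),
        "RHEE": np.stack([1.2 * t, np.asarray(ry, float), np.full(n, 0.03)],
                         axis=1),
    }
    return TrialRecord("S", "comfortable_gait", mk, rate)


class TestFootZoneScore:
    def test_both_heels_in_zone0(self):
        trial = _heel_trial(np.full(500, 0.05), np.full(500, -0.05))
        ref = np.stack([np.linspace(0, 6, 500), np.zeros(500)], axis=1)
        assert sm.foot_zone_score(trial, reference_xy=ref) == 0.0

    def test_both_in_zone1_fraction_of_time(self):
        n = 1000
        ly, ry = np.full(n, 0.05), np.full(n, -0.05)
        ly[400:600] = 0.20
        ry[400:600] = 0.18  # both inside zone 1 for 20% of the trial
        trial = _heel_trial(ly, ry)
        ref = np.stack([np.linspace(0, 12, n), np.zeros(n)], axis=1)
        score = sm.foot_zone_score(trial, reference_xy=ref)
        assert score == pytest.approx(0.20, abs=0.01)

    def test_one_foot_out_other_in_scores_zero(self):
        n = 500
        trial = _heel_trial(np.full(n, 0.30), np.full(n, -0.02))
        ref = np.stack([np.linspace(0, 6, n), np.zeros(n)], axis=1)
        assert sm.foot_zone_score(trial, reference_xy=ref) == 0.0


def _alternating_steps(widths_left=0.06, widths_right=-0.06, n_steps=8,
                       step_len=0.65, rate=100.0, rot_deg=0.0):
    """Trial with heels alternating on two parallel lines, plus events."""
    n = int(n_steps * 55 + 100)
    t_strikes = 0.3 + np.arange(n_steps) * 0.55
    lhee = np.zeros((n, 3))
    rhee = np.zeros((n, 3))
    records = []
    for k, ts in enumerate(t_strikes):
        side = "left" if k % 2 == 0 else "right"
        x = k * step_len
        y = widths_left if side == "left" else widths_right
        i = int(ts * rate)
        arr = lhee if side == "left" else rhee
        arr[i:, 0] = x
        arr[i:, 1] = y
        records.append((ts, side, "foot_strike"))
        records.append((ts + 0.4, side, "foot_off"))
    markers = {"LHEE": lhee + [0, 0, 0.03], "RHEE": rhee + [0, 0, 0.03]}
    trial = TrialRecord("S", "comfortable_gait", markers, rate)
    if rot_deg:
        trial = rotate_trial(trial, rot_deg)
    events = GaitEventTable.from_records(records)
    return trial, events


class TestStepWidth:
    def test_parallel_tracks(self):
        trial, events = _alternating_steps()
        steps = sm.build_step_series(trial, events)
        assert sm.step_width(steps) == pytest.approx(0.12, abs=1e-6)

    def test_rotation_invariance(self):
        trial, events = _alternating_steps(rot_deg=30.0)
        steps = sm.build_step_series(trial, events)
        assert sm.step_width(steps) == pytest.approx(0.12, abs=1e-6)

    def test_single_side_gives_missing(self):
        trial, events = _alternating_steps()
        left_only = GaitEventTable(
            events.events[events.events["side"] == "left"])
        steps = sm.build_step_series(trial, left_only)
        assert np.isnan(sm.step_width(steps))


class TestMlStepDistance:
    def test_periodic_gait_zero(self):
        trial, events = _alternating_steps()
        steps = sm.build_step_series(trial, events)
        assert sm.ml_step_distance(steps, "left") == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_catchup_step_displacement(self):
        # one left placement displaced laterally by 0.15 m (the next left
        # step returns to the track)
        trial, events = _alternating_steps()
        lhee = trial.markers["LHEE"].copy()
        i = int((0.3 + 4 * 0.55) * trial.rate)  # third left strike
        j = int((0.3 + 6 * 0.55) * trial.rate)  # fourth left strike
        lhee[i:j, 1] += 0.15
        trial = trial.copy_with(markers={**trial.markers, "LHEE": lhee})
        steps = sm.build_step_series(trial, events)
        assert sm.ml_step_distance(steps, "left") == pytest.approx(0.15,
                                                                   abs=0.01)

    def test_invariant_to_ap_step_length(self):
        a, ev_a = _alternating_steps(step_len=0.65)
        b, ev_b = _alternating_steps(step_len=0.85)
        da = sm.ml_step_distance(sm.build_step_series(a, ev_a), "left")
        db = sm.ml_step_distance(sm.build_step_series(b, ev_b), "left")
        assert da == pytest.approx(db, abs=1e-9)


class TestTandem:
    def test_first_placement_offline_counts_zero(self):
        trial, events = _alternating_steps(widths_left=0.30,
                                           widths_right=0.0)
        trial = trial.copy_with(task="tandem_walk")
        assert sm.tandem_step_count(trial, events) == 0

    def test_non_tandem_task_rejected(self):
        trial, events = _alternating_steps()
        with pytest.raises(ValueError, match="tandem"):
            sm.tandem_step_count(trial, events)

    @pytest.mark.parametrize("seed", [7, 9, 21])
    def test_generated_tandem_matches_sidecar(self, seed):
        draw = hs_draw(group="BV", step_width=0.16)
        trial, truth = sg.generate_trial(sg.PRESETS["BV"], "tandem_walk",
                                         draw, seed=seed)
        proc = pp.add_virtual_markers(pp.lowpass(trial))
        events = pp.detect_gait_events(proc)
        assert sm.tandem_step_count(proc, events) == truth["tandem_online_steps"]


class TestWalkingSpeed:
    def test_distance_over_time(self):
        n = 601
        t = np.arange(n) / 100.0
        pos = np.stack([1.2 * t, np.zeros(n), np.ones(n)], axis=1)
        com = bm.ComTrajectory(pos, np.gradient(pos, axis=0) * 100, 100.0)
        events = GaitEventTable.from_records(
            [(0.5, "left", "foot_strike"), (5.5, "right", "foot_strike")])
        assert sm.walking_speed(com, events) == pytest.approx(1.2, rel=1e-6)

    def test_fewer_than_two_strikes_missing(self):
        com = bm.ComTrajectory(np.zeros((100, 3)), np.zeros((100, 3)), 100.0)
        events = GaitEventTable.from_records([(0.5, "left", "foot_strike")])
        assert np.isnan(sm.walking_speed(com, events))


class TestDoubleSupport:
    EXAMPLE = [
        (0.00, "right", "foot_strike"),
        (0.12, "left", "foot_off"),
        (0.55, "left", "foot_strike"),
        (0.67, "right", "foot_off"),
        (1.10, "right", "foot_strike"),
    ]

    def test_worked_interval_arithmetic(self):
        events = GaitEventTable.from_records(self.EXAMPLE)
        ds, n = sm.double_support_time(events, side="right")
        assert ds == pytest.approx(0.24, abs=1e-9)
        assert n == 1

    def test_flight_phase_zero(self):
        events = GaitEventTable.from_records([
            (0.00, "right", "foot_strike"),
            (0.20, "right", "foot_off"),
            (0.30, "left", "foot_strike"),
            (0.50, "left", "foot_off"),
            (0.60, "right", "foot_strike"),
        ])
        ds, _ = sm.double_support_time(events, side="right")
        assert ds == pytest.approx(0.0, abs=1e-12)

    def test_time_scaling_linearity(self):
        events = GaitEventTable.from_records(self.EXAMPLE)
        scaled = GaitEventTable.from_records(
            [(2 * t, s, k) for t, s, k in self.EXAMPLE])
        ds1, _ = sm.double_support_time(events, side="right")
        ds2, _ = sm.double_support_time(scaled, side="right")
        assert ds2 == pytest.approx(2 * ds1, rel=1e-12)

    def test_brute_force_stance_overlap_oracle(self, processed_trial):
        """The interval arithmetic equals a fine-grid boolean integration
        of simultaneous stance."""
        events = pp.detect_gait_events(processed_trial)
        side = "left"
        strikes = events.strikes(side)
        dt = 1e-4
        grid = np.arange(0.0, processed_trial.duration, dt)

        def stance(side_name):
            on = np.zeros_like(grid, dtype=bool)
            sub = events.side(side_name)
            current = sub["kind"].iloc[0] == "foot_off"  # stance from start
            last = 0.0
            for _, row in sub.iterrows():
                if row["kind"] == "foot_strike":
                    current, last = True, row["time"]
                else:
                    if current:
                        on[(grid >= last) & (grid < row["time"])] = True
                    current = False
            if current:
                on[grid >= last] = True
            return on

        both = stance("left") & stance("right")
        expected = []
        for c0, c1 in zip(strikes[:-1], strikes[1:]):
            mask = (grid >= c0) & (grid < c1)
            expected.append(both[mask].sum() * dt)
        ds, n = sm.double_support_time(events, side=side)
        assert n == len(expected)
        assert ds == pytest.approx(np.median(expected), abs=2 * dt)


class TestTaskTimeAndAggregation:
    def test_full_trial_convention(self):
        trial = TrialRecord("S", "comfortable_gait",
                            {"LASI": np.zeros((500, 3))}, 100.0)
        assert sm.task_time(trial, None, convention="full") == \
            pytest.approx(4.99)

    def test_event_bounded_convention(self):
        trial = TrialRecord("S", "comfortable_gait",
                            {"LASI": np.zeros((500, 3))}, 100.0)
        events = GaitEventTable.from_records(
            [(0.4, "left", "foot_strike"), (4.2, "left", "foot_off")])
        assert sm.task_time(trial, events) == pytest.approx(3.8)

    @pytest.mark.parametrize("values,expected", [
        ([3], 3.0), ([1, 2, 10], 2.0), ([1, 2, 3, 4], 2.5)])
    def test_median_aggregation(self, values, expected):
        med, n = sm.aggregate_per_trial(values)
        assert med == expected
        assert n == len(values)

    def test_empty_gives_missing(self):
        med, n = sm.aggregate_per_trial([])
        assert np.isnan(med) and n == 0


class TestZoneSpecValidation:
    def test_nonincreasing_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sm.ZoneSpec(boundaries=(0.3, 0.2, 0.4))

    def test_nonzero_inner_weight_rejected(self):
        with pytest.raises(ValueError, match="zone 0"):
            sm.ZoneSpec(weights=(1.0, 1.0, 2.0, 3.0))
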