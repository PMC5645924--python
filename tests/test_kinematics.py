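"""Finite-difference kinematics, angles, peaks, timing, and the full pipeline."""

import math

import numpy as np
import pytest

from deglukin.coordinates import ScaleFactor
from deglukin.kinematics import (
    TrajectorySeries,
    analyze_recording,
    displacement_components,
    finite_difference_velocity,
    peak_summary,
    separation_distance_series,
    tilt_angle_series,
    transit_time,
)
from deglukin.smoothing import SmoothingSpec
from deglukin.trajectory_io import EventLog

from conftest import make_recording

UNIT_SCALE = ScaleFactor(s=1.0, reference_length_mm=24.0, n_frames=1)
NO_SMOOTH = SmoothingSpec(method="none")


class TestFiniteDifferenceVelocity:
    def test_linear_motion_gives_slope_everywhere(self):
        assert np.allclose(finite_difference_velocity([0, 1, 2, 3], 1.0), 1.0)

    def test_three_stencils_direct_evaluation(self):
        # forward (1-0)/1, central (4-0)/2 and (9-1)/2, backward (9-4)/1
        v = finite_difference_velocity([0, 1, 4, 9], 1.0)
        assert np.allclose(v, [1, 2, 4, 5])

    def test_constant_series_gives_zero(self):
        assert np.allclose(finite_difference_velocity(np.full(5, 2.2), 0.1), 0.0)

    def test_affine_exact_any_dt(self, rng):
        t = np.arange(12) * 0.033
        x = -4.0 * t + 9.0
        assert np.allclose(finite_difference_velocity(x, 0.033), -4.0, atol=1e-9)

    def test_quadratic_exact_at_interior_samples(self):
        dt = 0.1
        t = np.arange(10) * dt
        x = 3.0 * t**2 + t
        v = finite_difference_velocity(x, dt)
        assert np.allclose(v[1:-1], 6.0 * t[1:-1] + 1.0, atol=1e-9)

    def test_sinusoid_interior_error_within_third_derivative_bound(self):
        dt = 1 / 30
        t = np.arange(61) * dt
        x = 5.0 * np.sin(2.0 * t)
        v = finite_difference_velocity(x, dt)
        exact = 10.0 * np.cos(2.0 * t)
        bound = dt**2 / 6.0 * np.max(np.abs(5.0 * 2.0**3))  # max |x'''|
        assert np.abs(v[1:-1] - exact[1:-1]).max() <= bound + 1e-12

    def test_trapezoidal_reintegration_recovers_affine_displacement(self):
        dt = 0.05
        x = 2.0 * np.arange(20) * dt + 1.0
        v = finite_difference_velocity(x, dt)
        re = x[0] + np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * dt)])
        assert np.allclose(re, x, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            finite_difference_velocity([1.0], 0.1)


class TestDisplacementComponents:
    def test_reference_everywhere_gives_zero(self):
        traj = np.tile([2.0, 3.0], (6, 1))
        comps = displacement_components(traj)
        for arr in comps.values():
            assert np.allclose(arr, 0.0)

    def test_pythagorean_components(self):
        traj = np.array([[0.0, 0.0], [3.0, 4.0]])
        comps = displacement_components(traj)
        assert comps["horizontal"][1] == 3.0
        assert comps["vertical"][1] == 4.0
        assert comps["planar_magnitude"][1] == 5.0

    def test_magnitude_dominates_components(self, rng):
        traj = rng.normal(size=(30, 2))
        comps = displacement_components(traj)
        assert (comps["planar_magnitude"] >= np.abs(comps["vertical"]) - 1e-12).all()
        assert (comps["planar_magnitude"] >= np.abs(comps["horizontal"]) - 1e-12).all()

    def test_all_na_rejected(self):
        with pytest.raises(ValueError, match="all-NA"):
            displacement_components(np.full((4, 2), np.nan))


class TestTiltAngle:
    def test_upright_direction_is_zero_from_y_axis(self):
        base = np.zeros((1, 2))
        tip = np.array([[0.0, 1.0]])
        assert tilt_angle_series(base, tip, "from_y_axis")[0] == pytest.approx(0.0)

    def test_diagonal_direction_is_45_degrees(self):
        base = np.zeros((1, 2))
        tip = np.array([[1.0, 1.0]])
        assert tilt_angle_series(base, tip, "from_y_axis")[0] == pytest.approx(45.0)

    def test_from_initial_starts_at_zero(self):
        base = np.zeros((3, 2))
        tip = np.array([[0.2, 1.0], [0.5, 0.9], [0.9, 0.4]])
        ang = tilt_angle_series(base, tip, "from_initial")
        assert ang[0] == pytest.approx(0.0, abs=1e-12)

    def test_posterior_rotation_is_positive(self):
        # tip swings from upright toward -x (posterior): positive by convention
        base = np.zeros((2, 2))
        tip = np.array([[0.0, 1.0], [-1.0, 1.0]])
        ang = tilt_angle_series(base, tip, "from_initial")
        assert ang[1] == pytest.approx(45.0)

    def test_wraps_to_half_open_interval(self):
        base = np.zeros((2, 2))
        tip = np.array([[0.0, 1.0], [0.0, -1.0]])  # 180 degree flip
        ang = tilt_angle_series(base, tip, "from_initial")
        assert ang[1] == pytest.approx(180.0)

    def test_zero_length_orientation_rejected(self):
        base = np.zeros((1, 2))
        with pytest.raises(ValueError, match="zero-length"):
            tilt_angle_series(base, base, "from_y_axis")


class TestSeparationDistance:
    def test_identical_series_give_zero(self):
        a = np.ones((4, 2))
        assert np.allclose(separation_distance_series(a, a), 0.0)

    def test_pythagorean_distance_and_symmetry(self):
        a = np.zeros((1, 2))
        b = np.array([[3.0, 4.0]])
        assert separation_distance_series(a, b)[0] == 5.0
        assert np.array_equal(
            separation_distance_series(a, b), separation_distance_series(b, a)
        )

    def test_na_propagates(self):
        a = np.array([[0.0, 0.0], [np.nan, 0.0]])
        b = np.zeros((2, 2))
        d = separation_distance_series(a, b)
        assert d[0] == 0.0 and np.isnan(d[1])


class TestPeakSummary:
    def test_signed_peak_keeps_sign(self):
        assert peak_summary(np.array([0, 3, -5, 2]), signed=True) == (-5.0, 2)

    def test_earliest_frame_tie_break(self):
        assert peak_summary(np.array([1.0, 1.0, 1.0])) == (1.0, 0)

    def test_na_skipped(self):
        assert peak_summary(np.array([np.nan, 2.0, np.nan])) == (2.0, 1)

    def test_unsigned_mode_takes_maximum(self):
        assert peak_summary(np.array([-9.0, 1.0, 4.0]), signed=False) == (4.0, 2)

    def test_all_na_rejected(self):
        with pytest.raises(ValueError, match="all-NA"):
            peak_summary(np.array([np.nan, np.nan]))


class TestTransitTime:
    EVENTS = EventLog(entries={"bolus cross the mandible angle": 30,
                               "bolus tail cross the UES": 60})

    def test_one_second_transit(self):
        sec, rev = transit_time(self.EVENTS, "bolus cross the mandible angle",
                                "bolus tail cross the UES", 30.0)
        assert sec == 1.0 and not rev

    def test_same_frame_zero(self):
        log = EventLog(entries={"event_03": 10, "event_04": 10})
        assert transit_time(log, "event_03", "event_04", 30.0) == (0.0, False)

    def test_consecutive_frames_at_30fps(self):
        log = EventLog(entries={"event_03": 10, "event_04": 11})
        sec, _ = transit_time(log, "event_03", "event_04", 30.0)
        assert sec == pytest.approx(1 / 30)
        assert round(sec, 3) == 0.033

    def test_reversed_events_flagged(self):
        sec, rev = transit_time(self.EVENTS, "bolus tail cross the UES",
                                "bolus cross the mandible angle", 30.0)
        assert sec == -1.0 and rev

    def test_missing_event_rejected(self):
        with pytest.raises(KeyError):
            transit_time(self.EVENTS, "event_09", "bolus tail cross the UES", 30.0)


def vertical_ramp_recording(n=31, fps=30.0, total_mm=10.0):
    """Hyoid rises total_mm over (n-1)/fps seconds; everything else static."""
    rows = []
    for i in range(n):
        dy = total_mm * i / (n - 1)
        rows += [
            (i, "coin_a", 10.0, 10.0), (i, "coin_b", 34.0, 10.0),
            (i, "c2", 100.0, 180.0), (i, "c4", 100.0, 200.0),
            (i, "hyoid", 80.0, 190.0 - dy),  # up = decreasing v
        ]
    return make_recording(rows, fps=fps)


class TestAnalyzeRecording:
    def test_pure_vertical_ramp_recovers_peaks(self):
        rec = vertical_ramp_recording()
        res = analyze_recording(rec, UNIT_SCALE, smoothing=NO_SMOOTH)
        summary = res.summary
        assert summary.get("hyoid maximal displacement (vertical)").value == pytest.approx(10.0, abs=1e-9)
        assert summary.get("hyoid maximal displacement (horizontal)").value == pytest.approx(0.0, abs=1e-9)
        assert summary.get("hyoid maximal displacement (two dimensional)").value == pytest.approx(10.0, abs=1e-9)
        # constant-velocity ramp: 10 mm over 1 s
        assert summary.get("hyoid maximal velocity (vertical)").value == pytest.approx(10.0, abs=1e-6)

    def test_static_recording_all_zero(self, simple_recording):
        res = analyze_recording(simple_recording, UNIT_SCALE, smoothing=NO_SMOOTH)
        for rec_ in res.summary.peaks:
            assert rec_.value == pytest.approx(0.0, abs=1e-9)

    def test_units_match_parameter_classes(self):
        rec = vertical_ramp_recording()
        res = analyze_recording(rec, UNIT_SCALE, smoothing=NO_SMOOTH)
        for peak in res.summary.peaks:
            if "velocity" in peak.parameter:
                assert peak.units in ("mm/s", "degree/s")
            elif "angle" in peak.parameter:
                assert peak.units == "degree"
            else:
                assert peak.units == "mm"
        for name, ts in res.series.items():
            assert isinstance(ts, TrajectorySeries)
            assert len(ts.values) == len(res.times)

    def test_motion_start_event_sets_reference(self):
        events = EventLog(entries={"bolus cross the mandible angle": 15})
        rec = vertical_ramp_recording()
        rec.events = events
        res = analyze_recording(
            rec, UNIT_SCALE, smoothing=NO_SMOOTH,
            motion_start_event="bolus cross the mandible angle",
        )
        # reference halfway up the ramp: signed vertical peak is -5 (downward
        # relative displacement at frame 0) or +5 at the end; magnitude 5
        v = res.summary.get("hyoid maximal displacement (vertical)").value
        assert abs(v) == pytest.approx(5.0, abs=1e-9)

    def test_frame_rate_consistency_of_peaks(self):
        # same 1 s continuous motion sampled at 30 and 60 fps
        def make(fps):
            n = int(fps) + 1
            rows = []
            for i in range(n):
                t = i / fps
                dy = 10.0 * math.sin(math.pi * t / 2.0)
                rows += [
                    (i, "c2", 100.0, 180.0), (i, "c4", 100.0, 200.0),
                    (i, "hyoid", 80.0, 190.0 - dy),
                ]
            return make_recording(rows, fps=fps)

        res30 = analyze_recording(make(30.0), UNIT_SCALE, smoothing=NO_SMOOTH)
        res60 = analyze_recording(make(60.0), UNIT_SCALE, smoothing=NO_SMOOTH)
        d30 = res30.summary.get("hyoid maximal displacement (vertical)").value
        d60 = res60.summary.get("hyoid maximal displacement (vertical)").value
        assert d30 == pytest.approx(d60, abs=10.0 * math.pi / 2 / 30)  # one-sample bound
        v30 = res30.summary.get("hyoid maximal velocity (vertical)").value
        v60 = res60.summary.get("hyoid maximal velocity (vertical)").value
        vmax = 10.0 * math.pi / 2
        assert abs(v60 - vmax) < abs(v30 - vmax) + 1e-9  # second-order convergence

    def test_interior_gap_splits_velocity_runs(self):
        rows = []
        for i in range(9):
            rows += [(i, "c2", 100.0, 180.0), (i, "c4", 100.0, 200.0)]
            if i != 4:  # hyoid invisible in frame 4
                rows += [(i, "hyoid", 80.0, 190.0 - i)]
        rec = make_recording(rows)
        res = analyze_recording(rec, UNIT_SCALE, smoothing=NO_SMOOTH)
        vel = res.series["hyoid_vel_vert_mmps"].values
        assert np.isnan(vel[4])
        assert not np.isnan(np.delete(vel, 4)).any()

    def test_missing_structure_error_has_context(self, simple_recording):
        with pytest.raises(ValueError, match="larynx"):
            analyze_recording(simple_recording, UNIT_SCALE, smoothing=NO_SMOOTH,
                              structures=["larynx"])
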