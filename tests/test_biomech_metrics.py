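"""CoP arithmetic, crutch GRF decomposition, and event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from exogait.biomech_metrics import (
    GaitEvent,
    InsoleGeometry,
    cop_from_fsr,
    cop_series,
    decompose_crutch_grf,
    decompose_series,
    detect_events_markers,
    detect_heel_strikes_fsr,
    event_rmse,
    match_events,
    stride_metrics,
)

GEOM = InsoleGeometry(heel=(0.0, 0.0), m1=(0.0, 160.0), m5=(0.0, 150.0))


class TestCop:
    def test_pure_heel_load_sits_on_heel(self):
        sample = cop_from_fsr((1.0, 0.0, 0.0), GEOM)
        assert sample.valid
        assert sample.y_cop == 0.0

    def test_weighted_average_hand_arithmetic(self):
        # (0*2 + 160*1 + 150*1) / 4
        sample = cop_from_fsr((2.0, 1.0, 1.0), GEOM)
        assert sample.y_cop == pytest.approx(77.5)

    def test_unloaded_foot_is_invalid(self):
        sample = cop_from_fsr((0.0, 0.0, 0.0), GEOM)
        assert not sample.valid and np.isnan(sample.y_cop)

    def test_below_min_total_is_invalid(self):
        assert not cop_from_fsr((1.0, 1.0, 1.0), GEOM, min_total=10.0).valid

    def test_negative_reading_rejected(self):
        with pytest.raises(ValueError):
            cop_from_fsr((-1.0, 0.0, 0.0), GEOM)

    @settings(derandomize=True, max_examples=200)
    @given(forces=st.tuples(*[st.floats(0, 1000) for _ in range(3)]))
    def test_cop_is_convex_combination_of_sensor_coordinates(self, forces):
        geom = InsoleGeometry.default("medium")
        sample = cop_from_fsr(forces, geom, min_total=1e-9)
        if sample.valid:
            ys = geom.xy[:, 1]
            assert ys.min() - 1e-9 <= sample.y_cop <= ys.max() + 1e-9
            xs = geom.xy[:, 0]
            assert xs.min() - 1e-9 <= sample.x_cop <= xs.max() + 1e-9

    def test_shifting_load_to_m1_moves_cop_toward_m1(self):
        geom = InsoleGeometry.default("medium")
        y_previous = -np.inf
        for w in np.linspace(0, 1, 11):
            sample = cop_from_fsr((1.0 - w + 1e-6, w, 0.0), geom)
            assert sample.y_cop >= y_previous
            y_previous = sample.y_cop
        assert y_previous == pytest.approx(geom.m1[1], abs=1e-2)

    def test_series_matches_scalar_path(self, rng):
        geom = InsoleGeometry.default("large")
        triplets = rng.uniform(0, 100, size=(50, 3))
        y, x, valid = cop_series(triplets, geom)
        for i in range(50):
            s = cop_from_fsr(triplets[i], geom)
            assert y[i] == pytest.approx(s.y_cop)


class TestGrfDecomposition:
    def test_identity_orientation_is_all_vertical(self):
        force = decompose_crutch_grf(100.0, (0.0, 0.0, 0.0, 1.0))
        assert force.components == pytest.approx((100.0, 0.0, 0.0))

    def test_sixty_degree_sagittal_tilt(self):
        rot = Rotation.from_euler("y", 60, degrees=True)
        force = decompose_crutch_grf(100.0, rot)
        assert force.vertical == pytest.approx(50.0, abs=0.01)
        assert force.anteroposterior == pytest.approx(86.60, abs=0.01)

    @settings(derandomize=True, max_examples=200)
    @given(axial=st.floats(0, 500),
           angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]))
    def test_norm_preserved_and_inverse_consistent(self, axial, angles):
        rot = Rotation.from_euler("xyz", angles, degrees=True)
        force = decompose_crutch_grf(axial, rot)
        world = np.array([force.anteroposterior, force.mediolateral, force.vertical])
        assert np.linalg.norm(world) == pytest.approx(abs(axial), rel=1e-9, abs=1e-9)
        assert abs(force.vertical) <= abs(axial) + 1e-9
        back = rot.inv().apply(world)
        assert back == pytest.approx([0.0, 0.0, axial], abs=1e-6 * max(1.0, axial))

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(ValueError, match="norm"):
            decompose_crutch_grf(10.0, (0.0, 0.0, 0.0, 1.01))

    def test_vectorized_series_matches_scalar(self, rng):
        axial = rng.uniform(0, 300, 20)
        quats = Rotation.from_euler(
            "xyz", rng.uniform(-30, 30, (20, 3)), degrees=True).as_quat()
        world = decompose_series(axial, quats)
        for i in range(20):
            f = decompose_crutch_grf(axial[i], quats[i])
            assert world[i] == pytest.approx(f.components, abs=1e-9)


class TestFsrEventDetection:
    @staticmethod
    def bumps(centers, rate=130.0, length=6.0, width=0.08, amp=1.0):
        t = np.arange(0, length, 1 / rate)
        x = np.zeros_like(t)
        for c in centers:
            x += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
        return t, x

    def test_two_bumps_detected_at_their_centers(self):
        t, x = self.bumps([1.0, 4.2])
        events = detect_heel_strikes_fsr(t, x, "left", min_prominence=0.5)
        assert [e.kind for e in events] == ["heel_strike"] * 2
        times = [e.time for e in events]
        assert times == pytest.approx([1.0, 4.2], abs=0.5 / 130.0)

    def test_flat_series_has_no_events(self):
        t = np.arange(0, 5, 1 / 130.0)
        assert detect_heel_strikes_fsr(t, np.zeros_like(t), "left", 0.1) == []

    def test_translation_equivariance_and_scale_invariance(self):
        t, x = self.bumps([1.5, 3.5])
        base = [e.time for e in detect_heel_strikes_fsr(t, x, "left", 0.4)]
        shifted = [e.time for e in detect_heel_strikes_fsr(t + 10.0, x, "left", 0.4)]
        scaled = [e.time for e in detect_heel_strikes_fsr(t, 7.0 * x, "left", 0.4 * 7)]
        assert shifted == pytest.approx([b + 10.0 for b in base], abs=1e-9)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_refractory_must_be_positive(self):
        t, x = self.bumps([1.0])
        with pytest.raises(ValueError):
            detect_heel_strikes_fsr(t, x, "left", 0.5, refractory=0.0)

    def test_refractory_suppresses_close_double_peaks(self):
        t, x = self.bumps([2.0, 2.3])
        events = detect_heel_strikes_fsr(t, x, "left", 0.1, refractory=0.5)
        assert len(events) == 1


class TestMarkerEventDetection:
    def test_stationary_standing_has_no_events(self):
        t = np.arange(0, 5, 1 / 150.0)
        still = np.tile([0.2, 0.1, 0.0], (t.size, 1))
        sternum = np.tile([0.0, 0.0, 1.3], (t.size, 1))
        assert detect_events_markers(t, still, still, sternum, "left") == []

    def test_mismatched_lengths_rejected(self):
        t = np.arange(0, 1, 1 / 150.0)
        traj = np.zeros((t.size, 3))
        with pytest.raises(ValueError, match="lengths differ"):
            detect_events_markers(t, traj[:-1], traj, traj, "left")

    def test_known_foot_ahead_instants_recovered(self, noiseless_run):
        _, truth = noiseless_run
        mk = truth.markers
        events = detect_events_markers(truth.marker_time, mk["left_toe"],
                                       mk["left_heel"], mk["sternum"], "left")
        hs = [e.time for e in events if e.kind == "heel_strike"]
        to = [e.time for e in events if e.kind == "toe_off"]
        assert len(hs) == len(truth.heel_strikes["left"])
        assert event_rmse(hs, truth.heel_strikes["left"]) < 1 / 150.0
        assert event_rmse(to, truth.toe_offs["left"]) < 1 / 150.0

    def test_marker_and_fsr_methods_agree_on_noiseless_gait(self, noiseless_run):
        session, truth = noiseless_run
        t = truth.timestamps
        full_scale = 4095.0
        for side in ("left", "right"):
            heel = np.array([f.channels[f"{side}_insole_fsr_heel"]
                             for f in session.frames])
            fsr_times = [e.time for e in detect_heel_strikes_fsr(
                t, heel, side, 0.1 * full_scale)]
            mk = truth.markers
            marker_times = [e.time for e in detect_events_markers(
                truth.marker_time, mk[f"{side}_toe"], mk[f"{side}_heel"],
                mk["sternum"], side) if e.kind == "heel_strike"]
            pairs = match_events(fsr_times, marker_times, max_offset=0.3)
            assert len(pairs) >= len(marker_times) - 1
            assert all(abs(a - b) <= 1 / 130.0 for a, b in pairs)


class TestStrideMetrics:
    @staticmethod
    def hs(times, side="left"):
        return [GaitEvent("heel_strike", side, t, "fsr") for t in times]

    def test_durations_and_cadence_arithmetic(self):
        out = stride_metrics(self.hs([0.0, 3.33, 6.66]))
        assert out["durations"] == pytest.approx([3.33, 3.33])
        assert out["cadence"] == pytest.approx(60 / 3.33)

    def test_single_event_is_insufficient(self):
        with pytest.raises(ValueError, match="at least two"):
            stride_metrics(self.hs([1.0]))

    def test_recovers_configured_step_duration_distribution(self):
        from exogait.synthetic_gait import GaitSimConfig, simulate_session

        cfg = GaitSimConfig(n_strides=50, seed=11)
        _, truth = simulate_session(cfg)
        events = self.hs(truth.heel_strikes["right"], "right")
        out = stride_metrics(events)
        sem = 1.16 / np.sqrt(50)
        assert abs(out["mean_duration"] - 3.33) < 2 * sem
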