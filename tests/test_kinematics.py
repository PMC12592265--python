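import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from antnav import kinematics as kin
from antnav.types import InsufficientDataError, wrap_angle_deg


class TestSteps:
    def test_three_four_five_triangle(self, make_traj):
        traj = make_traj([[0, 0], [3, 4], [6, 8]])
        steps = kin.compute_steps(traj)
        np.testing.assert_allclose(steps.lengths, [5.0, 5.0])
        np.testing.assert_allclose(steps.headings, np.degrees(np.arctan2(4, 3)))

    def test_stationary_step_has_no_heading(self, make_traj):
        traj = make_traj([[1, 1], [1, 1], [2, 1]])
        steps = kin.compute_steps(traj)
        assert steps.lengths[0] == 0.0
        assert np.isnan(steps.headings[0])
        assert steps.n_zero_length == 1

    def test_lengths_match_pairwise_distance_oracle(self, make_traj, rng):
        pts = rng.normal(size=(100, 2)) * 10
        steps = kin.compute_steps(make_traj(pts))
        oracle = [np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum()) for i in range(99)]
        np.testing.assert_allclose(steps.lengths, oracle, atol=1e-12)

    def test_single_frame_rejected(self, make_traj):
        with pytest.raises(InsufficientDataError):
            kin.compute_steps(make_traj([[0, 0]]))


class TestTurningAngles:
    def test_collinear_path_turns_zero(self, make_traj):
        traj = make_traj([[i, 2 * i] for i in range(6)])
        steps = kin.compute_steps(traj)
        turns, skipped = kin.compute_turning_angles(steps.headings)
        np.testing.assert_allclose(turns, 0.0, atol=1e-12)
        assert skipped == 0

    def test_left_staircase_turns_plus_ninety(self, make_traj):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0], [1, 0]]
        steps = kin.compute_steps(make_traj(pts))
        turns, _ = kin.compute_turning_angles(steps.headings)
        np.testing.assert_allclose(turns, 90.0, atol=1e-9)

    def test_wraparound_170_to_minus170_is_plus20(self):
        turns, _ = kin.compute_turning_angles(np.array([170.0, -170.0]))
        # complex-argument oracle: arg(e^{i(h2-h1)})
        oracle = np.degrees(
            np.angle(np.exp(1j * np.radians(-170.0)) / np.exp(1j * np.radians(170.0)))
        )
        assert turns[0] == pytest.approx(20.0, abs=1e-9)
        assert turns[0] == pytest.approx(oracle, abs=1e-9)

    def test_undefined_heading_pairs_skipped_and_counted(self):
        turns, skipped = kin.compute_turning_angles(np.array([0.0, np.nan, 90.0, 45.0]))
        assert skipped == 2
        assert turns[2] == pytest.approx(-45.0)

    @given(st.lists(st.floats(-720, 720), min_size=2, max_size=30))
    def test_wrap_matches_phasor_oracle_everywhere(self, headings):
        h = np.asarray(headings)
        turns, _ = kin.compute_turning_angles(h)
        phasor = np.degrees(np.angle(np.exp(1j * np.radians(np.diff(h)))))
        ok = ~np.isnan(turns)
        assert np.all(turns[ok] > -180.0) and np.all(turns[ok] <= 180.0)
        # both conventions agree up to the boundary point -180 vs +180
        delta = wrap_angle_deg(turns[ok] - phasor[ok])
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)


class TestSpeed:
    def test_constant_speed_no_stops(self, make_traj):
        traj = make_traj([[0.4 * i, 0] for i in range(26)])  # 0.4 mm/frame @ 25fps
        speed, moving, summary = kin.compute_speed_series(traj)
        np.testing.assert_allclose(speed, 10.0)
        assert moving.all()
        assert summary.mean_speed == pytest.approx(10.0)
        assert summary.stopped_time == pytest.approx(0.0)

    def test_stop_excluded_mean_speed_arithmetic(self, make_traj):
        # 100 mm over 10 s moving, then 5 s fully stopped
        fps = 25.0
        moving_part = [[0.4 * i, 0] for i in range(251)]     # 10 s, 100 mm
        stopped_part = [[100.0, 0]] * 125                     # 5 s at rest
        traj = make_traj(moving_part + stopped_part, fps=fps)
        _, _, summary = kin.compute_speed_series(traj)
        assert summary.mean_speed == pytest.approx(10.0)
        assert summary.stopped_time == pytest.approx(5.0)
        assert summary.total_duration == pytest.approx(15.0)

    def test_random_walk_with_implanted_stops_matches_mask_oracle(self, make_traj, rng):
        pts = np.cumsum(rng.normal(0, 1.0, size=(300, 2)), axis=0)
        pts[100:140] = pts[100]   # implanted stop
        pts[200:220] = pts[200]
        traj = make_traj(pts)
        _, moving, summary = kin.compute_speed_series(traj, v_stop=0.01)
        d = np.diff(pts, axis=0)
        lengths = np.hypot(d[:, 0], d[:, 1])
        dt = np.diff(traj.t)
        mask = lengths / dt >= 0.01
        assert summary.mean_speed == pytest.approx(
            lengths[mask].sum() / dt[mask].sum(), abs=1e-12
        )
        assert summary.total_moving_time == pytest.approx(dt[mask].sum())

    def test_all_stopped_flagged_not_zero(self, make_traj):
        traj = make_traj([[5, 5]] * 10)
        _, _, summary = kin.compute_speed_series(traj)
        assert summary.all_stopped
        assert np.isnan(summary.mean_speed)

    def test_summary_identity(self, make_traj, rng):
        pts = np.cumsum(rng.normal(0, 0.8, size=(200, 2)), axis=0)
        _, _, s = kin.compute_speed_series(make_traj(pts))
        assert s.mean_speed * s.total_moving_time == pytest.approx(
            s.total_moving_distance, rel=1e-12
        )
        assert s.stopped_time + s.total_moving_time == pytest.approx(s.total_duration)


class TestOrientation:
    def test_head_above_thorax_is_ninety_degrees(self, make_traj):
        thorax = np.zeros((3, 2))
        head = np.array([[0, 2.0]] * 3)
        orient, n_undef = kin.compute_orientation_series(make_traj(thorax, head))
        np.testing.assert_allclose(orient, 90.0)
        assert n_undef == 0

    def test_coincident_points_undefined_and_counted(self, make_traj):
        thorax = np.zeros((3, 2))
        head = np.array([[1.0, 0], [0, 0], [1.0, 0]])
        orient, n_undef = kin.compute_orientation_series(make_traj(thorax, head))
        assert np.isnan(orient[1])
        assert n_undef == 1

    def test_matches_atan2_oracle(self, make_traj, rng):
        thorax = rng.normal(size=(50, 2))
        head = thorax + rng.normal(size=(50, 2))
        orient, _ = kin.compute_orientation_series(make_traj(thorax, head))
        d = head - thorax
        oracle = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        ok = ~np.isnan(orient)
        np.testing.assert_allclose(
            wrap_angle_deg(orient[ok] - oracle[ok]), 0.0, atol=1e-9
        )


class TestAngularVelocity:
    def test_constant_orientation_zero(self):
        omega, mean_abs, mean_signed = kin.compute_angular_velocity(
            np.full(20, 33.0), np.arange(20) / 25.0
        )
        assert mean_abs == 0.0 and mean_signed == 0.0

    def test_uniform_rotation_90deg_per_s_at_25fps(self):
        t = np.arange(100) / 25.0
        orient = wrap_angle_deg(90.0 * t)
        _, mean_abs, mean_signed = kin.compute_angular_velocity(orient, t)
        assert mean_abs == pytest.approx(90.0, abs=1e-9)
        assert mean_signed == pytest.approx(90.0, abs=1e-9)

    def test_oscillating_sweep_matches_unwrapped_oracle(self):
        t = np.arange(200) / 25.0
        orient = wrap_angle_deg(60.0 * np.sin(2 * np.pi * t / 1.5) + 170.0)
        omega, mean_abs, _ = kin.compute_angular_velocity(orient, t)
        unwrapped = np.unwrap(np.radians(orient))
        oracle = np.degrees(np.diff(unwrapped)) / np.diff(t)
        np.testing.assert_allclose(omega, oracle, atol=1e-9)
        assert mean_abs == pytest.approx(np.abs(oracle).mean(), abs=1e-9)


class TestInvariances:
    @given(st.floats(-180, 180))
    def test_rigid_rotation_leaves_scalars_invariant(self, phi):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 1, size=(60, 2)), axis=0)
        heads = pts + rng.normal(0, 0.5, size=(60, 2)) + [1.5, 0]
        c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        R = np.array([[c, -s], [s, c]])
        from antnav.types import Trajectory

        t = np.arange(60) / 25.0

        def traj(th, he):
            return Trajectory(t=t, head=he, thorax=th)

        a = kin.analyse(traj(pts, heads))
        b = kin.analyse(traj(pts @ R.T, heads @ R.T))
        np.testing.assert_allclose(b.steps.lengths, a.steps.lengths, atol=1e-9)
        np.testing.assert_allclose(b.turning_angles, a.turning_angles, atol=1e-9)
        np.testing.assert_allclose(b.speed, a.speed, atol=1e-9)
        assert b.mean_abs_angular_velocity == pytest.approx(
            a.mean_abs_angular_velocity, abs=1e-9
        )

    def test_time_rescaling_divides_rates_exactly(self, make_traj, rng):
        pts = np.cumsum(rng.normal(0, 1, size=(40, 2)), axis=0)
        heads = pts + [2.0, 1.0]
        k = 3.0
        a = kin.analyse(make_traj(pts, heads))
        t2 = (np.arange(40) / 25.0) * k
        b = kin.analyse(make_traj(pts, heads, t=t2))
        np.testing.assert_allclose(b.speed, a.speed / k, rtol=1e-12)
        np.testing.assert_allclose(b.angular_velocity, a.angular_velocity / k, rtol=1e-12)
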