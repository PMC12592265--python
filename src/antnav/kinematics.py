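"""Per-frame kinematics: steps, headings, turning angles, speed, orientation.

A *step* is the thorax displacement between consecutive video frames; the
*turning angle* is the wrapped change in direction between two consecutive
steps. Speed excludes stop periods (steps whose speed falls below
``v_stop``) from both the distance and the time totals. Body orientation is
the direction of the thorax-to-head axis; its angular velocity is the
wrapped orientation change divided by the frame interval.

Undefined quantities (zero-length steps, head coincident with thorax) are
propagated as NaN and counted, never interpolated or zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InsufficientDataError, ParameterError, Trajectory, wrap_angle_deg

DEFAULT_V_STOP = 0.01  # mm/s; stop threshold on per-step speed


@dataclass
class StepSeries:
    lengths: np.ndarray      # (n-1,) mm
    headings: np.ndarray     # (n-1,) deg, NaN for zero-length steps
    dt: np.ndarray           # (n-1,) s
    n_zero_length: int


@dataclass
class SpeedSummary:
    """Stop-excluded speed accounting for one trajectory.

    ``mean_speed`` is total moving distance over total moving time; it is
    NaN (flagged via ``all_stopped``) when the ant never moves.
    """

    mean_speed: float
    total_moving_distance: float
    total_moving_time: float
    total_duration: float
    stopped_time: float
    all_stopped: bool


@dataclass
class KinematicsSeries:
    """Bundled per-step and per-frame kinematics for one trajectory."""

    t: np.ndarray
    steps: StepSeries
    turning_angles: np.ndarray   # (n-2,) deg, NaN where a heading is undefined
    n_turn_skipped: int
    speed: np.ndarray            # (n-1,) mm/s per step
    moving: np.ndarray           # (n-1,) bool per step
    speed_summary: SpeedSummary
    orientation: np.ndarray      # (n,) deg, NaN where head == thorax
    n_orientation_undefined: int
    angular_velocity: np.ndarray  # (n-1,) deg/s, NaN where either end undefined
    mean_abs_angular_velocity: float
    mean_signed_angular_velocity: float
    thorax: np.ndarray
    v_stop: float


def compute_steps(traj: Trajectory) -> StepSeries:
    """Thorax step lengths and headings between consecutive frames."""
    if traj.n_frames < 2:
        raise InsufficientDataError("need >= 2 frames to form steps")
    d = np.diff(traj.thorax, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    zero = lengths == 0.0
    headings[zero] = np.nan
    return StepSeries(
        lengths=lengths,
        headings=wrap_angle_deg(headings),
        dt=np.diff(traj.t),
        n_zero_length=int(zero.sum()),
    )


def compute_turning_angles(headings: np.ndarray) -> tuple[np.ndarray, int]:
    """Wrapped heading changes between consecutive steps.

    Returns the (n_steps - 1,) turning-angle array in (-180, 180] with NaN
    where either heading is undefined, plus the count of skipped pairs.
    """
    headings = np.asarray(headings, dtype=float)
    if headings.size < 2:
        raise InsufficientDataError("need >= 2 step headings for turning angles")
    turns = wrap_angle_deg(np.diff(headings))
    skipped = int(np.isnan(turns).sum())
    if skipped == turns.size:
        raise InsufficientDataError("no consecutive pair of defined headings")
    return turns, skipped


def compute_speed_series(
    traj: Trajectory, v_stop: float = DEFAULT_V_STOP
) -> tuple[np.ndarray, np.ndarray, SpeedSummary]:
    """Per-step speed, moving flags, and the stop-excluded summary.

    A step is *stopped* when its speed falls below ``v_stop``; stopped
    steps contribute to neither the distance nor the time total of
    ``mean_speed``, but they do count toward ``total_duration``.
    """
    if v_stop < 0:
        raise ParameterError("v_stop must be >= 0")
    steps = compute_steps(traj)
    speed = steps.lengths / steps.dt
    moving = speed >= v_stop
    moving_dist = float(steps.lengths[moving].sum())
    moving_time = float(steps.dt[moving].sum())
    total = float(traj.t[-1] - traj.t[0])
    all_stopped = not moving.any()
    mean_speed = np.nan if all_stopped else moving_dist / moving_time
    summary = SpeedSummary(
        mean_speed=mean_speed,
        total_moving_distance=moving_dist,
        total_moving_time=moving_time,
        total_duration=total,
        stopped_time=total - moving_time,
        all_stopped=all_stopped,
    )
    return speed, moving, summary


def compute_orientation_series(traj: Trajectory) -> tuple[np.ndarray, int]:
    """Body-axis direction (thorax -> head) per frame, degrees.

    Frames where the two tracked points coincide get NaN (counted, not
    interpolated).
    """
    d = traj.head - traj.thorax
    degenerate = (d[:, 0] == 0.0) & (d[:, 1] == 0.0)
    if degenerate.all():
        raise InsufficientDataError("head coincides with thorax in every frame")
    orient = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    orient[degenerate] = np.nan
    return wrap_angle_deg(orient), int(degenerate.sum())


def compute_angular_velocity(
    orientations: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Orientation angular velocity: wrapped orientation change over time.

    Returns the per-interval series (deg/s, NaN where either orientation
    is undefined), the mean magnitude, and the signed mean.
    """
    orientations = np.asarray(orientations, dtype=float)
    times = np.asarray(times, dtype=float)
    if orientations.size < 2:
        raise InsufficientDataError("need >= 2 orientations")
    omega = wrap_angle_deg(np.diff(orientations)) / np.diff(times)
    valid = ~np.isnan(omega)
    if not valid.any():
        raise InsufficientDataError("no consecutive pair of defined orientations")
    return omega, float(np.abs(omega[valid]).mean()), float(omega[valid].mean())


def analyse(traj: Trajectory, v_stop: float = DEFAULT_V_STOP) -> KinematicsSeries:
    """Full kinematic decomposition of one trajectory."""
    if traj.n_frames < 3:
        raise InsufficientDataError("need >= 3 frames for kinematic analysis")
    steps = compute_steps(traj)
    turns, n_skipped = compute_turning_angles(steps.headings)
    speed, moving, summary = compute_speed_series(traj, v_stop=v_stop)
    orient, n_undef = compute_orientation_series(traj)
    omega, mean_abs, mean_signed = compute_angular_velocity(orient, traj.t)
    return KinematicsSeries(
        t=traj.t,
        steps=steps,
        turning_angles=turns,
        n_turn_skipped=n_skipped,
        speed=speed,
        moving=moving,
        speed_summary=summary,
        orientation=orient,
        n_orientation_undefined=n_undef,
        angular_velocity=omega,
        mean_abs_angular_velocity=mean_abs,
        mean_signed_angular_velocity=mean_signed,
        thorax=traj.thorax,
        v_stop=v_stop,
    )
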