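"""End-to-end per-ant summaries: one tidy row per trajectory.

Glue over the analysis modules: kinematics -> straightness indices ->
scan-bout detection -> route outcome, producing the per-ant metrics table
that the statistics layer consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import events, kinematics, path_metrics, routes
from .types import ArenaGeometry, Trajectory

logger = logging.getLogger(__name__)

#: Metric columns the statistics layer compares by default.
DEFAULT_METRICS = (
    "sinuosity",
    "e_a_max",
    "mean_speed",
    "mean_abs_angular_velocity",
    "duration",
    "n_scan_bouts",
    "mean_scan_duration",
)


@dataclass(frozen=True)
class Thresholds:
    """All tunable detection thresholds, logged with every run."""

    v_stop: float = kinematics.DEFAULT_V_STOP
    r_max: float = events.DEFAULT_R_MAX
    theta_min: float = events.DEFAULT_THETA_MIN
    min_dur: float = events.DEFAULT_MIN_DUR
    gap_merge: float = events.DEFAULT_GAP_MERGE
    d_app: float = routes.DEFAULT_D_APP

    def log(self) -> None:
        logger.info("analysis thresholds: %s", self)


def summarise_trajectory(
    traj: Trajectory,
    arena: ArenaGeometry | None = None,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """All per-ant summary metrics for one trajectory as a flat record."""
    kin = kinematics.analyse(traj, v_stop=thresholds.v_stop)
    pm = path_metrics.summarise(kin)
    bouts = events.detect_scan_bouts(
        kin,
        r_max=thresholds.r_max,
        theta_min=thresholds.theta_min,
        min_dur=thresholds.min_dur,
        gap_merge=thresholds.gap_merge,
    )
    n_bouts, durations = events.scan_summary(bouts)
    row = {
        "ant_id": traj.ant_id,
        "condition": traj.condition,
        "session": traj.session,
        "p": pm.p,
        "c": pm.c,
        "b": pm.b,
        "sinuosity": pm.sinuosity,
        "e_a_max": pm.e_a_max,
        "mean_speed": kin.speed_summary.mean_speed,
        "mean_abs_angular_velocity": kin.mean_abs_angular_velocity,
        "n_scan_bouts": n_bouts,
        "total_scan_duration": sum(durations),
        "mean_scan_duration": sum(durations) / n_bouts if n_bouts else 0.0,
        "n_steps": pm.n_steps,
        "flags": ";".join(pm.flags),
    }
    if arena is not None:
        row["duration"] = path_metrics.trip_duration(traj, arena)
        outcome = routes.classify_route(traj, arena, d_app=thresholds.d_app)
        row["route"] = outcome.category
    else:
        row["duration"] = float(traj.t[-1] - traj.t[0])
        row["route"] = ""
    return row


def summarise_batch(
    trajectories: list[Trajectory],
    arena: ArenaGeometry | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-ant metrics table for a batch of trajectories."""
    thresholds.log()
    return pd.DataFrame([summarise_trajectory(tr, arena, thresholds) for tr in trajectories])
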