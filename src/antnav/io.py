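"""Trajectory and metrics table I/O.

Trajectory files are comma-separated text with a header row: the four
coordinate columns ``head_x, head_y, thorax_x, thorax_y`` are mandatory;
a ``frame`` or ``t`` column is optional (absent, time = row index /
frame_rate). Point-tracker exports with different column names are
supported through ``column_map``. Rows with any unparseable coordinate
are dropped and counted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DEFAULT_FRAME_RATE,
    InsufficientDataError,
    Trajectory,
    TrajectoryFormatError,
)

logger = logging.getLogger(__name__)

COORD_COLUMNS = ("head_x", "head_y", "thorax_x", "thorax_y")


def read_trajectory(
    path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    column_map: dict[str, str] | None = None,
    scale: float = 1.0,
    ant_id: str = "",
    condition: str = "",
    session: str = "",
) -> Trajectory:
    """Read one ant run from a CSV table.

    ``column_map`` maps required names to the file's column names, e.g.
    ``{"head_x": "pt1_cam1_X"}`` for multi-point tracker exports.
    ``scale`` multiplies all coordinates (pixel-to-mm calibration is the
    caller's responsibility).
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in COORD_COLUMNS:
        if col not in df.columns:
            raise TrajectoryFormatError(f"missing mandatory column {col!r}")

    coords = df[list(COORD_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    for col in COORD_COLUMNS:
        if len(df) and coords[col].isna().all() and df[col].notna().any():
            raise TrajectoryFormatError(f"column {col!r} is entirely non-numeric")
    valid = coords.notna().all(axis=1)
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropped %d rows with unparseable coordinates from %s", dropped, path)
    coords = coords[valid]
    if len(coords) < 3:
        raise InsufficientDataError(
            f"{path}: only {len(coords)} valid rows; need >= 3"
        )

    if "t" in df.columns:
        t = pd.to_numeric(df.loc[valid, "t"], errors="coerce").to_numpy(float)
    elif "frame" in df.columns:
        frames = pd.to_numeric(df.loc[valid, "frame"], errors="coerce").to_numpy(float)
        t = frames / frame_rate
    else:
        t = np.flatnonzero(valid.to_numpy()) / frame_rate
    if np.isnan(t).any():
        raise TrajectoryFormatError(f"{path}: unparseable time/frame values")

    head = coords[["head_x", "head_y"]].to_numpy(float) * scale
    thorax = coords[["thorax_x", "thorax_y"]].to_numpy(float) * scale
    return Trajectory(
        t=t, head=head, thorax=thorax, frame_rate=frame_rate,
        ant_id=ant_id or Path(path).stem, condition=condition, session=session,
        dropped_rows=dropped,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in the same CSV dialect the reader consumes."""
    frames = np.round(traj.t * traj.frame_rate).astype(int)
    df = pd.DataFrame(
        {
            "frame": frames,
            "head_x": traj.head[:, 0],
            "head_y": traj.head[:, 1],
            "thorax_x": traj.thorax[:, 0],
            "thorax_y": traj.thorax[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_metrics_table(records: list[dict], path) -> None:
    """Write per-ant metric summaries as CSV, one row per ant.

    An empty record list yields a header-only table (standard summary
    columns). Values round-trip losslessly through
    :func:`read_metrics_table`.
    """
    df = pd.DataFrame.from_records(records)
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "ant_id", "condition", "session", "p", "c", "b",
                "sinuosity", "e_a_max", "mean_speed",
                "mean_abs_angular_velocity", "duration", "n_scan_bouts",
                "total_scan_duration", "n_steps", "flags",
            ]
        )
    df.to_csv(path, index=False, float_format="%.17g")


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TrajectoryFormatError(f"{path}: config must be a mapping")
    return cfg
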