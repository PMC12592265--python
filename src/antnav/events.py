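"""Scanning-bout detection.

A scanning bout is an episode in which the ant stops walking and rotates
on the spot through successive head fixations. Operationally a bout is a
maximal interval of stopped steps (speed below the stop threshold) during
which the thorax stays within ``r_max`` of the interval centroid and the
cumulative magnitude of body-orientation change reaches at least
``theta_min``, lasting at least ``min_dur`` seconds. Stopped intervals
separated by less than ``gap_merge`` seconds are merged before the
criteria are applied.

The defaults (r_max = 5 mm, theta_min = 45 deg, min_dur = 0.4 s,
gap_merge = 0.2 s) are package choices tuned for robustness on 25 fps
two-point tracks; every threshold is configurable and is logged with the
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicsSeries
from .types import wrap_angle_deg

logger = logging.getLogger(__name__)

DEFAULT_R_MAX = 5.0       # mm, max thorax excursion from bout centroid
DEFAULT_THETA_MIN = 45.0  # deg, min cumulative |orientation change|
DEFAULT_MIN_DUR = 0.4     # s
DEFAULT_GAP_MERGE = 0.2   # s
_MIN_ORIENT_FRACTION = 0.8  # required fraction of defined orientations


@dataclass
class ScanBout:
    start_t: float
    end_t: float
    duration: float
    location: tuple[float, float]   # mean thorax position, mm
    total_sweep: float              # cumulative |orientation change|, deg
    n_fixations: int                # head-sweep direction reversals + 1


def _stopped_runs(moving: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of stopped steps as (first_step, last_step) index pairs."""
    stopped = ~np.asarray(moving, dtype=bool)
    if not stopped.any():
        return []
    edges = np.flatnonzero(np.diff(stopped.astype(int)))
    starts = [0] if stopped[0] else []
    starts += [int(i) + 1 for i in edges if stopped[i + 1]]
    ends = [int(i) for i in edges if stopped[i]]
    if stopped[-1]:
        ends.append(stopped.size - 1)
    return list(zip(starts, ends))


def _count_fixations(orient: np.ndarray) -> int:
    """Fixations = head-sweep direction reversals + 1 over the bout."""
    d = wrap_angle_deg(np.diff(orient[~np.isnan(orient)]))
    d = d[np.abs(d) > 1e-6]
    if d.size == 0:
        return 1
    signs = np.sign(d)
    return int((np.diff(signs) != 0).sum()) + 1


def detect_scan_bouts(
    kin: KinematicsSeries,
    r_max: float = DEFAULT_R_MAX,
    theta_min: float = DEFAULT_THETA_MIN,
    min_dur: float = DEFAULT_MIN_DUR,
    gap_merge: float = DEFAULT_GAP_MERGE,
) -> list[ScanBout]:
    """Detect scanning bouts in one trajectory's kinematics.

    Returns bouts ordered by start time; the list is empty when the ant
    never pauses long enough or never sweeps widely enough. Candidate
    intervals with too many undefined orientations are skipped with a
    warning rather than guessed at.
    """
    t = kin.t
    runs = _stopped_runs(kin.moving)
    if not runs:
        return []

    # merge stopped runs separated by < gap_merge seconds
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1] + 1] < gap_merge:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    bouts: list[ScanBout] = []
    for s, e in merged:
        # step run [s, e] spans frames s .. e+1
        frames = slice(s, e + 2)
        duration = float(t[e + 1] - t[s])
        if duration < min_dur:
            continue
        thorax = kin.thorax[frames]
        centroid = thorax.mean(axis=0)
        if np.hypot(*(thorax - centroid).T).max() > r_max:
            continue
        orient = kin.orientation[frames]
        defined = ~np.isnan(orient)
        if defined.mean() < _MIN_ORIENT_FRACTION:
            logger.warning(
                "skipping candidate bout at t=%.2f s: %.0f%% orientations undefined",
                t[s], 100 * (1 - defined.mean()),
            )
            continue
        sweep = float(np.abs(wrap_angle_deg(np.diff(orient[defined]))).sum())
        if sweep < theta_min:
            continue
        bouts.append(
            ScanBout(
                start_t=float(t[s]),
                end_t=float(t[e + 1]),
                duration=duration,
                location=(float(centroid[0]), float(centroid[1])),
                total_sweep=sweep,
                n_fixations=_count_fixations(orient),
            )
        )
    return bouts


def scan_summary(bouts: list[ScanBout]) -> tuple[int, list[float]]:
    """Bout count and the full per-bout duration list for one trip."""
    return len(bouts), [b.duration for b in bouts]
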