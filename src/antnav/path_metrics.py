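"""Path straightness indices: sinuosity and maximum expected displacement.

Sinuosity follows the Benhamou-style tortuosity estimator

    S = 2 [ p ( (1 + c) / (1 - c) + b^2 ) ]^(-1/2)

with p the mean step length (mm), c the mean cosine of turning angles and
b the coefficient of variation of step lengths. Higher S means a more
convoluted path; S carries units of length^(-1/2) at frame-level steps.

The maximum expected displacement of a correlated random walk,
E^a_max = beta / (1 - beta) with beta the mean cosine of turning angles,
is the asymptotic straightness in units of steps: larger values mean
straighter paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import KinematicsSeries
from .types import ArenaGeometry, InsufficientDataError, Trajectory

_EPS = 1e-9


@dataclass
class PathMetrics:
    """Straightness summary for one trajectory.

    ``c`` and ``beta`` are the same sample quantity (mean cosine of
    turning angles), computed once. ``flags`` records degeneracies
    ("straight" when c >= 1 - eps, "reversal" when c <= -1 + eps) instead
    of raising, so batch tables never abort.
    """

    p: float          # mean step length, mm
    c: float          # mean cosine of turning angles
    b: float          # CV of step length (population-style sd, ddof=0)
    sinuosity: float
    beta: float
    e_a_max: float
    n_steps: int
    n_turns: int
    flags: tuple[str, ...] = ()


def _pcb(step_lengths: np.ndarray, turning_angles: np.ndarray):
    steps = np.asarray(step_lengths, dtype=float)
    turns = np.asarray(turning_angles, dtype=float)
    turns = turns[~np.isnan(turns)]
    if steps.size < 2:
        raise InsufficientDataError("need >= 2 steps")
    if turns.size < 1:
        raise InsufficientDataError("need >= 1 defined turning angle")
    p = float(steps.mean())
    c = float(np.cos(np.radians(turns)).mean())
    b = float(steps.std(ddof=0) / p) if p > 0 else np.nan
    return p, c, b, steps.size, turns.size


def sinuosity(step_lengths: np.ndarray, turning_angles: np.ndarray) -> PathMetrics:
    """Sinuosity S with its intermediates (p, c, b) from one trajectory.

    Degenerate straight paths (c -> 1) return S = 0 with a ``"straight"``
    flag; near-perfect reversals are flagged ``"reversal"``.
    """
    p, c, b, n_steps, n_turns = _pcb(step_lengths, turning_angles)
    flags: list[str] = []
    if c >= 1.0 - _EPS:
        flags.append("straight")
        s = 0.0
    else:
        if c <= -1.0 + _EPS:
            flags.append("reversal")
        base = p * ((1.0 + c) / (1.0 - c) + b * b)
        s = math.inf if base <= 0.0 else 2.0 * base**-0.5
    e = math.inf if c >= 1.0 - _EPS else c / (1.0 - c)
    return PathMetrics(
        p=p, c=c, b=b, sinuosity=s, beta=c, e_a_max=e,
        n_steps=n_steps, n_turns=n_turns, flags=tuple(flags),
    )


def emax(turning_angles: np.ndarray) -> float:
    """Maximum expected displacement beta / (1 - beta), in steps.

    Returns +inf for a perfectly straight path (beta -> 1).
    """
    turns = np.asarray(turning_angles, dtype=float)
    turns = turns[~np.isnan(turns)]
    if turns.size < 1:
        raise InsufficientDataError("need >= 1 defined turning angle")
    beta = float(np.cos(np.radians(turns)).mean())
    if beta >= 1.0 - _EPS:
        return math.inf
    return beta / (1.0 - beta)


def trip_duration(traj: Trajectory, arena: ArenaGeometry) -> float:
    """Time spent in the recording area: last in-arena frame minus first.

    Stops are included; this is distinct from the stop-excluded moving
    time of the speed summary.
    """
    inside = arena.contains(traj.thorax)
    if not inside.any():
        raise InsufficientDataError("trajectory never enters the arena")
    idx = np.flatnonzero(inside)
    return float(traj.t[idx[-1]] - traj.t[idx[0]])


def summarise(kin: KinematicsSeries) -> PathMetrics:
    """PathMetrics from an already-computed kinematics series."""
    return sinuosity(kin.steps.lengths, kin.turning_angles)
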