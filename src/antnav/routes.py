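"""Route-outcome classification against the odour band.

Each upward trip is classified by how it interacts with the horizontal
odour strip: *walked_over* (a contiguous bottom-to-top passage through the
band's vertical span while horizontally inside the band), *detour*
(reaches above the band but every passage happens horizontally beyond the
band's x-extent), *u_turn* (approaches the band from below, never gets
above it, and returns down out of the arena), or *incomplete* (the
recording ends before any of these resolve). Incomplete trips are
excluded from frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .types import ArenaGeometry, BandRect, InsufficientDataError, Trajectory

DEFAULT_D_APP = 100.0  # mm; approach distance below the band defining a "response"
CATEGORIES = ("walked_over", "detour", "u_turn", "incomplete")
# A passage straddling a band edge counts as walked_over when the thorax is
# horizontally inside the band for at least this fraction of span frames.
INSIDE_FRACTION = 0.5


@dataclass
class RouteOutcome:
    category: str
    first_encounter_t: float | None   # s; first frame within d_app below the band
    crossing_x: float | None          # mm; mean x during the walked-over passage
    max_y_reached: float              # mm
    ant_id: str = ""
    condition: str = ""
    session: str = ""


def _transits(y: np.ndarray, y_min: float, y_max: float) -> list[tuple[int, int]]:
    """Contiguous bottom-to-top passages as (enter, exit) frame indices.

    A transit starts when the path rises from below y_min into the band's
    vertical span and completes when it first exceeds y_max without having
    dropped back below y_min in between.
    """
    out: list[tuple[int, int]] = []
    in_transit = False
    start = 0
    below = y[0] < y_min
    for i in range(1, y.size):
        if in_transit:
            if y[i] > y_max:
                out.append((start, i))
                in_transit = False
                below = False
            elif y[i] < y_min:
                in_transit = False
                below = True
        elif below and y[i] >= y_min:
            in_transit = True
            start = i
        if y[i] < y_min:
            below = True
        elif y[i] > y_max:
            below = False
    return out


def classify_route(
    traj: Trajectory,
    arena: ArenaGeometry,
    band: BandRect | None = None,
    d_app: float = DEFAULT_D_APP,
) -> RouteOutcome:
    """Classify one trajectory's interaction with the odour band."""
    band = band if band is not None else arena.band
    inside_arena = arena.contains(traj.thorax)
    if not inside_arena.any():
        raise InsufficientDataError("trajectory never enters the arena")
    x = traj.thorax[:, 0]
    y = traj.thorax[:, 1]

    approach = y >= band.y_min - d_app
    first_enc = float(traj.t[np.argmax(approach)]) if approach.any() else None
    max_y = float(y.max())

    crossing_x: float | None = None
    any_inside = False
    for enter, exit_ in _transits(y, band.y_min, band.y_max):
        span = slice(enter, exit_)  # frames with y inside the vertical span
        span_x = x[span]
        if span_x.size == 0:  # single-frame jump across the whole span
            span_x = x[enter - 1 : exit_ + 1]
        frac = np.mean((span_x >= band.x_min) & (span_x <= band.x_max))
        if frac >= INSIDE_FRACTION:
            any_inside = True
            if crossing_x is None:
                crossing_x = float(span_x.mean())

    reached_above = max_y > band.y_max
    first_y = float(y[np.argmax(inside_arena)])
    if reached_above and any_inside:
        category = "walked_over"
    elif reached_above:
        category = "detour"
        crossing_x = None
    elif (
        max_y >= band.y_min - d_app
        and y[-1] <= min(first_y, band.y_min - d_app)
    ):
        category = "u_turn"
    else:
        category = "incomplete"

    return RouteOutcome(
        category=category,
        first_encounter_t=first_enc,
        crossing_x=crossing_x,
        max_y_reached=max_y,
        ant_id=traj.ant_id,
        condition=traj.condition,
        session=traj.session,
    )


def outcome_frequencies(
    outcomes: list[RouteOutcome], confidence: float = 0.95
) -> dict[str, dict[str, float]]:
    """Per-category proportions with exact (Clopper-Pearson) intervals.

    Incomplete trips are dropped from the denominator; the returned
    proportions sum to 1 over the classified categories.
    """
    classified = [o for o in outcomes if o.category != "incomplete"]
    if not classified:
        raise InsufficientDataError("no classified (complete) trajectories")
    n = len(classified)
    freqs: dict[str, dict[str, float]] = {}
    for cat in ("walked_over", "detour", "u_turn"):
        k = sum(o.category == cat for o in classified)
        ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
        freqs[cat] = {
            "count": float(k),
            "n": float(n),
            "proportion": k / n,
            "ci_low": float(ci.low),
            "ci_high": float(ci.high),
        }
    return freqs
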