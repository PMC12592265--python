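"""Synthetic two-point trajectory generator with known ground truth.

Thorax paths are correlated random walks: gamma-distributed step lengths
(mean ``mean_step``, coefficient of variation ``step_cv``) and
wrapped-normal turning angles whose concentration is parameterised by the
target mean cosine c* in [0, 1). The head point sits ``head_offset`` mm
ahead of the thorax along the body axis, which oscillates sinusoidally
about the walking direction the way an ant's head sweeps left and right.

Foragers add goal direction: the heading update blends the CRW turn with
attraction toward a waypoint, and a behaviour script implants stop
episodes, scanning bouts (thorax frozen, body axis sweeping) and one of
three responses to the odour band — cross it, detour laterally around
it, or U-turn back down. Every implanted event and the response mode are
returned as ground truth so detector and classifier recovery can be
scored exactly.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import ArenaGeometry, ParameterError, ScriptError, Trajectory, wrap_angle_deg

_WALL_MARGIN = 5.0       # mm kept off the lateral arena edges (reflecting walls)
_WAYPOINT_CAPTURE = 25.0  # mm; a waypoint counts as reached within this radius


@dataclass(frozen=True)
class CRWParams:
    """Correlated-random-walk parameters (per-frame steps at ``frame_rate``)."""

    mean_step: float = 1.2          # mm; p*
    step_cv: float = 0.3            # b*
    turn_concentration: float = 0.9  # target mean cosine of turning angles, c*
    drift_direction: float = 90.0   # deg; +y is up the trunk
    drift_weight: float = 0.0       # 0 = pure CRW; >0 blends goal attraction
    frame_rate: float = 25.0
    head_offset: float = 2.5        # mm, thorax -> head-tip distance
    head_osc_amplitude: float = 15.0  # deg, walking head sweep
    head_osc_period: float = 0.5    # s

    def __post_init__(self) -> None:
        if self.mean_step <= 0 or self.head_offset <= 0:
            raise ParameterError("mean_step and head_offset must be positive")
        if not 0.0 <= self.turn_concentration < 1.0:
            raise ParameterError("turn_concentration c* must lie in [0, 1)")
        if self.step_cv < 0 or not 0.0 <= self.drift_weight <= 1.0:
            raise ParameterError("step_cv >= 0 and drift_weight in [0, 1] required")

    @property
    def turn_sigma(self) -> float:
        """Wrapped-normal sigma (radians) giving mean cosine c*."""
        c = self.turn_concentration
        return math.inf if c == 0.0 else math.sqrt(-2.0 * math.log(c))


@dataclass(frozen=True)
class StopEpisode:
    start_t: float
    duration: float


@dataclass(frozen=True)
class ScanEpisode:
    start_t: float
    duration: float
    sweep_amplitude: float = 75.0  # deg


@dataclass(frozen=True)
class BehaviourScript:
    """Implanted events and odour-band response for one forager."""

    response_mode: str = "cross"   # cross | detour | u_turn
    stops: tuple[StopEpisode, ...] = ()
    scans: tuple[ScanEpisode, ...] = ()

    def __post_init__(self) -> None:
        if self.response_mode not in ("cross", "detour", "u_turn"):
            raise ScriptError(f"unknown response mode {self.response_mode!r}")
        episodes = sorted(
            [(e.start_t, e.start_t + e.duration) for e in self.stops + self.scans]
        )
        for (_, e0), (s1, _) in zip(episodes, episodes[1:]):
            if s1 < e0:
                raise ScriptError("behaviour episodes overlap")


def _draw_turns(rng, sigma: float, n: int) -> np.ndarray:
    """Turning angles in radians: wrapped normal, or uniform when c* = 0."""
    if math.isinf(sigma):
        return rng.uniform(-math.pi, math.pi, n)
    return rng.normal(0.0, sigma, n)


def _draw_steps(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, mean / shape, n)


def _head_from(thorax, orient_deg, offset):
    rad = np.radians(orient_deg)
    return thorax + offset * np.column_stack([np.cos(rad), np.sin(rad)])


def simulate_crw(
    params: CRWParams,
    n_steps: int,
    seed: int,
    start: tuple[float, float] = (0.0, 0.0),
) -> tuple[Trajectory, dict]:
    """Pure correlated random walk (no waypoints, no implanted events).

    Returns the two-point trajectory and a ground-truth record holding the
    population parameters (p*, c*, b*, turn sigma) actually used.
    """
    if n_steps < 2:
        raise ParameterError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    turns = _draw_turns(rng, params.turn_sigma, n_steps - 1)
    lengths = _draw_steps(rng, params.mean_step, params.step_cv, n_steps)
    h0 = math.radians(params.drift_direction)
    headings = h0 + np.concatenate([[0.0], np.cumsum(turns)])
    disp = lengths[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    thorax = np.vstack([start, start + np.cumsum(disp, axis=0)])
    t = np.arange(n_steps + 1) / params.frame_rate

    step_orient = np.degrees(headings)
    orient = np.concatenate([step_orient, step_orient[-1:]])
    phase = rng.uniform(0.0, 2.0 * math.pi)
    orient = orient + params.head_osc_amplitude * np.sin(
        2.0 * math.pi * t / params.head_osc_period + phase
    )
    head = _head_from(thorax, orient, params.head_offset)
    traj = Trajectory(t=t, head=head, thorax=thorax, frame_rate=params.frame_rate)
    truth = {
        "p_star": params.mean_step,
        "c_star": params.turn_concentration,
        "b_star": params.step_cv,
        "turn_sigma": params.turn_sigma,
        "drift_weight": 0.0,
        "seed": seed,
        "events": [],
        "response_mode": None,
    }
    return traj, truth


def _waypoints(mode: str, arena: ArenaGeometry, x0: float, rng) -> list[tuple[float, float]]:
    band = arena.band
    top_exit_y = arena.height + 60.0
    if mode == "cross":
        xc = min(max(x0, band.x_min + 60.0), band.x_max - 60.0)
        return [(xc, band.y_min - 60.0), (xc, top_exit_y)]
    if mode == "detour":
        left_room = band.x_min
        right_room = arena.width - band.x_max
        go_left = (left_room > right_room) or (
            left_room == right_room and rng.random() < 0.5
        )
        dx = 0.5 * band.x_min if go_left else 0.5 * (band.x_max + arena.width)
        return [
            (dx, band.y_min - 40.0),
            (dx, band.y_max + 60.0),
            (x0, top_exit_y),
        ]
    # u_turn: approach below the band, then return down and out the bottom
    return [(x0, arena.band.y_min - 60.0), (x0 + rng.uniform(-40, 40), -60.0)]


def _base_forager_path(
    params: CRWParams, mode: str, arena: ArenaGeometry, rng, max_frames: int
):
    """Waypoint-following CRW thorax path; returns (thorax, step headings deg)."""
    w = params.drift_weight if params.drift_weight > 0 else 0.35
    x = arena.width / 2.0 + rng.uniform(-50.0, 50.0)
    y = 15.0
    waypoints = _waypoints(mode, arena, x, rng)
    turns = _draw_turns(rng, params.turn_sigma, max_frames)
    lengths = _draw_steps(rng, params.mean_step, params.step_cv, max_frames)
    wp_i = 0
    tx, ty = waypoints[0]
    heading = math.atan2(ty - y, tx - x)
    xs = [x]
    ys = [y]
    head_dirs: list[float] = []
    lo, hi = _WALL_MARGIN, arena.width - _WALL_MARGIN
    for i in range(max_frames):
        target = math.atan2(ty - y, tx - x)
        err = math.atan2(math.sin(target - heading), math.cos(target - heading))
        heading = heading + w * err + turns[i]
        x += lengths[i] * math.cos(heading)
        y += lengths[i] * math.sin(heading)
        # lateral walls reflect (the forager stays in its corridor);
        # only the top/bottom edges end the recording
        if x < lo:
            x = 2.0 * lo - x
            heading = math.pi - heading
        elif x > hi:
            x = 2.0 * hi - x
            heading = math.pi - heading
        xs.append(x)
        ys.append(y)
        head_dirs.append(math.degrees(heading))
        if math.hypot(tx - x, ty - y) < _WAYPOINT_CAPTURE and wp_i < len(waypoints) - 1:
            wp_i += 1
            tx, ty = waypoints[wp_i]
        if y < 0.0 or y > arena.height:
            break
    return np.column_stack([xs, ys]), np.asarray(head_dirs)


def simulate_forager(
    params: CRWParams,
    script: BehaviourScript,
    arena: ArenaGeometry,
    seed: int,
    max_frames: int = 6000,
) -> tuple[Trajectory, dict]:
    """Upward-drifting forager executing a behaviour script in the arena.

    Episode start times refer to the final (post-implantation) timeline.
    Raises :class:`ScriptError` if an episode starts after the trajectory
    has already left the arena.
    """
    rng = np.random.default_rng(seed)
    fps = params.frame_rate
    thorax, step_dirs = _base_forager_path(params, script.response_mode, arena, rng, max_frames)

    # walking orientation: outgoing step heading + sinusoidal head sweep
    orient = np.concatenate([step_dirs, step_dirs[-1:]])
    phase = rng.uniform(0.0, 2.0 * math.pi)
    tt = np.arange(orient.size) / fps
    orient = orient + params.head_osc_amplitude * np.sin(
        2.0 * math.pi * tt / params.head_osc_period + phase
    )

    thorax_l = [thorax[i] for i in range(thorax.shape[0])]
    orient_l = list(orient)
    events: list[dict] = []
    episodes = sorted(
        [("stop", e) for e in script.stops] + [("scan", e) for e in script.scans],
        key=lambda kv: kv[1].start_t,
    )
    for kind, ep in episodes:
        idx = int(round(ep.start_t * fps))
        m = max(1, int(round(ep.duration * fps)))
        if idx >= len(thorax_l):
            raise ScriptError(
                f"{kind} episode at t={ep.start_t:.2f}s starts after trajectory end"
            )
        frozen = thorax_l[idx]
        base = orient_l[idx]
        if kind == "stop":
            new_orient = [base] * m
        else:
            n_cyc = max(1.0, round(ep.duration * 1.25))
            k = np.arange(m)
            new_orient = list(
                base + ep.sweep_amplitude * np.sin(2.0 * math.pi * n_cyc * k / m)
            )
        thorax_l[idx:idx] = [frozen] * m
        orient_l[idx:idx] = new_orient
        events.append(
            {
                "kind": kind,
                "start_t": idx / fps,
                "end_t": (idx + m) / fps,
                "duration": m / fps,
                "sweep_amplitude": getattr(ep, "sweep_amplitude", 0.0),
            }
        )

    thorax = np.asarray(thorax_l)
    orient = np.asarray(orient_l)
    t = np.arange(thorax.shape[0]) / fps
    head = _head_from(thorax, orient, params.head_offset)
    traj = Trajectory(t=t, head=head, thorax=thorax, frame_rate=fps)
    truth = {
        "p_star": params.mean_step,
        "c_star": params.turn_concentration,
        "b_star": params.step_cv,
        "turn_sigma": params.turn_sigma,
        "drift_weight": params.drift_weight if params.drift_weight > 0 else 0.35,
        "seed": seed,
        "events": sorted(events, key=lambda e: e["start_t"]),
        "response_mode": script.response_mode,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# experiment-level generation

@dataclass(frozen=True)
class ConditionProfile:
    """Per-condition generator settings for an experiment design."""

    params: CRWParams = field(default_factory=CRWParams)
    scan_rate: float = 0.5            # mean implanted scans per trip (Poisson)
    stop_rate: float = 0.5            # mean implanted plain stops per trip
    mode_mixture: tuple[float, float, float] = (1.0, 0.0, 0.0)  # cross/detour/u_turn

    def __post_init__(self) -> None:
        if abs(sum(self.mode_mixture) - 1.0) > 1e-9 or min(self.mode_mixture) < 0:
            raise ParameterError("mode_mixture must be a probability vector")


def _profile(c_star, mean_step, scan_rate, mixture, stop_rate=0.5) -> ConditionProfile:
    return ConditionProfile(
        params=CRWParams(mean_step=mean_step, turn_concentration=c_star),
        scan_rate=scan_rate,
        stop_rate=stop_rate,
        mode_mixture=mixture,
    )


#: Baseline foraging: straight, brisk ascent, rare scanning, crossing the band.
CONTROL_PROFILE = _profile(0.95, 1.6, 0.5, (1.0, 0.0, 0.0))

#: Odour-added condition: more meander, slower, frequent scanning,
#: detour-dominant response mixture.
ODOUR_EFFECT_PROFILE = {
    "control": CONTROL_PROFILE,
    "test": _profile(0.85, 1.1, 4.0, (0.35, 0.55, 0.10), stop_rate=1.5),
}

#: All conditions identical to control (type-I / null checks).
NULL_PROFILE = {"control": CONTROL_PROFILE, "test": CONTROL_PROFILE}

#: Habituation: strong shift on day 1, partial recovery day 2, near-control day 3.
HABITUATION_PROFILE = {
    "control": CONTROL_PROFILE,
    "day1": _profile(0.82, 1.15, 4.0, (0.10, 0.70, 0.20), stop_rate=1.5),
    "day2": _profile(0.89, 1.35, 2.0, (0.40, 0.55, 0.05)),
    "day3": _profile(0.94, 1.55, 1.0, (0.80, 0.20, 0.00)),
}

_SUBJECT_STEP_SD = 0.06   # per-subject random intercept, log mean step
_SUBJECT_C_SD = 0.012     # per-subject random intercept on c*


def _auto_script(profile: ConditionProfile, mode: str, rng) -> BehaviourScript:
    """Random non-overlapping stop/scan episodes early in the trip."""
    n_scans = int(rng.poisson(profile.scan_rate))
    n_stops = int(rng.poisson(profile.stop_rate))
    n_total = n_scans + n_stops
    starts: list[float] = []
    t_next = 2.0 + rng.uniform(0.0, 1.5)
    for _ in range(n_total):
        starts.append(t_next)
        t_next += rng.uniform(2.5, 4.0)
    rng.shuffle(starts)
    scans = tuple(
        ScanEpisode(
            start_t=s,
            duration=rng.uniform(0.8, 2.0),
            sweep_amplitude=rng.uniform(60.0, 90.0),
        )
        for s in starts[:n_scans]
    )
    stops = tuple(
        StopEpisode(start_t=s, duration=rng.uniform(0.5, 1.5))
        for s in starts[n_scans:]
    )
    return BehaviourScript(response_mode=mode, stops=stops, scans=scans)


def _perturbed(params: CRWParams, rng, step_mult: float = 1.0, dc: float = 0.0) -> CRWParams:
    """Per-ant / per-subject variation around a condition's parameters."""
    c = min(max(params.turn_concentration + dc, 0.0), 0.995)
    return replace(
        params,
        mean_step=params.mean_step * step_mult,
        turn_concentration=c,
    )


def simulate_experiment(
    design: str,
    effect_profile: dict[str, ConditionProfile],
    n_per_cell: int,
    seed: int,
    arena: ArenaGeometry | None = None,
) -> tuple[list[tuple[Trajectory, dict]], pd.DataFrame]:
    """Generate a full experiment's worth of forager trajectories.

    ``design="paired"`` emulates the per-nest control-vs-test layout
    (independent ants per condition); ``design="repeated"`` reuses subject
    identities across all conditions with per-subject random intercepts
    on speed and turning concentration. Returns the trajectories with
    their ground-truth records plus a manifest table.
    """
    if n_per_cell < 2:
        raise ParameterError("n_per_cell must be >= 2")
    if design not in ("paired", "repeated"):
        raise ParameterError(f"unknown design {design!r}")
    arena = arena or ArenaGeometry()
    rng = np.random.default_rng(seed)
    modes = np.array(["cross", "detour", "u_turn"])

    if design == "repeated":
        step_mults = np.exp(rng.normal(0.0, _SUBJECT_STEP_SD, n_per_cell))
        dcs = rng.normal(0.0, _SUBJECT_C_SD, n_per_cell)
    out: list[tuple[Trajectory, dict]] = []
    rows = []
    for cond, profile in effect_profile.items():
        for i in range(n_per_cell):
            if design == "repeated":
                step_mult, dc = step_mults[i], dcs[i]
            else:
                step_mult = math.exp(rng.normal(0.0, _SUBJECT_STEP_SD))
                dc = rng.normal(0.0, _SUBJECT_C_SD)
            params = _perturbed(profile.params, rng, step_mult, dc)
            mode = str(rng.choice(modes, p=profile.mode_mixture))
            script = _auto_script(profile, mode, rng)
            forager_seed = int(rng.integers(0, 2**31 - 1))
            while True:
                try:
                    traj, truth = simulate_forager(params, script, arena, seed=forager_seed)
                    break
                except ScriptError:
                    # trip ended before the latest-scheduled episode: shed it
                    episodes = sorted(
                        [("stops", e) for e in script.stops]
                        + [("scans", e) for e in script.scans],
                        key=lambda kv: kv[1].start_t,
                    )
                    kept = episodes[:-1]
                    script = BehaviourScript(
                        response_mode=script.response_mode,
                        stops=tuple(e for k, e in kept if k == "stops"),
                        scans=tuple(e for k, e in kept if k == "scans"),
                    )
            traj = traj.with_labels(
                ant_id=f"{cond}_{i:03d}", condition=cond, session=cond
            )
            truth["subject"] = i
            truth["condition"] = cond
            out.append((traj, truth))
            rows.append(
                {
                    "ant_id": traj.ant_id,
                    "subject": i,
                    "condition": cond,
                    "response_mode": mode,
                    "n_scans": sum(e["kind"] == "scan" for e in truth["events"]),
                    "n_stops": sum(e["kind"] == "stop" for e in truth["events"]),
                    "p_star": params.mean_step,
                    "c_star": params.turn_concentration,
                    "b_star": params.step_cv,
                }
            )
    return out, pd.DataFrame(rows)
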