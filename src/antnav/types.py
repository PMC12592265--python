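"""Core containers and errors shared across the pipeline.

Coordinates are arena-frame millimetres with +y pointing up the trunk.
Angles are degrees externally, wrapped to (-180, 180]; time is seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FRAME_RATE = 25.0  # frames per second of the tracking videos


class TrajectoryFormatError(ValueError):
    """A trajectory table is malformed (missing column, non-numeric data)."""


class InsufficientDataError(ValueError):
    """Too few valid frames/steps/pairs for the requested computation."""


class ParameterError(ValueError):
    """An analysis or generator parameter is outside its valid domain."""


class DesignError(ValueError):
    """A statistical design is incomplete or inconsistent."""


class ScriptError(ValueError):
    """A behaviour script is inconsistent with the trajectory or arena."""


def wrap_angle_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass
class Trajectory:
    """One ant run: frame-indexed head-tip and thorax-centre positions.

    Parameters
    ----------
    t : (n,) array
        Time of each frame in seconds, strictly increasing.
    head, thorax : (n, 2) arrays
        Positions in millimetres, arena frame, +y upward.
    frame_rate : float
        Nominal video frame rate (frames/s).
    ant_id, condition, session : str
        Labels carried through to output tables. ``condition`` is
        conventionally ``"control"`` or ``"test"``.
    """

    t: np.ndarray
    head: np.ndarray
    thorax: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    ant_id: str = ""
    condition: str = ""
    session: str = ""
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        self.thorax = np.asarray(self.thorax, dtype=float)
        if self.head.shape != (self.t.size, 2) or self.thorax.shape != (self.t.size, 2):
            raise TrajectoryFormatError(
                "head and thorax must be (n, 2) arrays matching the time vector"
            )
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise TrajectoryFormatError("frame times must be strictly increasing")
        if not (np.all(np.isfinite(self.head)) and np.all(np.isfinite(self.thorax))):
            raise TrajectoryFormatError("head/thorax coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    def with_labels(self, **labels) -> "Trajectory":
        out = Trajectory(
            self.t, self.head, self.thorax, self.frame_rate,
            self.ant_id, self.condition, self.session, self.dropped_rows,
        )
        for key, value in labels.items():
            setattr(out, key, value)
        return out


@dataclass(frozen=True)
class BandRect:
    """Axis-aligned odour-band rectangle in arena coordinates (mm)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ParameterError("band rectangle must have positive extent")

    @property
    def x_centre(self) -> float:
        return 0.5 * (self.x_min + self.x_max)


@dataclass(frozen=True)
class ArenaGeometry:
    """Recording-area extent and odour band.

    Defaults reflect a 70 cm wide x 1 m high recording area with a
    50 cm x 5 cm horizontal odour strip centred in it; the strip is
    narrower than the arena so walking around it in frame is possible.
    """

    width: float = 700.0
    height: float = 1000.0
    band: BandRect = field(
        default_factory=lambda: BandRect(100.0, 600.0, 475.0, 525.0)
    )

    def __post_init__(self) -> None:
        b = self.band
        inside = (
            0.0 <= b.x_min and b.x_max <= self.width
            and 0.0 < b.y_min and b.y_max < self.height
        )
        if not inside:
            raise ParameterError("band rectangle must lie strictly inside the arena")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) inside the arena extent."""
        xy = np.asarray(xy, dtype=float)
        return (
            (xy[:, 0] >= 0.0) & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0.0) & (xy[:, 1] <= self.height)
        )
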