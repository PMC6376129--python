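"""The water-maze world: coordinate frame, pool, platform, cues, protocol.

Coordinate frame
----------------
Origin at the pool centre, +y = North, +x = East.  Bearings (and swim
headings) are measured in degrees clockwise from North, so a heading of
0 deg moves due North and 90 deg due East:

    x += dr * sin(heading),   y += dr * cos(heading).

All lengths are centimetres, times are seconds, angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CueSpec",
    "ArenaConfig",
    "RegionInfo",
    "OutOfArenaError",
    "QUADRANTS",
    "COMPASS_BEARINGS",
    "compass_to_xy",
    "bearing_of",
    "bearing_between",
    "region_membership",
    "make_default_arena",
]

#: Compass labels -> bearing in degrees clockwise from North.
COMPASS_BEARINGS: Mapping[str, float] = {
    "N": 0.0,
    "NE": 45.0,
    "E": 90.0,
    "SE": 135.0,
    "S": 180.0,
    "SW": 225.0,
    "W": 270.0,
    "NW": 315.0,
}

#: Quadrant labels in clockwise order starting at North; the half-open
#: bearing interval [0, 90) deg is NE, [90, 180) SE, and so on.
QUADRANTS = ("NE", "SE", "SW", "NW")


def compass_to_xy(label: str, radius: float) -> tuple[float, float]:
    """Cartesian point at ``radius`` cm from the centre at a compass bearing."""
    b = math.radians(COMPASS_BEARINGS[label])
    return (radius * math.sin(b), radius * math.cos(b))


def bearing_of(x: float, y: float) -> float:
    """Bearing of (x, y) seen from the pool centre, in [0, 360) degrees."""
    return math.degrees(math.atan2(x, y)) % 360.0


def bearing_between(p: Sequence[float], q: Sequence[float]) -> float:
    """Bearing of the direction from point p to point q, degrees in [0, 360)."""
    return bearing_of(q[0] - p[0], q[1] - p[1])


class OutOfArenaError(ValueError):
    """Raised when a point that should lie inside the pool does not."""


@dataclass(frozen=True)
class CueSpec:
    """A distal landmark hanging outside the pool.

    salience is the Rescorla-Wagner weighting alpha_i in [0, 1]; across a
    two-cue scenario saliences are expressed as complementary shares
    (e.g. 0.5/0.5 or 0.83/0.17).  brightness_label is descriptive only.
    """

    cue_id: str
    position: tuple[float, float]
    salience: float = 0.5
    brightness_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.salience <= 1.0:
            raise ValueError(f"salience must lie in [0, 1], got {self.salience}")


def _default_cues() -> tuple[CueSpec, ...]:
    # Cue mounting radius is not a measured quantity; 120 cm (outside the
    # 85 cm pool, inside the curtain) preserves the task geometry.
    return (
        CueSpec("Near", compass_to_xy("NE", 120.0), 0.5),
        CueSpec("Far", compass_to_xy("NW", 120.0), 0.5),
    )


@dataclass(frozen=True)
class ArenaConfig:
    """Pool, platform, cue geometry and the trial protocol.

    Defaults encode the standard task: a 1.7 m diameter pool, a 9 cm
    hidden platform in the NE quadrant, landmarks in the NE (Near) and NW
    (Far) corners, 4 x 60 s trials/day for 10 days from {N, S, E, W}, and
    a 24 h probe released from SW.
    """

    pool_radius: float = 85.0
    platform_center: tuple[float, float] = compass_to_xy("NE", 42.5)
    platform_radius: float = 4.5
    escape_region_radius: float = 20.0
    cues: tuple[CueSpec, ...] = field(default_factory=_default_cues)
    trial_duration: float = 60.0
    trials_per_day: int = 4
    n_days: int = 10
    start_positions: tuple[str, ...] = ("N", "S", "E", "W")
    probe_start: str = "SW"
    #: Platform-contact rule: "path" detects centre-to-centre distance
    #: <= platform_radius anywhere along the straight step segment (the
    #: swimmer moves continuously between samples); "endpoint" only checks
    #: the sampled positions.
    contact_rule: str = "path"

    def __post_init__(self) -> None:
        px, py = self.platform_center
        if math.hypot(px, py) + self.platform_radius >= self.pool_radius:
            raise ValueError("platform must lie strictly inside the pool")
        for cue in self.cues:
            if math.hypot(*cue.position) <= self.pool_radius:
                raise ValueError(f"cue {cue.cue_id!r} must lie outside the pool")
        if self.escape_region_radius < self.platform_radius:
            raise ValueError("escape_region_radius must be >= platform_radius")
        for label in tuple(self.start_positions) + (self.probe_start,):
            if label not in COMPASS_BEARINGS:
                raise ValueError(f"unknown compass label {label!r}")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.contact_rule not in ("path", "endpoint"):
            raise ValueError(f"unknown contact_rule {self.contact_rule!r}")

    # -- helpers -----------------------------------------------------------
    @property
    def cue_ids(self) -> tuple[str, ...]:
        return tuple(c.cue_id for c in self.cues)

    def cue(self, cue_id: str) -> CueSpec:
        for c in self.cues:
            if c.cue_id == cue_id:
                return c
        raise KeyError(f"no cue named {cue_id!r}")

    def start_point(self, label: str) -> tuple[float, float]:
        """Release point on the pool rim at the named compass bearing."""
        return compass_to_xy(label, self.pool_radius)

    def n_trials(self) -> int:
        return self.trials_per_day * self.n_days

    def with_saliences(self, saliences: Mapping[str, float]) -> "ArenaConfig":
        """Copy of the arena with the given cue saliences."""
        cues = tuple(
            replace(c, salience=saliences.get(c.cue_id, c.salience))
            for c in self.cues
        )
        return replace(self, cues=cues)

    def saliences(self) -> dict[str, float]:
        return {c.cue_id: c.salience for c in self.cues}


@dataclass(frozen=True)
class RegionInfo:
    """Quadrant label plus membership of the escape-scoring circle."""

    quadrant: str
    in_escape_region: bool


def region_membership(point: Sequence[float], arena: ArenaConfig) -> RegionInfo:
    """Classify a point inside the pool into quadrant / escape circle.

    Quadrants are half-open angular sectors [0, 90) = NE, [90, 180) = SE,
    [180, 270) = SW, [270, 360) = NW, so boundary points (including the
    pool centre, which has bearing 0) are assigned deterministically.
    """
    x, y = float(point[0]), float(point[1])
    if math.hypot(x, y) > arena.pool_radius * (1 + 1e-9):
        raise OutOfArenaError(f"point {(x, y)} lies outside the pool")
    quadrant = QUADRANTS[int(bearing_of(x, y) // 90.0) % 4]
    px, py = arena.platform_center
    inside = math.hypot(x - px, y - py) <= arena.escape_region_radius
    return RegionInfo(quadrant, inside)


def make_default_arena(**overrides) -> ArenaConfig:
    """The default arena, with any field overridable by keyword."""
    return replace(ArenaConfig(), **overrides) if overrides else ArenaConfig()
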