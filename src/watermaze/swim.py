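"""Directed random walk with AR(2) heading dynamics and feedback control.

The swimmer takes Rayleigh-distributed steps.  The heading change is an
autoregressive process driven by a control input u = K * e_hat + noise,
where e_hat is a low-pass-filtered estimate of the heading error
(desired heading minus current heading).  With no desired heading the
controller is disengaged and the walk is an undirected meander.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SwimParams",
    "SwimState",
    "wrap_angle",
    "draw_step_size",
    "update_error_filter",
    "control_input",
    "step",
    "initial_state",
]


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class SwimParams:
    """Parameters of the swimming controller.

    Defaults were calibrated (scripts/calibrate_swim.py) so that an
    untrained swimmer fails to find the platform within a 60 s trial
    while a well-trained swimmer reaches it in roughly 5-10 s from the
    rim, and so that the four single-channel learning conditions fall in
    their reference escape-time regimes.  The step-size scale is an
    effective behavioural parameter (one step is one control update, not
    a literal stride), so the 7-step cue-approach episode spans the
    pool, which the goal-directed dynamics require.

    A1, A2        AR(2) coefficients on past heading changes.
    K             proportional feedback gain (dimensionless).
    F             filter weight in [0, 1]; F = 1 means no filtering.
    rayleigh_scale  scale (cm) of the Rayleigh step-size distribution.
    noise_std     std (degrees) of the normal heading-noise nu_t.
    dt            sampling time (s); one step per dt.
    n_steps       steps per behavioural episode (random or cue approach).
    goal_tolerance  distance (cm) at which a goal approach counts as arrived.
    goal_budget_factor  a goal approach is abandoned after
                  goal_budget_factor * n_steps steps (the guess may be
                  unreachable, e.g. outside the pool).
    boundary      wall rule: "clamp" (radially clamp to the wall) or
                  "reflect" (fold the overshoot back inside).
    uncued_steer_north  if True, an episode without a cue literally steers
                  toward bearing 0 instead of disengaging the controller.
    uncued_reorient  if True (default), each uncued episode starts with a
                  fresh uniform-random heading (run-and-tumble search);
                  if False the heading simply drifts under noise.
    """

    A1: float = 0.25
    A2: float = 0.05
    K: float = 0.95
    F: float = 0.92
    rayleigh_scale: float = 20.0
    noise_std: float = 4.0
    dt: float = 0.5
    n_steps: int = 7
    goal_tolerance: float = 2.0
    goal_budget_factor: int = 2
    boundary: str = "clamp"
    uncued_steer_north: bool = False
    uncued_reorient: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")
        if self.rayleigh_scale <= 0:
            raise ValueError("rayleigh_scale must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        if self.boundary not in ("clamp", "reflect"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")


class SwimState:
    """Evolving swimmer state: position, heading, AR history, filtered error."""

    __slots__ = ("x", "y", "heading", "dalpha_1", "dalpha_2", "ehat")

    def __init__(
        self,
        x: float,
        y: float,
        heading: float,
        dalpha_1: float = 0.0,
        dalpha_2: float = 0.0,
        ehat: float = 0.0,
    ) -> None:
        self.x = x
        self.y = y
        self.heading = heading
        self.dalpha_1 = dalpha_1  # heading change at t - dt
        self.dalpha_2 = dalpha_2  # heading change at t - 2 dt
        self.ehat = ehat

    def position(self) -> tuple[float, float]:
        return (self.x, self.y)

    def copy(self) -> "SwimState":
        return SwimState(
            self.x, self.y, self.heading, self.dalpha_1, self.dalpha_2, self.ehat
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"SwimState(x={self.x:.2f}, y={self.y:.2f}, "
            f"heading={self.heading:.1f}, ehat={self.ehat:.2f})"
        )


def initial_state(
    arena, start_label: str, rng: np.random.Generator | None = None
) -> SwimState:
    """State at release: on the rim at the named bearing.

    The release heading is uniform random when a generator is given
    (animals are dropped in without a controlled orientation), otherwise
    facing the pool centre.
    """
    from .arena import bearing_between

    x, y = arena.start_point(start_label)
    if rng is not None:
        heading = float(rng.uniform(-180.0, 180.0))
    else:
        heading = bearing_between((x, y), (0.0, 0.0))
    return SwimState(x, y, heading)


def draw_step_size(params: SwimParams, rng: np.random.Generator) -> float:
    """One Rayleigh-distributed step length (cm)."""
    if params.rayleigh_scale <= 0:
        raise ValueError("rayleigh_scale must be positive")
    return float(rng.rayleigh(params.rayleigh_scale))


def update_error_filter(
    ehat_prev: float, heading: float, desired_heading: float, params: SwimParams
) -> float:
    """Low-pass filter of the heading error: a convex combination of the
    previous estimate and the current wrapped error."""
    err = wrap_angle(desired_heading - heading)
    return (1.0 - params.F) * ehat_prev + params.F * err


def control_input(ehat: float, params: SwimParams, rng: np.random.Generator) -> float:
    """Control term u = K * e_hat + nu with nu ~ N(0, noise_std^2)."""
    nu = float(rng.normal(0.0, params.noise_std)) if params.noise_std > 0 else 0.0
    return params.K * ehat + nu


def step(
    state: SwimState,
    desired_heading: float | None,
    params: SwimParams,
    arena,
    rng: np.random.Generator,
) -> SwimState:
    """Advance the swimmer by one step of length dt (mutates ``state``).

    With a desired heading the error filter and controller are applied;
    with ``None`` the controller is disengaged (e_hat pinned at 0, so the
    input is pure noise) unless ``uncued_steer_north`` requests literal
    steering toward bearing 0.  The new position is constrained to the
    pool by the configured wall rule.
    """
    if desired_heading is None and not params.uncued_steer_north:
        state.ehat = 0.0
        u = float(rng.normal(0.0, params.noise_std)) if params.noise_std > 0 else 0.0
    else:
        desired = 0.0 if desired_heading is None else desired_heading
        state.ehat = update_error_filter(state.ehat, state.heading, desired, params)
        u = control_input(state.ehat, params, rng)

    dalpha = params.A1 * state.dalpha_1 + params.A2 * state.dalpha_2 + u
    heading = wrap_angle(state.heading + dalpha)
    dr = float(rng.rayleigh(params.rayleigh_scale))
    h = math.radians(heading)
    x = state.x + dr * math.sin(h)
    y = state.y + dr * math.cos(h)

    r = math.hypot(x, y)
    pool_r = arena.pool_radius
    if r > pool_r:
        if params.boundary == "clamp":
            scale = pool_r / r
        else:  # reflect: fold the radial overshoot back inside
            r_new = max(2.0 * pool_r - r, 0.0)
            scale = r_new / r if r > 0 else 0.0
        x *= scale
        y *= scale

    state.x = x
    state.y = y
    state.heading = heading
    state.dalpha_2 = state.dalpha_1
    state.dalpha_1 = dalpha
    return state
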