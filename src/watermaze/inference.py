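"""Inferring platform locations from learned distance/direction knowledge.

A guess is the cue position plus the true cue-to-platform polar offset
(r, phi) perturbed by zero-mean normal errors whose standard deviations
shrink linearly as the corresponding associations approach 1:

    sigma_dist = 1 - V_dist,   Var(eps_dist) = 200 * sigma_dist  [cm^2]
    sigma_dir  = 1 - V_dir,    Var(eps_dir)  =  75 * sigma_dir   [deg^2]

The 200 and 75 factors scale the error *variance* (the default,
``error_model="variance_linear"``); read as standard-deviation
multipliers instead (``"std_linear"``, std = 200 sigma_dist cm) a fully
uncertain channel would scatter guesses over several pool diameters and
single-channel learners could not reach the escape-time regime this
model is known for — see docs/methods.md for the full argument.

Guesses are deliberately not clipped to the pool: they act as steering
targets, and the wall rule of the swimmer handles containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .arena import ArenaConfig, CueSpec, bearing_between, bearing_of

__all__ = [
    "DIST_ERROR_SCALE",
    "DIR_ERROR_SCALE",
    "PlatformGuess",
    "cue_platform_offset",
    "uncertainties",
    "sample_errors",
    "infer_platform",
    "guess_cloud",
    "guess_heatmap",
]

#: Distance-error variance multiplier (cm^2 per unit of distance uncertainty).
DIST_ERROR_SCALE = 200.0
#: Direction-error variance multiplier (deg^2 per unit of direction uncertainty).
DIR_ERROR_SCALE = 75.0

#: How the scale factors map uncertainty to error spread.
ERROR_MODELS = ("variance_linear", "std_linear")
DEFAULT_ERROR_MODEL = "variance_linear"


def _error_stds(sigma_dist: float, sigma_dir: float, error_model: str) -> tuple[float, float]:
    if error_model == "variance_linear":
        return (
            math.sqrt(DIST_ERROR_SCALE * sigma_dist),
            math.sqrt(DIR_ERROR_SCALE * sigma_dir),
        )
    if error_model == "std_linear":
        return DIST_ERROR_SCALE * sigma_dist, DIR_ERROR_SCALE * sigma_dir
    raise ValueError(f"unknown error_model {error_model!r}")


@dataclass(frozen=True)
class PlatformGuess:
    """One sampled platform-location guess and the errors that made it."""

    point: tuple[float, float]
    source_cue: str
    eps_dist: float
    eps_dir: float


def cue_platform_offset(cue: CueSpec, arena: ArenaConfig) -> tuple[float, float]:
    """True polar offset (r cm, phi deg bearing) from the cue to the platform."""
    cx, cy = cue.position
    px, py = arena.platform_center
    r = math.hypot(px - cx, py - cy)
    phi = bearing_between(cue.position, arena.platform_center)
    return r, phi


def uncertainties(state, cue_id: str) -> tuple[float, float]:
    """(sigma_dist, sigma_dir) = (1 - V_dist, 1 - V_dir) for the cue."""
    if cue_id not in state.cue_ids:
        raise KeyError(f"no cue named {cue_id!r} in learning state")
    return 1.0 - state.v_dist[cue_id], 1.0 - state.v_dir[cue_id]


def sample_errors(
    sigma_dist: float,
    sigma_dir: float,
    rng: np.random.Generator,
    error_model: str = DEFAULT_ERROR_MODEL,
) -> tuple[float, float]:
    """Draw (eps_dist cm, eps_dir deg) for the given uncertainties.

    Under the default model the error variances are 200*sigma_dist and
    75*sigma_dir; both errors are exactly zero at full knowledge.
    """
    if not (0.0 <= sigma_dist <= 1.0 and 0.0 <= sigma_dir <= 1.0):
        raise ValueError("uncertainties must lie in [0, 1]")
    sd_dist, sd_dir = _error_stds(sigma_dist, sigma_dir, error_model)
    eps_dist = float(rng.normal(0.0, sd_dist)) if sd_dist > 0 else 0.0
    eps_dir = float(rng.normal(0.0, sd_dir)) if sd_dir > 0 else 0.0
    return eps_dist, eps_dir


def infer_platform(
    state,
    cue: CueSpec,
    arena: ArenaConfig,
    rng: np.random.Generator,
    anchor_position: Sequence[float] | None = None,
    negative_radius: str = "reflect",
    error_model: str = DEFAULT_ERROR_MODEL,
) -> PlatformGuess:
    """Sample one platform guess from the learned offsets of ``cue``.

    ``anchor_position`` anchors the learned polar vector somewhere other
    than the cue's own position; this expresses cue misinterpretation
    (applying cue j's learned relationship to a different physical
    landmark).  The learned bearing is expressed relative to the cue
    configuration: when the vector is re-anchored, it is rotated by the
    angular offset between the anchor's and the cue's bearings from the
    pool centre, so a rat that misreads the NE landmark as its NW cue
    searches in the SE (the platform estimate rotates with the presumed
    cue identity).  A sampled radius below zero is reflected through the
    anchor (bearing flipped by 180 deg) by default, or truncated at zero
    with ``negative_radius="truncate"``.
    """
    r, phi = cue_platform_offset(cue, arena)
    sigma_dist, sigma_dir = uncertainties(state, cue.cue_id)
    eps_dist, eps_dir = sample_errors(sigma_dist, sigma_dir, rng, error_model)
    rotation = 0.0
    if anchor_position is not None:
        cx, cy = cue.position
        ax, ay = anchor_position
        rotation = bearing_of(ax, ay) - bearing_of(cx, cy)
    radius = r + eps_dist
    bearing = phi + eps_dir + rotation
    if radius < 0:
        if negative_radius == "reflect":
            radius = -radius
            bearing += 180.0
        elif negative_radius == "truncate":
            radius = 0.0
        else:
            raise ValueError(f"unknown negative_radius rule {negative_radius!r}")
    ax, ay = anchor_position if anchor_position is not None else cue.position
    b = math.radians(bearing)
    point = (ax + radius * math.sin(b), ay + radius * math.cos(b))
    return PlatformGuess(point, cue.cue_id, eps_dist, eps_dir)


def guess_cloud(
    state,
    arena: ArenaConfig,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample guesses pooling cues in proportion to V_use.

    Returns an (n_samples, 3) array of (x, y, cue index into arena.cues).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    weights = np.array([state.v_use[c.cue_id] for c in arena.cues], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot pool guesses: all V_use are zero")
    probs = weights / total
    choices = rng.choice(len(arena.cues), size=n_samples, p=probs)
    out = np.empty((n_samples, 3))
    for i, ci in enumerate(choices):
        g = infer_platform(state, arena.cues[ci], arena, rng)
        out[i] = (g.point[0], g.point[1], ci)
    return out


def guess_heatmap(
    state,
    arena: ArenaConfig,
    n_samples: int,
    rng: np.random.Generator,
    bins: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D guess density over the square bounding the pool.

    Guesses falling outside the bounding square are clipped onto its edge
    bins so the returned histogram always sums to 1.
    Returns (density with shape (bins, bins) indexed [ix, iy], xedges, yedges).
    """
    cloud = guess_cloud(state, arena, n_samples, rng)
    lim = arena.pool_radius
    xy = np.clip(cloud[:, :2], -lim, lim)
    hist, xedges, yedges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=[[-lim, lim], [-lim, lim]]
    )
    return hist / hist.sum(), xedges, yedges
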