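"""Summary statistics over trials: latencies, occupancy, variability.

Occupancy is computed from step midpoints weighted by the sampling time,
which is unbiased for piecewise-linear paths at small dt.  Censored
trials (no escape within the trial duration) contribute the full
duration to latency summaries, the standard water-maze convention; the
censoring count is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig, QUADRANTS, bearing_of

__all__ = [
    "CohortSummary",
    "latency_summary",
    "trajectory_occupancy",
    "equivalent_area_occupancy",
    "occupancy_summary",
    "cv_comparison",
]


@dataclass(frozen=True)
class CohortSummary:
    """Latency and/or occupancy statistics for one condition."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    cv: float
    n_censored: int = 0
    occupancy: dict = field(default_factory=dict)


def latency_summary(
    latencies: Sequence[float],
    censored: Sequence[bool] | None = None,
    trial_duration: float | None = None,
) -> CohortSummary:
    """Mean/sd/median/quartiles of escape latency.

    Censored entries are counted at trial_duration when given (they
    normally already carry that value).
    """
    lat = np.asarray(latencies, dtype=float)
    if lat.size == 0:
        raise ValueError("latency_summary needs at least one latency")
    cens = (
        np.zeros(lat.shape, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    if trial_duration is not None:
        lat = np.where(cens, trial_duration, lat)
    mean = float(lat.mean())
    sd = float(lat.std(ddof=1)) if lat.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(lat, [25, 50, 75]))
    cv = sd / mean if mean > 0 else float("nan")
    return CohortSummary(
        n=int(lat.size),
        mean=mean,
        sd=sd,
        median=med,
        q1=q1,
        q3=q3,
        cv=cv,
        n_censored=int(cens.sum()),
    )


def trajectory_occupancy(
    trajectory: np.ndarray, arena: ArenaConfig, dt: float
) -> dict[str, float]:
    """Time-weighted region occupancy fractions for one trajectory.

    ``trajectory`` has rows (t, x, y, heading).  Each step contributes dt
    at its midpoint.  Returns fractions per quadrant plus "escape" (the
    scoring circle around the former platform position); quadrant
    fractions sum to 1.
    """
    xy = np.asarray(trajectory)[:, 1:3]
    if xy.shape[0] < 2:
        raise ValueError("trajectory must contain at least one step")
    mid = 0.5 * (xy[1:] + xy[:-1])
    bearings = np.degrees(np.arctan2(mid[:, 0], mid[:, 1])) % 360.0
    quad_idx = (bearings // 90.0).astype(int) % 4
    n = mid.shape[0]
    out = {q: float(np.count_nonzero(quad_idx == i)) / n for i, q in enumerate(QUADRANTS)}
    px, py = arena.platform_center
    dist = np.hypot(mid[:, 0] - px, mid[:, 1] - py)
    out["escape"] = float(np.count_nonzero(dist <= arena.escape_region_radius)) / n
    return out


def equivalent_area_occupancy(
    trajectory: np.ndarray, arena: ArenaConfig, dt: float
) -> dict[str, float]:
    """Fraction of time in the platform-area circle and its rotational
    equivalents in the other three quadrants (the standard control
    regions for probe scoring)."""
    xy = np.asarray(trajectory)[:, 1:3]
    mid = 0.5 * (xy[1:] + xy[:-1])
    n = mid.shape[0]
    px, py = arena.platform_center
    out = {}
    for k, quadrant in enumerate(QUADRANTS):
        # rotate the platform centre clockwise by k * 90 degrees
        a = math.radians(90.0 * k)
        cx = px * math.cos(a) + py * math.sin(a)
        cy = -px * math.sin(a) + py * math.cos(a)
        dist = np.hypot(mid[:, 0] - cx, mid[:, 1] - cy)
        out[quadrant] = float(
            np.count_nonzero(dist <= arena.escape_region_radius)
        ) / n
    return out


def occupancy_summary(records: Sequence, arena: ArenaConfig) -> pd.DataFrame:
    """Per-rat occupancy table for a list of TrialRecords (probe trials)."""
    rows = []
    for i, rec in enumerate(records):
        occ = trajectory_occupancy(rec.trajectory, arena, rec.dt)
        rows.append({"rat": i, **occ})
    return pd.DataFrame(rows)


def cv_comparison(
    learning,
    arena: ArenaConfig,
    swim,
    n_rats: int,
    seed: int,
) -> tuple[float, float]:
    """Across-rat CVs of single-trial latency vs probe time-in-area.

    For each rat of a trained cohort: one platform-present trial from a
    start drawn from the acquisition start set (latency, censored at the
    trial duration) and one platform-absent probe from the probe start
    (seconds inside the escape-scoring circle).  Returns
    (CV_latency, CV_occupancy).
    """
    from ._rng import rat_rng
    from .navigator import simulate_trial

    latencies = np.empty(n_rats)
    in_area = np.empty(n_rats)
    for rat in range(n_rats):
        rng = rat_rng(seed, rat)
        start = arena.start_positions[int(rng.integers(len(arena.start_positions)))]
        rec = simulate_trial(learning, arena, swim, start, rng, platform_present=True)
        latencies[rat] = rec.escape_latency
        probe = simulate_trial(
            learning, arena, swim, arena.probe_start, rng, platform_present=False
        )
        occ = trajectory_occupancy(probe.trajectory, arena, swim.dt)
        in_area[rat] = occ["escape"] * arena.trial_duration
    cv_lat = float(latencies.std(ddof=1) / latencies.mean())
    cv_occ = float(in_area.std(ddof=1) / in_area.mean())
    return cv_lat, cv_occ
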