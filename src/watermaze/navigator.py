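"""The integration loop binding learning, inference and swimming.

A trial is a sequence of behavioural episodes:

1. Select a learned cue relationship; cue i is chosen with probability
   V_i,use (the choices are mutually exclusive, so no cue is selected
   with probability 1 - sum_i V_i,use).
2. No cue selected: the rat swims randomly (controller disengaged) for
   n_steps and the loop restarts.
3. Cue selected: the rat steers toward the (physically presented) cue
   for n_steps, re-aiming each step,
4. then draws a fresh platform guess from the selected relationship and
   steers toward it until within goal_tolerance or 2 * n_steps elapse.
5. Restart at 1.

The trial ends at platform contact (centre-to-centre distance at or
below the platform radius, when a platform is present) or at the trial
duration, in which case the latency is censored at that duration.

Cue-removal probes and interpretation policies are expressed by giving
``simulate_trial`` a :class:`CuePresentation` (which cues are physically
available, optionally repositioned) and a policy object with a ``mode``
attribute; the policy decides which *learned* relationship is anchored
at which *presented* landmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import rat_rng
from .arena import ArenaConfig, bearing_between
from .inference import infer_platform
from .learning import LearningParams, LearningState, run_training
from .swim import SwimParams, SwimState, initial_state, step

__all__ = [
    "CuePresentation",
    "Episode",
    "TrialRecord",
    "select_cue",
    "simulate_trial",
    "run_acquisition",
    "run_retention",
    "latency_frame",
]


@dataclass(frozen=True)
class CuePresentation:
    """Which cues are physically present in a trial (all, if None is used
    instead of an instance), with optional position overrides for swaps."""

    present: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def position_of(self, cue_id: str, arena: ArenaConfig) -> tuple[float, float]:
        if cue_id in self.positions:
            return self.positions[cue_id]
        return arena.cue(cue_id).position


@dataclass
class Episode:
    kind: str  # "random" | "cue-approach" | "goal-approach"
    learned_cue: str | None
    anchor_cue: str | None
    guess: tuple[float, float] | None
    start_step: int
    end_step: int


@dataclass
class TrialRecord:
    """One simulated trial: trajectory, episode log, escape latency."""

    trajectory: np.ndarray  # rows (t, x, y, heading), including the release row
    episodes: list[Episode]
    escape_latency: float
    censored: bool
    start: str
    trial_index: int
    dt: float


def select_cue(state: LearningState, rng: np.random.Generator) -> str | None:
    """Draw a cue with probability V_use (or None with 1 - sum V_use)."""
    total = state.total_use()
    if total > 1.0 + 1e-9:
        raise ValueError(f"sum of V_use exceeds 1 ({total:.6f}); invalid state")
    u = float(rng.random())
    acc = 0.0
    for cue_id in state.cue_ids:
        acc += state.v_use[cue_id]
        if u < acc:
            return cue_id
    return None


def _policy_mode(policy) -> str:
    return "identity" if policy is None else policy.mode


def _choose_episode(
    learning: LearningState,
    presentation: CuePresentation | None,
    policy,
    rng: np.random.Generator,
) -> tuple[str | None, str | None]:
    """Pick (learned relationship, presented anchor cue) for one episode.

    Returns (None, None) for a random-swim episode.  When every trained
    cue is presented the cue configuration is unambiguous and every
    policy reduces to the identity mapping.
    """
    present = learning.cue_ids if presentation is None else presentation.present
    mode = _policy_mode(policy)
    all_present = set(present) >= set(learning.cue_ids)

    if mode == "probabilistic_misinterpretation" and not all_present and len(present) == 1:
        c = present[0]
        target = getattr(policy, "misinterpreted_cue", None)
        if target is None or target == c:
            others = [k for k in learning.cue_ids if k != c]
            p = policy.misinterpretation_probability
            if others and float(rng.random()) < p:
                j = (
                    others[int(rng.integers(len(others)))]
                    if len(others) > 1
                    else others[0]
                )
            else:
                j = c
            if float(rng.random()) < learning.v_use[j]:
                return j, c
            return None, None
        mode = "identity"  # the policy only covers the named cue

    k = select_cue(learning, rng)
    if k is None:
        return None, None
    if mode == "identity" or all_present:
        return (k, k) if k in present else (None, None)
    if mode in ("indistinguishable", "generalize_to_salient"):
        if not present:
            return None, None
        anchor = present[int(rng.integers(len(present)))] if len(present) > 1 else present[0]
        return k, anchor
    raise ValueError(f"unknown interpretation mode {mode!r}")


def simulate_trial(
    learning: LearningState,
    arena: ArenaConfig,
    swim: SwimParams,
    start: str,
    rng: np.random.Generator,
    platform_present: bool = True,
    interpretation=None,
    presentation: CuePresentation | None = None,
    trial_index: int = 0,
) -> TrialRecord:
    """Run one trial of the five-step algorithm and record everything."""
    max_steps = int(round(arena.trial_duration / swim.dt))
    state = initial_state(arena, start)
    px, py = arena.platform_center
    contact_r = arena.platform_radius

    traj = np.empty((max_steps + 1, 4))
    traj[0] = (0.0, state.x, state.y, state.heading)
    episodes: list[Episode] = []
    steps = 0
    escaped = False

    check_path = arena.contact_rule == "path"

    def advance(desired: float | None) -> bool:
        """One swim step; returns True if the platform was contacted."""
        nonlocal steps
        x0, y0 = state.x, state.y
        step(state, desired, swim, arena, rng)
        steps += 1
        traj[steps] = (steps * swim.dt, state.x, state.y, state.heading)
        if not platform_present:
            return False
        if math.hypot(state.x - px, state.y - py) <= contact_r:
            return True
        if check_path:
            # closest approach of the straight step segment to the platform
            dx, dy = state.x - x0, state.y - y0
            seg2 = dx * dx + dy * dy
            if seg2 > 0.0:
                u = ((px - x0) * dx + (py - y0) * dy) / seg2
                if 0.0 < u < 1.0:
                    cx, cy = x0 + u * dx, y0 + u * dy
                    return math.hypot(cx - px, cy - py) <= contact_r
        return False

    while steps < max_steps and not escaped:
        learned_id, anchor_id = _choose_episode(learning, presentation, interpretation, rng)
        ep_start = steps
        if anchor_id is None:
            if swim.uncued_reorient:
                # run-and-tumble: an uncued episode starts with a fresh
                # random heading, making undirected search diffusive at
                # the trial scale instead of ballistic wall-following
                state.heading = float(rng.uniform(-180.0, 180.0))
                state.dalpha_1 = state.dalpha_2 = 0.0
            for _ in range(swim.n_steps):
                if steps >= max_steps:
                    break
                if advance(None):
                    escaped = True
                    break
            episodes.append(Episode("random", None, None, None, ep_start, steps))
            continue

        anchor_pos = (
            presentation.position_of(anchor_id, arena)
            if presentation is not None
            else arena.cue(anchor_id).position
        )
        for _ in range(swim.n_steps):
            if steps >= max_steps:
                break
            if advance(bearing_between(state.position(), anchor_pos)):
                escaped = True
                break
        episodes.append(
            Episode("cue-approach", learned_id, anchor_id, None, ep_start, steps)
        )
        if escaped or steps >= max_steps:
            break

        guess = infer_platform(
            learning, arena.cue(learned_id), arena, rng, anchor_position=anchor_pos
        )
        gx, gy = guess.point
        ep_start = steps
        for _ in range(swim.goal_budget_factor * swim.n_steps):
            if steps >= max_steps:
                break
            if math.hypot(state.x - gx, state.y - gy) <= swim.goal_tolerance:
                break
            if advance(bearing_between(state.position(), (gx, gy))):
                escaped = True
                break
        episodes.append(
            Episode("goal-approach", learned_id, anchor_id, guess.point, ep_start, steps)
        )

    latency = steps * swim.dt if escaped else arena.trial_duration
    return TrialRecord(
        trajectory=traj[: steps + 1],
        episodes=episodes,
        escape_latency=latency,
        censored=not escaped,
        start=start,
        trial_index=trial_index,
        dt=swim.dt,
    )


def run_acquisition(
    arena: ArenaConfig,
    swim: SwimParams,
    learning_params: LearningParams,
    n_rats: int,
    seed: int,
    saliences: Mapping[str, float] | None = None,
    presentation: CuePresentation | None = None,
    keep_records: bool = False,
):
    """Simulate the full training protocol for a cohort.

    Each rat gets an independent stream derived from (seed, rat index)
    and its own pseudorandom permutation of the start positions each
    day.  The associative updates depend only on saliences, so the
    learning trajectory is shared by all rats; trial t is swum under the
    state reached after t - 1 updates.

    Returns (latency DataFrame, final LearningState, state history) and,
    with keep_records, appends the per-trial TrialRecords per rat.
    """
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    history = run_training(arena, learning_params, arena.n_trials(), saliences)
    rows = []
    records: list[list[TrialRecord]] = []
    for rat in range(n_rats):
        rng = rat_rng(seed, rat)
        rat_records = []
        t = 0
        for day in range(arena.n_days):
            order = [
                arena.start_positions[i]
                for i in rng.permutation(len(arena.start_positions))
            ]
            for trial in range(arena.trials_per_day):
                start = order[trial % len(order)]
                rec = simulate_trial(
                    history[t],
                    arena,
                    swim,
                    start,
                    rng,
                    platform_present=True,
                    presentation=presentation,
                    trial_index=t,
                )
                rows.append(
                    {
                        "rat": rat,
                        "day": day + 1,
                        "trial": t + 1,
                        "start": start,
                        "latency": rec.escape_latency,
                        "censored": rec.censored,
                    }
                )
                if keep_records:
                    rat_records.append(rec)
                t += 1
        if keep_records:
            records.append(rat_records)
    frame = pd.DataFrame(rows)
    if keep_records:
        return frame, history[-1], history, records
    return frame, history[-1], history


def run_retention(
    learning: LearningState,
    arena: ArenaConfig,
    swim: SwimParams,
    manipulation: CuePresentation | None = None,
    interpretation=None,
    n_rats: int = 50,
    seed: int = 0,
    keep_records: bool = False,
):
    """Platform-absent 60 s probes from the probe start for a trained cohort.

    No learning occurs during probes (evaluation only).  Returns a tidy
    DataFrame with one row per rat: quadrant occupancy fractions, the
    fraction and seconds of time inside the escape-scoring circle.
    """
    from .metrics import trajectory_occupancy

    rows = []
    records = []
    for rat in range(n_rats):
        rng = rat_rng(seed, rat)
        rec = simulate_trial(
            learning,
            arena,
            swim,
            arena.probe_start,
            rng,
            platform_present=False,
            interpretation=interpretation,
            presentation=manipulation,
        )
        occ = trajectory_occupancy(rec.trajectory, arena, swim.dt)
        row = {"rat": rat, **occ}
        row["escape_seconds"] = occ["escape"] * arena.trial_duration
        rows.append(row)
        if keep_records:
            records.append(rec)
    frame = pd.DataFrame(rows)
    return (frame, records) if keep_records else frame


def latency_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy latency table for a list of trial records."""
    return pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "start": [r.start for r in records],
            "latency": [r.escape_latency for r in records],
            "censored": [r.censored for r in records],
        }
    )
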