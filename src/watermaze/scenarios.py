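"""Declarative reproductions of the model's experiment battery.

Covers: the direction/distance dissection, salience sweeps of the guess
distribution, cue-removal probes under different interpretation
policies, the two uncertainty models for dim cues (ignoring the dim cue
versus probabilistically misinterpreting it), and the overshadowing
group design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import master_rng, rat_rng
from .arena import ArenaConfig, make_default_arena
from .inference import guess_cloud, guess_heatmap
from .learning import LearningParams, LearningState, run_training
from .metrics import equivalent_area_occupancy, trajectory_occupancy
from .navigator import CuePresentation, run_retention, simulate_trial
from .swim import SwimParams

__all__ = [
    "InterpretationPolicy",
    "ScenarioSpec",
    "IDENTITY",
    "INDISTINGUISHABLE",
    "trained_state",
    "dissect_information",
    "salience_sweep",
    "cue_removal_retention",
    "uncertainty_models",
    "overshadowing_experiment",
]

_MODES = (
    "identity",
    "indistinguishable",
    "generalize_to_salient",
    "probabilistic_misinterpretation",
)


@dataclass(frozen=True)
class InterpretationPolicy:
    """How a presented cue is mapped to a learned cue-platform relationship.

    identity: each presented cue is read as itself.
    indistinguishable: the rat cannot tell the cues apart; a learned
        relationship is assigned to the available landmark with
        probability equal to its V_use, re-drawn every episode.
    generalize_to_salient: behaviourally the same machinery; at extreme
        saliences (V_use concentrated on one cue) it degenerates to
        always applying the dominant cue's relationship, and at a 50:50
        split it coincides with `indistinguishable`.
    probabilistic_misinterpretation: the presented cue (optionally only
        the one named by `misinterpreted_cue`) is read as itself with
        probability 1 - p and as the other cue with probability p.
    """

    mode: str = "identity"
    misinterpretation_probability: float = 0.0
    misinterpreted_cue: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown interpretation mode {self.mode!r}")
        if not 0.0 <= self.misinterpretation_probability <= 1.0:
            raise ValueError("misinterpretation_probability must lie in [0, 1]")


IDENTITY = InterpretationPolicy("identity")
INDISTINGUISHABLE = InterpretationPolicy("indistinguishable")


@dataclass(frozen=True)
class ScenarioSpec:
    """A trained-then-probed scenario: who was trained on what, and what
    is presented (and how it is interpreted) at retention."""

    name: str
    saliences: Mapping[str, float]
    retention_conditions: Mapping[str, tuple[str, ...]]
    interpretation: InterpretationPolicy = IDENTITY
    channel_override: str | None = None  # None | "direction" | "distance"
    n_rats: int = 50
    seed: int = 0
    n_trials: int | None = None

    def __post_init__(self) -> None:
        if self.channel_override not in (None, "direction", "distance"):
            raise ValueError(f"bad channel_override {self.channel_override!r}")


def trained_state(
    arena: ArenaConfig,
    learning_params: LearningParams,
    saliences: Mapping[str, float] | None = None,
    n_trials: int | None = None,
    channel_override: str | None = None,
) -> LearningState:
    """Final learning state after the training protocol; optionally zero
    out one vector channel (direction-only / distance-only conditions)."""
    n = arena.n_trials() if n_trials is None else n_trials
    state = run_training(arena, learning_params, n, saliences)[-1]
    if channel_override == "direction":
        state = LearningState(
            state.cue_ids, dict(state.v_use), dict(state.v_dir),
            {c: 0.0 for c in state.cue_ids},
        )
    elif channel_override == "distance":
        state = LearningState(
            state.cue_ids, dict(state.v_use),
            {c: 0.0 for c in state.cue_ids}, dict(state.v_dist),
        )
    return state


def _single_channel_state(
    arena: ArenaConfig, cue: str, channel: str, strength: float
) -> LearningState:
    """State in which one cue is always used and only one vector channel
    of it is learned, at the given strength."""
    if channel not in ("direction", "distance", "both"):
        raise ValueError(f"unknown channel {channel!r}")
    v_dir = strength if channel in ("direction", "both") else 0.0
    v_dist = strength if channel in ("distance", "both") else 0.0
    return LearningState.from_values(
        arena.cue_ids,
        v_use={cue: 1.0},
        v_dir={cue: v_dir},
        v_dist={cue: v_dist},
    )


def dissect_information(
    arena: ArenaConfig,
    swim: SwimParams,
    channel: str,
    cue: str,
    strength: float,
    n_rats: int,
    seed: int,
    n_guesses: int = 1000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Latency distribution and guess cloud for a single-channel learner.

    The named cue is used in every episode (its V_use is 1) and only the
    named channel ("direction", "distance" or "both") carries the given
    association strength; the other channel is fully uncertain.  One
    60 s platform-present trial per rat, start drawn from the
    acquisition start set.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    state = _single_channel_state(arena, cue, channel, strength)
    rows = []
    for rat in range(n_rats):
        rng = rat_rng(seed, rat)
        start = arena.start_positions[int(rng.integers(len(arena.start_positions)))]
        rec = simulate_trial(state, arena, swim, start, rng, platform_present=True)
        rows.append(
            {
                "rat": rat,
                "start": start,
                "latency": rec.escape_latency,
                "censored": rec.censored,
            }
        )
    cloud = guess_cloud(state, arena, n_guesses, master_rng(seed))
    return pd.DataFrame(rows), cloud


def _ne_fraction(cloud: np.ndarray) -> float:
    """Fraction of guesses landing in the NE quadrant (x > 0, y > 0... by
    bearing sector [0, 90))."""
    bear = np.degrees(np.arctan2(cloud[:, 0], cloud[:, 1])) % 360.0
    return float(np.count_nonzero(bear < 90.0)) / cloud.shape[0]


def _entropy(density: np.ndarray) -> float:
    p = density[density > 0]
    return float(-(p * np.log(p)).sum())


def salience_sweep(
    arena: ArenaConfig,
    strengths: Sequence[float],
    ratios: Sequence[tuple[float, float]],
    channels: Sequence[str] = ("direction", "distance"),
    n_samples: int = 2000,
    seed: int = 0,
    learning_params: LearningParams | None = None,
    bins: int = 40,
):
    """Guess-distribution sweep over salience strength and ratio.

    Each ratio (w1, w2) splits salience between the two cues in
    complementary shares (w1 + w2 = 1); the overall strength s scales
    both, with the cue saliences set to (2 s w1, 2 s w2) so that the
    strongest setting s = 0.5 recovers the shares themselves.  For each
    cell the learner is trained through the standard protocol, the
    channels not in ``channels`` are zeroed, and the pooled guess
    distribution is summarised by its NE-quadrant fraction, entropy and
    heatmap.

    Returns (tidy DataFrame, dict keyed (strength, ratio, channels) ->
    (density, xedges, yedges)).
    """
    params = learning_params or LearningParams()
    channels = tuple(channels)
    override = None
    if channels == ("direction",):
        override = "direction"
    elif channels == ("distance",):
        override = "distance"
    elif set(channels) != {"direction", "distance"}:
        raise ValueError(f"bad channel set {channels!r}")
    cue1, cue2 = arena.cue_ids[:2]
    rows = []
    heatmaps = {}
    for s in strengths:
        for w1, w2 in ratios:
            if not math.isclose(w1 + w2, 1.0, abs_tol=1e-9):
                raise ValueError("ratio components must sum to 1")
            sal = {cue1: 2.0 * s * w1, cue2: 2.0 * s * w2}
            state = trained_state(arena, params, sal, channel_override=override)
            rng = master_rng(seed)
            cloud = guess_cloud(state, arena, n_samples, rng)
            density, xe, ye = guess_heatmap(state, arena, n_samples, rng, bins=bins)
            key = (s, (w1, w2), channels)
            heatmaps[key] = (density, xe, ye)
            rows.append(
                {
                    "strength": s,
                    "ratio": f"{w1:g}:{w2:g}",
                    "channels": "+".join(channels),
                    "ne_fraction": _ne_fraction(cloud),
                    "entropy": _entropy(density),
                }
            )
    return pd.DataFrame(rows), heatmaps


def cue_removal_retention(
    spec: ScenarioSpec,
    arena: ArenaConfig | None = None,
    swim: SwimParams | None = None,
    learning_params: LearningParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Train per the spec, then probe under each retention condition.

    Returns {condition name: per-rat occupancy DataFrame} (quadrant
    fractions plus the escape-circle fraction and seconds).
    """
    arena = arena or make_default_arena()
    swim = swim or SwimParams()
    params = learning_params or LearningParams()
    state = trained_state(
        arena, params, spec.saliences, spec.n_trials, spec.channel_override
    )
    out = {}
    for cond, present in spec.retention_conditions.items():
        unknown = set(present) - set(arena.cue_ids)
        if unknown:
            raise ValueError(f"condition {cond!r} presents unknown cues {unknown}")
        out[cond] = run_retention(
            state,
            arena,
            swim,
            manipulation=CuePresentation(tuple(present)),
            interpretation=spec.interpretation,
            n_rats=spec.n_rats,
            seed=spec.seed,
        )
    return out


def uncertainty_models(
    arena: ArenaConfig | None = None,
    swim: SwimParams | None = None,
    learning_params: LearningParams | None = None,
    n_rats: int = 50,
    seed: int = 0,
) -> dict[str, dict[str, pd.DataFrame]]:
    """The two dim-cue uncertainty models.

    "ignore_dim": the bright Near cue takes all the salience
    (alpha = (1, 0)); the dim Far cue carries no learned information, so
    probing with it yields random search.

    "misinterpret": the bright Far cue dominates (alpha = (0.2, 0.8))
    but the dim Near cue keeps some salience from its location; when the
    dim cue is presented alone the rat misreads it as the bright cue
    half the time, splitting search between NE and SE.

    Returns {model: {"dim"/"bright"/"both": occupancy DataFrame}}.
    """
    arena = arena or make_default_arena()
    swim = swim or SwimParams()
    params = learning_params or LearningParams()
    near, far = arena.cue_ids[:2]

    out: dict[str, dict[str, pd.DataFrame]] = {}

    # Model (c): bright Near, ignored dim Far.
    state_c = trained_state(arena, params, {near: 1.0, far: 0.0})
    out["ignore_dim"] = {
        "dim": run_retention(
            state_c, arena, swim, CuePresentation((far,)), IDENTITY, n_rats, seed
        ),
        "bright": run_retention(
            state_c, arena, swim, CuePresentation((near,)), IDENTITY, n_rats, seed
        ),
        "both": run_retention(
            state_c, arena, swim, CuePresentation((near, far)), IDENTITY, n_rats, seed
        ),
    }

    # Model (d): bright Far dominates, dim Near misread half the time.
    state_d = trained_state(arena, params, {near: 0.2, far: 0.8})
    policy = InterpretationPolicy(
        "probabilistic_misinterpretation",
        misinterpretation_probability=0.5,
        misinterpreted_cue=near,
    )
    out["misinterpret"] = {
        "dim": run_retention(
            state_d, arena, swim, CuePresentation((near,)), policy, n_rats, seed
        ),
        "bright": run_retention(
            state_d, arena, swim, CuePresentation((far,)), policy, n_rats, seed
        ),
        "both": run_retention(
            state_d, arena, swim, CuePresentation((near, far)), policy, n_rats, seed
        ),
    }
    return out


#: Overshadowing group roster: (training saliences key, probe cue).
_OVERSHADOW_GROUPS = (
    ("Far-Far", "far_only", ("Far",)),
    ("Near-Near", "near_only", ("Near",)),
    ("Both-Far", "both", ("Far",)),
    ("Both-Near", "both", ("Near",)),
    ("Both-Both", "both", ("Near", "Far")),
)


def overshadowing_experiment(
    arena: ArenaConfig | None = None,
    swim: SwimParams | None = None,
    learning_params: LearningParams | None = None,
    n_rats: int = 50,
    seed: int = 0,
):
    """Compound-versus-element training, probed with single cues.

    Five groups of n_rats: trained with the Far cue alone, the Near cue
    alone, or both cues, then probed with the Far cue, the Near cue or
    both.  A lone training cue takes the full salience share (alpha = 1),
    both-cue training splits it equally.  Returns (per-rat DataFrame
    with percent time in the platform area and its quadrant-equivalent
    areas, summary DataFrame of group means and sds).
    """
    arena = arena or make_default_arena()
    swim = swim or SwimParams()
    params = learning_params or LearningParams()
    near, far = "Near", "Far"
    training = {
        "far_only": {near: 0.0, far: 1.0},
        "near_only": {near: 1.0, far: 0.0},
        "both": {near: 0.5, far: 0.5},
    }
    states = {k: trained_state(arena, params, sal) for k, sal in training.items()}

    rows = []
    for gi, (group, train_key, present) in enumerate(_OVERSHADOW_GROUPS):
        state = states[train_key]
        for rat in range(n_rats):
            # offset the stream per group so groups are independent
            rng = rat_rng(seed, gi * 1_000_000 + rat)
            rec = simulate_trial(
                state,
                arena,
                swim,
                arena.probe_start,
                rng,
                platform_present=False,
                interpretation=IDENTITY,
                presentation=CuePresentation(present),
            )
            occ = trajectory_occupancy(rec.trajectory, arena, swim.dt)
            equiv = equivalent_area_occupancy(rec.trajectory, arena, swim.dt)
            rows.append(
                {
                    "group": group,
                    "rat": rat,
                    "pct_platform_area": 100.0 * occ["escape"],
                    **{f"pct_area_{q}": 100.0 * v for q, v in equiv.items()},
                }
            )
    per_rat = pd.DataFrame(rows)
    summary = (
        per_rat.groupby("group", sort=False)["pct_platform_area"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per_rat, summary
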