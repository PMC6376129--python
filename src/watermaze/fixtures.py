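"""Small deterministic fixtures for metric and inference checks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import master_rng
from .arena import ArenaConfig, make_default_arena
from .learning import LearningState

__all__ = [
    "straight_line_trajectory",
    "uniform_coverage_trajectory",
    "trained_learning_state",
    "untrained_learning_state",
    "generate_fixture",
]


def straight_line_trajectory(
    arena: ArenaConfig | None = None,
    dt: float = 0.5,
    step_cm: float = 10.0,
    start: str = "S",
) -> np.ndarray:
    """Straight swim from a rim start to the platform, rows (t, x, y, heading)."""
    from .arena import bearing_between

    arena = arena or make_default_arena()
    p0 = np.array(arena.start_point(start))
    p1 = np.array(arena.platform_center)
    heading = bearing_between(p0, p1)
    total = float(np.linalg.norm(p1 - p0))
    n = int(np.ceil(total / step_cm))
    rows = []
    for i in range(n + 1):
        frac = min(i * step_cm / total, 1.0)
        x, y = p0 + frac * (p1 - p0)
        rows.append((i * dt, x, y, heading))
    return np.array(rows)


def uniform_coverage_trajectory(
    arena: ArenaConfig | None = None,
    dt: float = 0.5,
    n_steps: int = 4000,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-trajectory whose midpoints are uniform over the pool disc."""
    arena = arena or make_default_arena()
    rng = master_rng(seed)
    r = arena.pool_radius * np.sqrt(rng.random(n_steps + 1))
    theta = rng.random(n_steps + 1) * 2 * np.pi
    x = r * np.sin(theta)
    y = r * np.cos(theta)
    t = np.arange(n_steps + 1) * dt
    heading = np.zeros_like(t)
    return np.column_stack([t, x, y, heading])


def trained_learning_state(
    arena: ArenaConfig | None = None, v: float = 0.95
) -> LearningState:
    """Near-asymptotic learner: equal V_use shares, both channels at v."""
    arena = arena or make_default_arena()
    n = len(arena.cue_ids)
    return LearningState.from_values(
        arena.cue_ids, v_use={c: v / n for c in arena.cue_ids}, v_dir=v, v_dist=v
    )


def untrained_learning_state(arena: ArenaConfig | None = None) -> LearningState:
    arena = arena or make_default_arena()
    return LearningState.zeros(arena.cue_ids)


def generate_fixture(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Write one named fixture as text; returns the written path.

    Kinds: "straight-line", "uniform-coverage", "trained-state",
    "untrained-state".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arena = make_default_arena()
    if kind == "straight-line":
        traj = straight_line_trajectory(arena)
        path = out_dir / "straight_line_trajectory.csv"
        pd.DataFrame(traj, columns=["t", "x", "y", "heading"]).to_csv(path, index=False)
    elif kind == "uniform-coverage":
        traj = uniform_coverage_trajectory(arena, seed=seed)
        path = out_dir / "uniform_coverage_trajectory.csv"
        pd.DataFrame(traj, columns=["t", "x", "y", "heading"]).to_csv(path, index=False)
    elif kind in ("trained-state", "untrained-state"):
        state = (
            trained_learning_state(arena)
            if kind == "trained-state"
            else untrained_learning_state(arena)
        )
        path = out_dir / f"{kind.replace('-', '_')}.csv"
        rows = [
            {
                "cue": c,
                "v_use": state.v_use[c],
                "v_dir": state.v_dir[c],
                "v_dist": state.v_dist[c],
            }
            for c in state.cue_ids
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return path
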