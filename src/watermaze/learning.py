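"""Rescorla-Wagner learning of cue usage and per-cue vector information.

Two kinds of association are learned per trial:

* cue usage (competitive): all cues share one asymptote lambda_use, and
  every cue's increment is driven by the same residual
  (lambda_use - sum_i V_i,use), so salient cues crowd out the others —
  the substrate of overshadowing;
* direction and distance knowledge (independent): each cue's channels
  converge to their own asymptotes regardless of the other cue.

Updates are trial-level: one increment per trial, V_new = V_old + dV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LearningParams",
    "LearningState",
    "update_use",
    "update_info",
    "run_training",
    "history_frame",
]


@dataclass(frozen=True)
class LearningParams:
    """Learning rates (per trial) and asymptotes, all dimensionless.

    Defaults put a two-equal-cue animal at >98.5% of every asymptote
    after the standard 40-trial protocol.
    """

    beta_use: float = 0.15
    beta_dir: float = 0.2
    beta_dist: float = 0.2
    lambda_use: float = 1.0
    lambda_dir: float = 1.0
    lambda_dist: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta_use", "beta_dir", "beta_dist"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("lambda_use", "lambda_dir", "lambda_dist"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class LearningState:
    """Per-cue associative strengths V_use, V_dir, V_dist."""

    cue_ids: tuple[str, ...]
    v_use: Mapping[str, float]
    v_dir: Mapping[str, float]
    v_dist: Mapping[str, float]

    @classmethod
    def zeros(cls, cue_ids: Iterable[str]) -> "LearningState":
        """Naive animal: every strength at zero."""
        ids = tuple(cue_ids)
        z = {c: 0.0 for c in ids}
        return cls(ids, dict(z), dict(z), dict(z))

    @classmethod
    def from_values(
        cls,
        cue_ids: Iterable[str],
        v_use: Mapping[str, float] | float = 0.0,
        v_dir: Mapping[str, float] | float = 0.0,
        v_dist: Mapping[str, float] | float = 0.0,
    ) -> "LearningState":
        """Build a state from per-cue dicts or uniform scalars."""
        ids = tuple(cue_ids)

        def expand(v):
            if isinstance(v, Mapping):
                return {c: float(v.get(c, 0.0)) for c in ids}
            return {c: float(v) for c in ids}

        return cls(ids, expand(v_use), expand(v_dir), expand(v_dist))

    def total_use(self) -> float:
        return sum(self.v_use[c] for c in self.cue_ids)


def update_use(
    state: LearningState,
    saliences: Mapping[str, float],
    params: LearningParams,
) -> LearningState:
    """One competitive cue-usage update (all cues simultaneously).

    Every cue's increment alpha_i * beta_use * (lambda_use - V_sigma)
    uses the pre-update total V_sigma.  If a large rate would push the
    total past lambda_use, the increments are rescaled proportionally so
    the bound is never violated.
    """
    v_sigma = state.total_use()
    residual = params.lambda_use - v_sigma
    deltas = {
        c: saliences.get(c, 0.0) * params.beta_use * residual for c in state.cue_ids
    }
    total_delta = sum(deltas.values())
    if residual > 0 and total_delta > residual:
        scale = residual / total_delta
        deltas = {c: d * scale for c, d in deltas.items()}
    new_use = {c: state.v_use[c] + deltas[c] for c in state.cue_ids}
    return LearningState(state.cue_ids, new_use, dict(state.v_dir), dict(state.v_dist))


def update_info(
    state: LearningState,
    saliences: Mapping[str, float],
    params: LearningParams,
) -> LearningState:
    """One direction/distance update; each cue relaxes toward its own
    asymptote independently of the other cues."""
    new_dir = {}
    new_dist = {}
    for c in state.cue_ids:
        a = saliences.get(c, 0.0)
        new_dir[c] = state.v_dir[c] + a * params.beta_dir * (
            params.lambda_dir - state.v_dir[c]
        )
        new_dist[c] = state.v_dist[c] + a * params.beta_dist * (
            params.lambda_dist - state.v_dist[c]
        )
    return LearningState(state.cue_ids, dict(state.v_use), new_dir, new_dist)


def run_training(
    arena,
    params: LearningParams,
    n_trials: int,
    saliences: Mapping[str, float] | None = None,
    initial: LearningState | None = None,
) -> list[LearningState]:
    """Apply the usage then the information update once per trial.

    Saliences default to those configured on the arena's cues.  Returns
    the state history: element 0 is the initial state, element t the
    state after trial t (length n_trials + 1).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if saliences is None:
        saliences = arena.saliences()
    state = initial if initial is not None else LearningState.zeros(arena.cue_ids)
    history = [state]
    for _ in range(n_trials):
        state = update_info(update_use(state, saliences, params), saliences, params)
        history.append(state)
    return history


def history_frame(history: Sequence[LearningState]) -> pd.DataFrame:
    """Tidy table of a learning history: (trial, cue, v_use, v_dir, v_dist)."""
    rows = []
    for t, st in enumerate(history):
        for c in st.cue_ids:
            rows.append(
                {
                    "trial": t,
                    "cue": c,
                    "v_use": st.v_use[c],
                    "v_dir": st.v_dir[c],
                    "v_dist": st.v_dist[c],
                }
            )
    return pd.DataFrame(rows)
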