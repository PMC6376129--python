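"""Calibrate the swimming-controller defaults.

The controller parameter values are not fixed by theory; they are chosen
so that simulated behaviour sits in the right regime:

* an untrained swimmer meanders over the pool and mostly fails to find
  the platform within a 60 s trial (day-1 behaviour);
* a well-trained swimmer released at the rim escapes in roughly 5-10 s;
* the four single-channel conditions (direction/distance x Near/Far at
  association 0.95) reproduce the reference mean latencies
  11 / 7.8 / 6.9 / 12.1 s.

Usage:
    python scripts/calibrate_swim.py eval            # score current defaults
    python scripts/calibrate_swim.py eval --n 500    # more precision
    python scripts/calibrate_swim.py grid            # coarse grid search

Edit CANDIDATES or the grid below to explore; once satisfied, freeze the
winning values as the SwimParams defaults.
"""

from __future__ import annotations

import argparse
import itertools
import sys
from dataclasses import replace

import numpy as np

from watermaze import LearningParams, LearningState, SwimParams, make_default_arena
from watermaze._rng import rat_rng
from watermaze.learning import run_training
from watermaze.metrics import cv_comparison
from watermaze.navigator import simulate_trial
from watermaze.scenarios import dissect_information

TARGETS = {
    ("direction", "Near"): 11.0,
    ("direction", "Far"): 7.8,
    ("distance", "Near"): 6.9,
    ("distance", "Far"): 12.1,
}


def untrained_mean(arena, swim, n, seed=123):
    state = LearningState.zeros(arena.cue_ids)
    lat = []
    for rat in range(n):
        rng = rat_rng(seed, rat)
        start = arena.start_positions[int(rng.integers(4))]
        lat.append(simulate_trial(state, arena, swim, start, rng).escape_latency)
    return float(np.mean(lat))


def score(arena, swim, n, seed=1, verbose=True):
    rows = {}
    err = 0.0
    for (channel, cue), target in TARGETS.items():
        frame, _ = dissect_information(arena, swim, channel, cue, 0.95, n, seed)
        m = frame["latency"].mean()
        s = frame["latency"].std()
        rows[(channel, cue)] = (m, s)
        err += abs(m - target) / target
        if verbose:
            print(f"  {channel:9s} {cue:4s}: mean {m:6.2f} (target {target:5.1f})  sd {s:5.2f}")
    if verbose:
        u = untrained_mean(arena, swim, max(n // 4, 50))
        print(f"  untrained mean latency: {u:6.1f} s")
    return err / len(TARGETS), rows


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("mode", choices=["eval", "grid"])
    ap.add_argument("--n", type=int, default=300)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    arena = make_default_arena()

    if args.mode == "eval":
        swim = SwimParams()
        print("current defaults:", swim)
        err, _ = score(arena, swim, args.n, args.seed)
        print(f"mean relative error vs reference means: {err:.3f}")
        # CV regime for the trained equal-cue cohort
        state = run_training(arena, LearningParams(), arena.n_trials())[-1]
        cv_lat, cv_occ = cv_comparison(state, arena, swim, max(args.n, 200), args.seed)
        print(f"trained cohort: CV(latency) = {cv_lat:.3f}, CV(time-in-area) = {cv_occ:.3f}, "
              f"ratio {cv_lat / cv_occ:.1f}")
        return

    grid = {
        "K": [0.45, 0.55, 0.65],
        "F": [0.5, 0.7],
        "rayleigh_scale": [8.0, 9.0, 10.5],
        "noise_std": [12.0, 14.0, 18.0],
        "A1": [0.25],
        "A2": [0.05],
    }
    best = None
    for combo in itertools.product(*grid.values()):
        kw = dict(zip(grid.keys(), combo))
        swim = SwimParams(**kw)
        err, _ = score(arena, swim, args.n, args.seed, verbose=False)
        u = untrained_mean(arena, swim, 80)
        ok = 30.0 <= u <= 55.0  # day-1 regime
        print(f"{kw} -> err {err:.3f}, untrained {u:.1f}{'' if ok else '  (untrained off-regime)'}")
        if ok and (best is None or err < best[0]):
            best = (err, kw)
    if best:
        print("\nbest:", best[1], "err", f"{best[0]:.3f}")


if __name__ == "__main__":
    sys.exit(main())
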