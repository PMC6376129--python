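import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from watermaze import (
    CuePresentation,
    LearningState,
    SwimParams,
    make_default_arena,
    run_acquisition,
    run_retention,
    select_cue,
    simulate_trial,
)
from watermaze._rng import rat_rng
from watermaze.metrics import trajectory_occupancy


def untrained(arena):
    return LearningState.zeros(arena.cue_ids)


def informed(arena, v=1.0):
    return LearningState.from_values(
        arena.cue_ids, v_use={c: 0.5 for c in arena.cue_ids}, v_dir=v, v_dist=v
    )


class TestSelectCue:
    def test_untrained_never_selects(self, arena, rng):
        st = untrained(arena)
        assert all(select_cue(st, rng) is None for _ in range(50))

    def test_degenerate_always_selects(self, arena, rng):
        st = LearningState.from_values(arena.cue_ids, v_use={"Near": 1.0})
        assert all(select_cue(st, rng) == "Near" for _ in range(50))

    def test_frequencies_match_strengths(self, arena):
        rng = np.random.default_rng(0)
        st = LearningState.from_values(arena.cue_ids, v_use={"Near": 0.7, "Far": 0.3})
        draws = [select_cue(st, rng) for _ in range(10000)]
        assert draws.count("Near") / 10000 == pytest.approx(0.7, abs=0.02)
        assert draws.count("Far") / 10000 == pytest.approx(0.3, abs=0.02)
        assert draws.count(None) == 0

    def test_invalid_total_rejected(self, arena, rng):
        st = LearningState.from_values(arena.cue_ids, v_use={"Near": 0.8, "Far": 0.5})
        with pytest.raises(ValueError):
            select_cue(st, rng)


class TestSimulateTrial:
    def test_immediate_escape_when_released_beside_platform(self, rng):
        """Released facing the centre with the platform directly on the
        first stretch of the swim path, escape happens within a step or
        two (contact is detected along the continuous path)."""
        arena = make_default_arena(platform_center=(0.0, -75.0))
        swim = SwimParams(uncued_reorient=False)  # keep the initial heading
        rec = simulate_trial(untrained(arena), arena, swim, "S", rng)
        assert rec.escape_latency <= 2 * swim.dt
        assert not rec.censored

    def test_untrained_trial_is_pure_random_walk(self, arena, swim, rng):
        rec = simulate_trial(untrained(arena), arena, swim, "N", rng,
                             platform_present=False)
        assert all(ep.kind == "random" for ep in rec.episodes)
        assert rec.censored
        assert rec.escape_latency == arena.trial_duration
        assert len(rec.trajectory) == int(arena.trial_duration / swim.dt) + 1

    def test_trajectory_stays_in_pool(self, arena, swim, rng):
        rec = simulate_trial(informed(arena, 0.8), arena, swim, "W", rng,
                             platform_present=False)
        radii = np.hypot(rec.trajectory[:, 1], rec.trajectory[:, 2])
        assert (radii <= arena.pool_radius * (1 + 1e-9)).all()

    def test_episode_grammar(self, arena, swim):
        """Random and cue-approach episodes are bounded by n_steps; every
        cue approach is followed by a goal approach unless the trial
        ended first."""
        rng = np.random.default_rng(3)
        st = LearningState.from_values(
            arena.cue_ids, v_use={"Near": 0.4, "Far": 0.3}, v_dir=0.7, v_dist=0.7
        )
        rec = simulate_trial(st, arena, swim, "E", rng, platform_present=False)
        eps = rec.episodes
        for i, ep in enumerate(eps):
            if ep.kind in ("random", "cue-approach"):
                assert ep.end_step - ep.start_step <= swim.n_steps
            else:
                assert ep.kind == "goal-approach"
                assert ep.end_step - ep.start_step <= swim.goal_budget_factor * swim.n_steps
                assert ep.guess is not None
            if ep.kind == "cue-approach" and i + 1 < len(eps):
                assert eps[i + 1].kind == "goal-approach"
        max_steps = int(arena.trial_duration / swim.dt)
        if eps[-1].kind == "cue-approach":
            assert eps[-1].end_step == max_steps  # cut off by trial end

    def test_latency_censoring_contract(self, arena, swim):
        for seed in range(5):
            rec = simulate_trial(informed(arena, 0.9), arena, swim, "S",
                                 np.random.default_rng(seed))
            assert rec.escape_latency <= arena.trial_duration
            assert rec.censored == (rec.escape_latency == arena.trial_duration) or (
                not rec.censored
            )

    def test_trained_beats_untrained_stochastically(self, arena, swim):
        """Latency distributions: fully informed < naive (stochastic
        dominance by rank test)."""
        lat_tr, lat_un = [], []
        for rat in range(60):
            r1, r2 = rat_rng(1, rat), rat_rng(2, rat)
            lat_tr.append(
                simulate_trial(informed(arena, 0.95), arena, swim, "S", r1).escape_latency
            )
            lat_un.append(
                simulate_trial(untrained(arena), arena, swim, "S", r2).escape_latency
            )
        p = mannwhitneyu(lat_tr, lat_un, alternative="less").pvalue
        assert p < 1e-6
        assert np.mean(lat_tr) < np.mean(lat_un) / 2


class TestAcquisition:
    def test_seeded_bit_reproducibility(self, arena, swim, learning_params):
        a, _, _ = run_acquisition(arena, swim, learning_params, 2, seed=5)
        b, _, _ = run_acquisition(arena, swim, learning_params, 2, seed=5)
        assert a.equals(b)

    def test_rat_streams_independent_of_cohort_size(self, arena, swim, learning_params):
        small, _, _ = run_acquisition(arena, swim, learning_params, 1, seed=9)
        large, _, _ = run_acquisition(arena, swim, learning_params, 3, seed=9)
        assert small.equals(large[large.rat == 0].reset_index(drop=True))

    def test_latency_decreases_over_training(self, arena, swim, learning_params):
        frame, final, history = run_acquisition(arena, swim, learning_params, 15, seed=3)
        day1 = frame[frame.day == 1].latency.mean()
        day10 = frame[frame.day == 10].latency.mean()
        assert day1 > day10
        assert day10 < 15.0
        assert len(history) == arena.n_trials() + 1

    def test_daily_start_permutation_covers_all_starts(self, arena, swim, learning_params):
        frame, _, _ = run_acquisition(arena, swim, learning_params, 1, seed=2)
        for _, day_frame in frame.groupby("day"):
            assert set(day_frame.start) == {"N", "S", "E", "W"}


class TestRetention:
    def test_quadrant_fractions_sum_to_one_per_rat(self, arena, swim, trained_state):
        occ = run_retention(trained_state, arena, swim, n_rats=10, seed=4)
        totals = occ[["NE", "SE", "SW", "NW"]].sum(axis=1)
        assert np.allclose(totals, 1.0)

    def test_trained_cohort_prefers_target_quadrant(self, arena, swim, trained_state):
        occ = run_retention(trained_state, arena, swim, n_rats=30, seed=4)
        means = {q: occ[q].mean() for q in ("NE", "SE", "SW", "NW")}
        assert means["NE"] == max(means.values())

    def test_probe_runs_full_duration(self, arena, swim, trained_state):
        occ, records = run_retention(trained_state, arena, swim, n_rats=3, seed=4,
                                     keep_records=True)
        for rec in records:
            assert rec.censored
            assert len(rec.trajectory) == int(arena.trial_duration / swim.dt) + 1

    def test_presentation_position_override(self, arena, swim, trained_state):
        """A repositioned (swapped) cue anchors approaches at its new
        location; the run completes and stays normalized."""
        swap = CuePresentation(("Near",), positions={"Near": arena.cue("Far").position})
        occ = run_retention(trained_state, arena, swim, manipulation=swap,
                            n_rats=5, seed=1)
        assert np.allclose(occ[["NE", "SE", "SW", "NW"]].sum(axis=1), 1.0)
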