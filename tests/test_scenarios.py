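import numpy as np
import pytest

from watermaze import LearningParams, make_default_arena
from watermaze.scenarios import (
    IDENTITY,
    INDISTINGUISHABLE,
    InterpretationPolicy,
    ScenarioSpec,
    cue_removal_retention,
    dissect_information,
    overshadowing_experiment,
    salience_sweep,
    trained_state,
    uncertainty_models,
)

QUADS = ("NE", "SE", "SW", "NW")


def quad_means(df):
    return {q: df[q].mean() for q in QUADS}


class TestPolicies:
    def test_validation(self):
        with pytest.raises(ValueError):
            InterpretationPolicy("telepathy")
        with pytest.raises(ValueError):
            InterpretationPolicy("probabilistic_misinterpretation",
                                 misinterpretation_probability=1.5)

    def test_generalize_at_even_split_equals_indistinguishable(self, arena, swim,
                                                               learning_params):
        """With a 50:50 salience split the salience-generalization policy
        must produce exactly the indistinguishable policy's behaviour."""
        common = dict(
            name="x",
            saliences={"Near": 0.5, "Far": 0.5},
            retention_conditions={"Near": ("Near",)},
            n_rats=8,
            seed=3,
        )
        a = cue_removal_retention(
            ScenarioSpec(interpretation=INDISTINGUISHABLE, **common),
            arena, swim, learning_params)
        b = cue_removal_retention(
            ScenarioSpec(interpretation=InterpretationPolicy("generalize_to_salient"),
                         **common),
            arena, swim, learning_params)
        assert a["Near"].equals(b["Near"])


class TestDissection:
    def test_full_knowledge_is_near_direct_swim(self, arena, swim):
        frame, cloud = dissect_information(arena, swim, "both", "Near", 1.0,
                                           n_rats=40, seed=0)
        assert frame.latency.mean() < 10.0
        assert not frame.censored.any()
        assert np.allclose(cloud[:, :2], arena.platform_center, atol=1e-6)

    def test_distance_near_guesses_concentrate_in_target_quadrant(self, arena, swim):
        _, cloud = dissect_information(arena, swim, "distance", "Near", 0.95,
                                       n_rats=1, seed=0, n_guesses=1500)
        bear = np.degrees(np.arctan2(cloud[:, 0], cloud[:, 1])) % 360
        assert (bear < 90).mean() > 0.9

    def test_strength_bounds(self, arena, swim):
        with pytest.raises(ValueError):
            dissect_information(arena, swim, "direction", "Near", 1.2, 1, 0)
        with pytest.raises(ValueError):
            dissect_information(arena, swim, "sideways", "Near", 0.5, 1, 0)


@pytest.fixture(scope="module")
def removal_tables(arena, swim, learning_params):
    spec = ScenarioSpec(
        name="removal",
        saliences={"Near": 0.5, "Far": 0.5},
        retention_conditions={"both": ("Near", "Far"), "Near": ("Near",),
                              "Far": ("Far",)},
        interpretation=INDISTINGUISHABLE,
        n_rats=30,
        seed=0,
    )
    return cue_removal_retention(spec, arena, swim, learning_params)


@pytest.fixture(scope="module")
def uncertainty_tables(arena, swim, learning_params):
    return uncertainty_models(arena, swim, learning_params, n_rats=25, seed=0)


class TestCueRemoval:
    def test_both_cues_present_targets_ne(self, removal_tables):
        m = quad_means(removal_tables["both"])
        assert m["NE"] == max(m.values())

    def test_near_only_probe_splits_ne_se(self, removal_tables):
        m = quad_means(removal_tables["Near"])
        assert m["NE"] > m["SW"] and m["NE"] > m["NW"]
        assert m["SE"] > m["SW"] and m["SE"] > m["NW"]

    def test_far_only_probe_splits_ne_nw(self, removal_tables):
        m = quad_means(removal_tables["Far"])
        assert m["NE"] > m["SW"] and m["NE"] > m["SE"]
        assert m["NW"] > m["SW"] and m["NW"] > m["SE"]

    def test_identity_policy_targets_ne_with_either_cue(self, arena, swim,
                                                        learning_params):
        spec = ScenarioSpec(
            name="identity",
            saliences={"Near": 0.5, "Far": 0.5},
            retention_conditions={"Near": ("Near",), "Far": ("Far",)},
            interpretation=IDENTITY,
            n_rats=25,
            seed=1,
        )
        tables = cue_removal_retention(spec, arena, swim, learning_params)
        for cond in ("Near", "Far"):
            m = quad_means(tables[cond])
            assert m["NE"] == max(m.values())

    def test_salient_cue_generalization_misdirects_search(self, arena, swim,
                                                          learning_params):
        """Trained with only the Near cue salient, a presented Far cue is
        read as the Near one and search lands in NW; the mirror setup
        sends a presented Near cue's search into SE."""
        near_sal = ScenarioSpec(
            name="near-salient",
            saliences={"Near": 1.0, "Far": 0.0},
            retention_conditions={"Far": ("Far",)},
            interpretation=InterpretationPolicy("generalize_to_salient"),
            n_rats=25, seed=2,
        )
        m = quad_means(cue_removal_retention(near_sal, arena, swim,
                                             learning_params)["Far"])
        assert m["NW"] == max(m.values())

        far_sal = ScenarioSpec(
            name="far-salient",
            saliences={"Near": 0.0, "Far": 1.0},
            retention_conditions={"Near": ("Near",)},
            interpretation=InterpretationPolicy("generalize_to_salient"),
            n_rats=25, seed=2,
        )
        m = quad_means(cue_removal_retention(far_sal, arena, swim,
                                             learning_params)["Near"])
        assert m["SE"] == max(m.values())

    def test_unknown_cue_in_condition_rejected(self, arena, swim, learning_params):
        spec = ScenarioSpec(name="bad", saliences={"Near": 0.5, "Far": 0.5},
                            retention_conditions={"x": ("Moon",)})
        with pytest.raises(ValueError):
            cue_removal_retention(spec, arena, swim, learning_params)


class TestUncertaintyModels:
    def test_ignored_dim_cue_gives_unstructured_search(self, uncertainty_tables):
        m = quad_means(uncertainty_tables["ignore_dim"]["dim"])
        assert max(m.values()) < 0.45
        assert min(m.values()) > 0.10

    def test_bright_cue_targets_ne(self, uncertainty_tables):
        for model in ("ignore_dim", "misinterpret"):
            m = quad_means(uncertainty_tables[model]["bright"])
            assert m["NE"] == max(m.values())

    def test_misinterpreted_dim_cue_splits_ne_se(self, uncertainty_tables):
        m = quad_means(uncertainty_tables["misinterpret"]["dim"])
        assert m["NE"] > m["SW"] and m["NE"] > m["NW"]
        assert m["SE"] > m["SW"] and m["SE"] > m["NW"]


class TestOvershadowing:
    def test_orderings_and_competition(self, arena, swim, learning_params):
        per_rat, summary = overshadowing_experiment(arena, swim, learning_params,
                                                    n_rats=20, seed=0)
        m = dict(zip(summary["group"], summary["mean"]))
        assert m["Far-Far"] > m["Both-Far"]
        assert m["Near-Near"] > m["Both-Near"]
        assert set(per_rat.group) == {"Far-Far", "Near-Near", "Both-Far",
                                      "Both-Near", "Both-Both"}
        # single-cue training saturates that cue's usage strength
        solo = trained_state(arena, learning_params, {"Near": 0.0, "Far": 1.0})
        assert solo.v_use["Far"] == pytest.approx(learning_params.lambda_use, abs=1e-2)
        assert solo.v_use["Near"] == 0.0

    def test_deterministic_given_seed(self, arena, swim, learning_params):
        a = overshadowing_experiment(arena, swim, learning_params, n_rats=5, seed=3)[0]
        b = overshadowing_experiment(arena, swim, learning_params, n_rats=5, seed=3)[0]
        assert a.equals(b)


class TestSalienceSweep:
    def test_concentration_grows_with_strength(self, arena, learning_params):
        frame, heatmaps = salience_sweep(
            arena, strengths=[0.1, 0.3, 0.5], ratios=[(0.5, 0.5)],
            channels=("direction", "distance"), n_samples=1500, seed=0,
            learning_params=learning_params,
        )
        ent = frame.sort_values("strength").entropy.to_numpy()
        assert (np.diff(ent) < 0).all()
        ne = frame.sort_values("strength").ne_fraction.to_numpy()
        assert (np.diff(ne) >= 0).all()
        assert len(heatmaps) == 3

    def test_single_channel_sweeps_differ_in_shape(self, arena, learning_params):
        fd, _ = salience_sweep(arena, [0.5], [(0.83, 0.17)], ("distance",),
                               1500, 0, learning_params)
        assert fd.ne_fraction.iloc[0] > 0.5  # near-dominant distance: NE confined

    def test_ratio_must_sum_to_one(self, arena):
        with pytest.raises(ValueError):
            salience_sweep(arena, [0.1], [(0.6, 0.6)])
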