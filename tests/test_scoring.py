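import numpy as np
import pytest

import oracles
from conftest import make_lexicon, random_rotation, rotate_lexicon
from embinfer import (
    ChwillaPair,
    DegenerateDataError,
    McKoonItem,
    MetusalemItem,
    StimulusSet,
    SyntheticConfig,
    generate_world,
    run_task_battery,
    score_chwilla,
    score_mckoon_inference,
    score_metusalem_inference,
    score_metusalem_semantics,
)


class TestWorkedToys:
    def test_sentence_semantics_hand_example(self):
        # sentence vector (1,0); expected collinear, related orthogonal,
        # unrelated antiparallel: score = 1 - (0 + (-1))/2 = 1.5
        lex = make_lexicon(
            {"s1": [1, 0], "ew": [1, 0], "rw": [0, 1], "uw": [-1, 0], "s2": [1, 0]}
        )
        items = StimulusSet(
            "metusalem",
            [
                MetusalemItem("i1", "", "s1 s2", "ew", "rw", "uw"),
                MetusalemItem("i2", "", "s1 s2", "rw", "ew", "uw"),
            ],
        )
        res = score_metusalem_semantics(lex, items)
        assert res.trial_scores[0].score == pytest.approx(1.5, abs=1e-12)
        assert res.trial_scores[1].score == pytest.approx(0.0, abs=1e-12)

    def test_discourse_rescue_hand_example(self):
        # sentence (1,0); context mean (0.6,0.8) after adding one discourse
        # token (0.2,1.6): score = (0.8 - 0.6) - (0 - 1) = 1.2
        lex = make_lexicon(
            {"s1": [1, 0], "d1": [0.2, 1.6], "ew": [1, 1], "rw": [0, 1], "uw": [1, 0]}
        )
        items = StimulusSet(
            "metusalem",
            [
                MetusalemItem("i1", "d1", "s1", "ew", "rw", "uw"),
                MetusalemItem("i2", "d1", "s1", "ew", "uw", "rw"),
            ],
        )
        res = score_metusalem_inference(lex, items)
        assert res.trial_scores[0].score == pytest.approx(1.2, abs=1e-12)
        assert res.trial_scores[1].score == pytest.approx(-1.2, abs=1e-12)

    def test_word_order_hand_example(self):
        # context mean (1,0), control mean (0,1), target (1,0): score = 1 - 0
        lex = make_lexicon({"c1": [1, 0], "c2": [0, 1], "tw": [1, 0]})
        items = StimulusSet(
            "mckoon",
            [McKoonItem("i1", "c1", "c2", "tw"), McKoonItem("i2", "c2", "c1", "tw")],
        )
        res = score_mckoon_inference(lex, items)
        assert res.trial_scores[0].score == pytest.approx(1.0, abs=1e-12)
        assert res.trial_scores[1].score == pytest.approx(-1.0, abs=1e-12)

    def test_identical_targets_score_zero(self):
        lex = make_lexicon(
            {"s1": [1, 1], "ew": [2, 0], "rw": [1, 0], "uw": [3, 0], "e2": [0, 1]}
        )
        items = StimulusSet(
            "metusalem",
            [
                MetusalemItem("i1", "", "s1", "ew", "rw", "uw"),
                MetusalemItem("i2", "", "s1", "e2", "rw", "uw"),
            ],
        )
        # item i1: all three targets collinear, so the expected word has no
        # advantage and the score is exactly 0
        res = score_metusalem_semantics(lex, items)
        assert res.trial_scores[0].score == pytest.approx(0.0, abs=1e-12)


class TestExactNulls:
    def test_empty_discourse_cancels_rescue(self):
        lex = make_lexicon({"s1": [1, 0.5], "ew": [1, 1], "rw": [0, 1], "uw": [1, 0]})
        items = StimulusSet(
            "metusalem",
            [MetusalemItem(f"i{k}", "", "s1", "ew", "rw", "uw") for k in range(3)],
        )
        res = score_metusalem_inference(lex, items)
        assert all(s.score == 0.0 for s in res.trial_scores)
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_static_backend_cancels_word_order(self, small_world):
        res = score_mckoon_inference(small_world.lexicon, small_world.stimulus_sets["mckoon"])
        assert all(s.score == 0.0 for s in res.trial_scores)
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_degenerate_variance_with_effect_raises(self):
        vecs = {}
        pairs = []
        for i in range(3):
            vecs[f"r{i}a"] = np.array([1.0, 0.0]); vecs[f"r{i}b"] = np.array([2.0, 0.0])
            vecs[f"u{i}a"] = np.array([1.0, 0.0]); vecs[f"u{i}b"] = np.array([0.0, 1.0])
            pairs.append(ChwillaPair(f"r{i}a", f"r{i}b", True))
            pairs.append(ChwillaPair(f"u{i}a", f"u{i}b", False))
        lex = make_lexicon(vecs)
        with pytest.raises(DegenerateDataError, match="zero within-group variance"):
            score_chwilla(lex, StimulusSet("chwilla", pairs))


class TestOracleEquivalence:
    """Per-trial scores vs brute-force loops; t stats vs textbook formulas."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trial_scores_match_brute_force(self, seed):
        cfg = SyntheticConfig(
            dim=6, vocab_size=10, n_chwilla_pairs=8, n_metusalem_items=8,
            n_mckoon_items=6, seed=seed,
        )
        w = generate_world(cfg)
        lex = w.lexicon

        res = score_chwilla(lex, w.stimulus_sets["chwilla"])
        rel, unr = oracles.chwilla_scores_brute(lex, w.stimulus_sets["chwilla"])
        got_rel = [s.score for s in res.trial_scores if s.components["related"]]
        got_unr = [s.score for s in res.trial_scores if not s.components["related"]]
        np.testing.assert_allclose(got_rel, rel, atol=1e-12)
        np.testing.assert_allclose(got_unr, unr, atol=1e-12)
        t, p, df = oracles.two_sample_t_brute(rel, unr)
        assert res.t_stat == pytest.approx(t, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)
        assert res.df == df

        met = w.stimulus_sets["metusalem"]
        res = score_metusalem_semantics(lex, met)
        np.testing.assert_allclose(
            [s.score for s in res.trial_scores],
            oracles.metusalem_sem_scores_brute(lex, met),
            atol=1e-12,
        )
        res = score_metusalem_inference(lex, met)
        brute = oracles.metusalem_inf_scores_brute(lex, met)
        np.testing.assert_allclose(
            [s.score for s in res.trial_scores], brute, atol=1e-12
        )
        ctx = [s.components["D-R"] - s.components["D-U"] for s in res.trial_scores]
        sen = [s.components["S-R"] - s.components["S-U"] for s in res.trial_scores]
        t, p, df = oracles.paired_t_brute(ctx, sen)
        assert res.t_stat == pytest.approx(t, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)
        assert res.df == df

    def test_trial_score_recomputable_from_components(self, small_world):
        res = score_metusalem_inference(
            small_world.lexicon, small_world.stimulus_sets["metusalem"]
        )
        for s in res.trial_scores:
            c = s.components
            assert s.score == pytest.approx(
                (c["D-R"] - c["D-U"]) - (c["S-R"] - c["S-U"]), abs=1e-12
            )
            assert all(-1.0 <= v <= 1.0 for v in c.values())


class TestGeometry:
    def test_all_tasks_rotation_invariant(self, small_world):
        rng = np.random.default_rng(9)
        q = random_rotation(rng, small_world.lexicon.dim)
        rotated = rotate_lexicon(small_world.lexicon, q)
        for scorer, proto in [
            (score_chwilla, "chwilla"),
            (score_metusalem_semantics, "metusalem"),
            (score_metusalem_inference, "metusalem"),
            (score_mckoon_inference, "mckoon"),
        ]:
            base = scorer(small_world.lexicon, small_world.stimulus_sets[proto])
            rot = scorer(rotated, small_world.stimulus_sets[proto])
            np.testing.assert_allclose(
                [s.score for s in base.trial_scores],
                [s.score for s in rot.trial_scores],
                atol=1e-10,
            )


class TestPlantedEffects:
    def test_semantic_t_monotone_in_planted_advantage(self):
        ts = []
        for delta in (0.1, 0.3, 0.5):
            cfg = SyntheticConfig(
                related_gap=delta, n_metusalem_items=24, vocab_size=0, seed=5
            )
            w = generate_world(cfg, protocols=("metusalem",))
            ts.append(score_metusalem_semantics(w.lexicon, w.stimulus_sets["metusalem"]).t_stat)
        assert ts[0] > 0 and ts[0] < ts[1] < ts[2]

    def test_rescue_profile_shows_discourse_advantage(self, small_world):
        res = score_metusalem_inference(
            small_world.lexicon, small_world.stimulus_sets["metusalem"]
        )
        m = res.profile.means
        assert set(m) == set(res.profile.KEYS)
        assert all(-1.0 <= v <= 1.0 for v in m.values())
        # the discourse rescues the related word; the sentence alone does not
        assert (m["D-R"] - m["D-U"]) > (m["S-R"] - m["S-U"]) + 0.1


class TestBattery:
    def test_battery_returns_four_finite_scores(self, small_world):
        rec = run_task_battery(small_world.lexicon, small_world.stimulus_sets)
        assert set(rec.t_scores) == {
            "chwilla_sem", "metusalem_sem", "metusalem_inf", "mckoon_inf"
        }
        assert all(np.isfinite(v) for v in rec.t_scores.values())
        assert rec.model_class == "static"

    def test_battery_deterministic(self, small_world):
        a = run_task_battery(small_world.lexicon, small_world.stimulus_sets)
        b = run_task_battery(small_world.lexicon, small_world.stimulus_sets)
        assert a == b

    def test_failing_task_named_in_error(self, small_world):
        crippled = dict(small_world.lexicon.vectors)
        missing = small_world.stimulus_sets["metusalem"].items[0].expected
        del crippled[missing]
        from embinfer import StaticLexicon

        lex = StaticLexicon(vectors=crippled, dim=small_world.lexicon.dim)
        with pytest.raises(RuntimeError, match="metusalem_sem"):
            run_task_battery(lex, small_world.stimulus_sets)

    def test_welch_flag(self, small_world):
        pooled = score_chwilla(small_world.lexicon, small_world.stimulus_sets["chwilla"])
        welch = score_chwilla(
            small_world.lexicon, small_world.stimulus_sets["chwilla"], welch=True
        )
        assert welch.df <= pooled.df
        assert welch.t_stat != 0.0
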