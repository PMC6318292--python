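"""Attention-model primitives, the sequence likelihood against an
independent step-by-step oracle, and the simplex invariants."""

import math

import numpy as np
import pytest

from wcstmap.model import (
    DegenerateFeedbackError,
    ModelAgent,
    ModelConfig,
    ModelParams,
    ModelVariant,
    choice_probabilities,
    feedback_signal,
    sequence_loglik,
    simulate_participant,
    update_attention,
)
from wcstmap.task import Card, DeckConfig, ExaminerConfig, build_deck, match_vector

NO_FLOOR = ModelConfig(choice_floor=0.0)


# ---------------------------------------------------------------------------
# independent oracle: plain-Python trace of the update equations

def oracle_loglik(params, trials, choice_floor=1e-3, attention_floor=1e-6):
    a = [1.0 / 3.0] * 3
    total = 0.0
    for rec in trials:
        m = list(rec.match)
        powered = [ai**params.d for ai in a]
        raw = sum(mi * pi for mi, pi in zip(m, powered)) / sum(powered)
        total += math.log((1.0 - choice_floor) * raw + choice_floor / 4.0)
        weights = [ai**params.f for ai in a]
        if rec.feedback == "right":
            support = m
            rate = params.r
        else:
            support = [1 - mi for mi in m]
            rate = params.p
        w = [si * wi for si, wi in zip(support, weights)]
        ws = sum(w)
        if ws > 0:
            a = [(1 - rate) * ai + rate * wi / ws for ai, wi in zip(a, w)]
        a = [min(max(ai, attention_floor), 1.0) for ai in a]
        s = sum(a)
        a = [ai / s for ai in a]
    return total


#: matches three distinct piles: color -> pile 2, form -> pile 1, number -> pile 3
CARD = Card("green", "triangle", 3)


class TestChoiceProbabilities:
    def test_uniform_attention_spreads_over_matching_piles(self):
        p = choice_probabilities(np.full(3, 1 / 3), d=2.0, card=CARD, config=NO_FLOOR)
        assert np.allclose(p, [1 / 3, 1 / 3, 1 / 3, 0.0])

    def test_d_equal_one_is_proportional(self):
        p = choice_probabilities(np.array([0.6, 0.3, 0.1]), d=1.0, card=CARD, config=NO_FLOOR)
        # color weight 0.6 -> pile 2; form 0.3 -> pile 1; number 0.1 -> pile 3
        assert np.allclose(p, [0.3, 0.6, 0.1, 0.0])

    def test_d_equal_two_sharpens(self):
        p = choice_probabilities(np.array([0.6, 0.3, 0.1]), d=2.0, card=CARD, config=NO_FLOOR)
        expected = np.array([0.09, 0.36, 0.01, 0.0]) / 0.46
        assert np.allclose(p, expected, atol=1e-12)

    def test_two_dimension_match_pools_weights(self):
        # (green, triangle, 1) matches pile 1 on form AND number
        card = Card("green", "triangle", 1)
        p = choice_probabilities(np.array([0.6, 0.3, 0.1]), d=1.0, card=card, config=NO_FLOOR)
        assert np.allclose(p, [0.4, 0.6, 0.0, 0.0])

    def test_floor_mixes_uniform(self):
        cfg = ModelConfig(choice_floor=0.2)
        p = choice_probabilities(np.array([1.0, 0.0, 0.0]), d=1.0, card=CARD, config=cfg)
        assert p.min() >= 0.05 - 1e-12
        assert abs(p.sum() - 1.0) < 1e-9

    def test_sums_to_one_for_random_states(self):
        rng = np.random.default_rng(0)
        deck = build_deck(DeckConfig(copies=1))
        for _ in range(200):
            a = rng.dirichlet([1, 1, 1])
            d = rng.uniform(0, 5)
            card = deck[rng.integers(64)]
            p = choice_probabilities(a, d, card)
            assert abs(p.sum() - 1.0) < 1e-9
            assert p.min() >= ModelConfig().choice_floor / 4 - 1e-12


class TestFeedbackSignal:
    def test_zero_focus_spreads_uniformly_over_nonmatching(self):
        s = feedback_signal(np.full(3, 1 / 3), f=0.0, m=np.array([1, 0, 0]), feedback="wrong")
        assert np.allclose(s, [0, 0.5, 0.5])

    def test_single_support_right(self):
        for f in (0.0, 1.0, 3.7):
            s = feedback_signal(np.array([0.2, 0.5, 0.3]), f=f, m=np.array([1, 0, 0]), feedback="right")
            assert np.allclose(s, [1, 0, 0])

    def test_focus_one_weights_by_attention(self):
        s = feedback_signal(np.array([0.5, 0.3, 0.2]), f=1.0, m=np.array([1, 0, 0]), feedback="wrong")
        assert np.allclose(s, [0, 0.6, 0.4])

    def test_empty_support_raises(self):
        with pytest.raises(DegenerateFeedbackError):
            feedback_signal(np.full(3, 1 / 3), f=1.0, m=np.array([1, 1, 1]), feedback="wrong")
        with pytest.raises(DegenerateFeedbackError):
            feedback_signal(np.full(3, 1 / 3), f=1.0, m=np.array([0, 0, 0]), feedback="right")


class TestUpdateAttention:
    def test_zero_rate_keeps_state(self):
        a = np.array([0.5, 0.3, 0.2])
        params = ModelParams(0.0, 0.5, 1.0, 1.0)
        out = update_attention(a, np.array([0, 0.6, 0.4]), params, "right")
        assert np.allclose(out, a)

    def test_full_rate_replaces_state(self):
        params = ModelParams(0.5, 1.0, 1.0, 1.0)
        s = np.array([0.0, 0.6, 0.4])
        out = update_attention(np.array([0.5, 0.3, 0.2]), s, params, "wrong")
        # clamp at the attention floor keeps the zero entry epsilon-positive
        assert np.allclose(out, s, atol=1e-5)

    def test_half_rate_convex_combination(self):
        params = ModelParams(0.5, 0.5, 1.0, 1.0)
        out = update_attention(
            np.array([0.5, 0.3, 0.2]), np.array([0.0, 0.6, 0.4]), params, "wrong"
        )
        assert np.allclose(out, [0.25, 0.45, 0.30], atol=1e-6)

    def test_larger_punishment_rate_moves_closer_to_signal(self):
        a = np.array([0.6, 0.25, 0.15])
        s = np.array([0.0, 0.5, 0.5])
        dists = []
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            params = ModelParams(0.3, p, 1.0, 1.0)
            out = update_attention(a, s, params, "wrong")
            dists.append(np.abs(out - s).sum())
        assert all(d2 < d1 for d1, d2 in zip(dists, dists[1:]))


class TestSequenceLoglik:
    def test_empty_log_is_zero(self):
        assert sequence_loglik(ModelParams(0.3, 0.7, 2.0, 1.0), []) == 0.0

    def test_matches_independent_trace(self, random_logs):
        rng = np.random.default_rng(7)
        cfg = ModelConfig()
        for trials in random_logs:
            params = ModelParams(
                rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 5), rng.uniform(0, 5)
            )
            got = sequence_loglik(params, trials, config=cfg)
            want = oracle_loglik(params, trials, cfg.choice_floor, cfg.attention_floor)
            assert got == pytest.approx(want, abs=1e-10)

    def test_finite_even_for_no_match_choices(self, examiner):
        # force a log containing a choice of the pile sharing no attribute
        card = Card("green", "triangle", 1)
        from wcstmap.task import TrialRecord

        rec = TrialRecord(1, card, 3, "wrong", "color", tuple(match_vector(card, 3)))
        ll = sequence_loglik(ModelParams(0.2, 0.8, 3.0, 1.0), [rec])
        assert np.isfinite(ll)
        assert ll >= math.log(ModelConfig().choice_floor / 4.0) - 1e-9

    def test_variant_constraints_apply(self, random_logs):
        trials = random_logs[0]
        params = ModelParams(0.4, 0.9, 2.0, 1.5)
        rrdf = sequence_loglik(params, trials, variant=ModelVariant.RRDF)
        tied = sequence_loglik(ModelParams(0.4, 0.4, 2.0, 1.5), trials)
        assert rrdf == pytest.approx(tied, abs=1e-12)
        rpd0 = sequence_loglik(params, trials, variant=ModelVariant.RPD0)
        unfocused = sequence_loglik(ModelParams(0.4, 0.9, 2.0, 0.0), trials)
        assert rpd0 == pytest.approx(unfocused, abs=1e-12)


class TestSimplexInvariants:
    def test_attention_state_stays_on_simplex_under_many_updates(self):
        rng = np.random.default_rng(11)
        a = np.full(3, 1 / 3)
        for _ in range(10_000):
            m = np.zeros(3)
            m[rng.integers(3)] = 1
            feedback = "right" if rng.random() < 0.5 else "wrong"
            if feedback == "wrong" and m.sum() == 3:
                continue
            params = ModelParams(rng.uniform(0, 1), rng.uniform(0, 1), 1.0, rng.uniform(0, 5))
            s = feedback_signal(a, params.f, m, feedback)
            a = update_attention(a, s, params, feedback)
            assert abs(a.sum() - 1.0) < 1e-9
            assert a.min() >= 0


class TestSimulation:
    def test_same_seed_reproduces_log(self, default_deck, examiner):
        params = ModelParams(0.3, 0.7, 2.0, 1.0)
        a = simulate_participant(params, default_deck, examiner, seed=3)
        b = simulate_participant(params, default_deck, examiner, seed=3)
        assert a.trials == b.trials

    def test_chance_agent_never_completes_a_category(self, default_deck, examiner):
        cfg = ModelConfig(choice_floor=1.0)  # pure uniform lapse -> chance
        ncats = [
            simulate_participant(ModelParams(0, 0, 0, 0), default_deck, examiner, seed=s, config=cfg)
            .categories_completed
            for s in range(10)
        ]
        assert max(ncats) == 0

    def test_ideal_parameters_reach_ceiling(self, examiner):
        # low R keeps the belief stable once correct; high P, sharp choices,
        # unfocused updating -> near-ceiling performance
        params = ModelParams(0.1, 1.0, 5.0, 0.0)
        ncats = []
        for s in range(30):
            deck = build_deck(DeckConfig(seed=s))
            res = simulate_participant(params, deck, examiner, seed=s)
            ncats.append(res.categories_completed)
        assert np.mean(ncats) > 5

    def test_model_agent_state_tracks_updates(self, default_deck, examiner):
        agent = ModelAgent(ModelParams(0.3, 0.7, 2.0, 1.0), seed=0)
        from wcstmap.task import administer

        administer(agent, default_deck, examiner)
        assert abs(agent.attention.sum() - 1.0) < 1e-9


class TestVariants:
    def test_free_parameter_counts(self):
        assert ModelVariant.RPDF.n_free == 4
        for v in (ModelVariant.RRDF, ModelVariant.RP1F, ModelVariant.RPD0):
            assert v.n_free == 3

    def test_materialization(self):
        p = ModelVariant.RRDF.to_params(np.array([0.4, 2.0, 1.0]))
        assert p.r == p.p == 0.4
        p = ModelVariant.RP1F.to_params(np.array([0.2, 0.6, 1.5]))
        assert p.d == 1.0
        p = ModelVariant.RPD0.to_params(np.array([0.2, 0.6, 2.0]))
        assert p.f == 0.0

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ModelParams(1.2, 0.5, 1.0, 1.0).validate()
        with pytest.raises(ValueError):
            ModelParams(0.5, 0.5, 6.0, 1.0).validate()
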