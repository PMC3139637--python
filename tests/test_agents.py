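"""Agent policies: reactivity sampling, the four models, mixtures, baselines."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from scipy import stats as sps

from gbsearch.agents import (
    DecayMap,
    HeldReactivityAgent,
    Model1Agent,
    Model2Agent,
    Model3Agent,
    Model4Agent,
    ModelParams,
    NormativeAgent,
    apply_reaction,
    initial_guess,
    make_team,
    normative_numeric_react,
    sample_raw_reactivity,
    solo_bisection_exact_mean,
    solo_bisection_expected_rounds,
)
from gbsearch.engine import (
    Direction,
    FeedbackMode,
    FeedbackSignal,
    GameConfig,
    play_game,
)

TOO_LOW = FeedbackSignal(Direction.TOO_LOW)
TOO_HIGH = FeedbackSignal(Direction.TOO_HIGH)


def enumerate_support(guess: int, direction: Direction, clip: int = 20) -> set[int]:
    """Brute-force support of the rejection sampler: stated range within +-clip."""
    if direction is Direction.TOO_LOW:
        raw = range(0, 50 - guess + 1)
    else:
        raw = range(-guess, 1)
    return {r for r in raw if abs(r) <= clip}


class TestInitialGuess:
    def test_always_within_guess_bounds(self):
        rng = random.Random(0)
        for n in (1, 2, 7, 17):
            draws = [initial_guess(ModelParams(), n, rng) for _ in range(500)]
            assert all(0 <= g <= 50 for g in draws)

    def test_degenerate_distribution_is_constant(self):
        params = ModelParams(
            initial_mean_total=10.0, initial_sigma_frac=0.0, initial_sigma_min=0.0
        )
        assert all(
            initial_guess(params, 1, random.Random(s)) == 10 for s in range(20)
        )

    def test_pair_mean_matches_fair_share(self):
        """For n=2 the stand-in is centred on 75.5/2; 10,000 draws agree."""
        rng = random.Random(7)
        draws = [initial_guess(ModelParams(), 2, rng) for _ in range(10_000)]
        assert abs(np.mean(draws) - 75.5 / 2) < 3.0


class TestRawReactivity:
    def test_range_collapses_at_bounds(self):
        rng = random.Random(0)
        assert sample_raw_reactivity(50, Direction.TOO_LOW, 20, rng) == 0
        assert sample_raw_reactivity(0, Direction.TOO_HIGH, 20, rng) == 0

    def test_correct_direction_rejected(self):
        with pytest.raises(ValueError):
            sample_raw_reactivity(10, Direction.CORRECT, 20, random.Random(0))

    def test_support_matches_enumeration_everywhere(self):
        """Observed support equals the brute-force enumeration for every
        current guess 0..50 and both directions."""
        rng = random.Random(123)
        for guess in range(51):
            for direction in (Direction.TOO_LOW, Direction.TOO_HIGH):
                expected = enumerate_support(guess, direction)
                n_draws = 60 * len(expected)
                seen = {
                    sample_raw_reactivity(guess, direction, 20, rng)
                    for _ in range(n_draws)
                }
                assert seen == expected, (guess, direction)

    def test_truncated_range_is_uniform(self):
        """Guess 10, too low: raw range {0..40} truncated at +20 must be
        uniform over {0..20} (chi-square at alpha = .01, 20,000 draws)."""
        rng = random.Random(5)
        draws = [
            sample_raw_reactivity(10, Direction.TOO_LOW, 20, rng)
            for _ in range(20_000)
        ]
        counts = np.bincount(draws, minlength=21)
        _, p = sps.chisquare(counts)
        assert p > 0.01

    def test_magnitude_cap_restricts_support(self):
        rng = random.Random(9)
        draws = {
            sample_raw_reactivity(10, Direction.TOO_LOW, 20, rng, magnitude_cap=4)
            for _ in range(500)
        }
        assert draws == {0, 1, 2, 3, 4}


@pytest.mark.parametrize(
    "guess, reaction, expected",
    [(48, 5, 50), (3, -7, 0), (10, 4, 14), (0, 0, 0), (50, 1, 50)],
)
def test_apply_reaction_clamps(guess, reaction, expected):
    assert apply_reaction(guess, reaction) == expected


def _primed(agent, guess=10, rng=None, config=None):
    agent.reset(rng or random.Random(0), config or GameConfig())
    agent.current_guess = guess
    return agent


class TestModel1:
    def test_sign_follows_feedback(self):
        agent = _primed(Model1Agent(group_size=2), guess=10)
        assert all(agent._reaction(TOO_LOW) >= 0 for _ in range(50))
        assert all(agent._reaction(TOO_HIGH) <= 0 for _ in range(50))

    def test_too_high_range_bounded_by_guess(self):
        agent = _primed(Model1Agent(group_size=2), guess=5)
        draws = {agent._reaction(TOO_HIGH) for _ in range(300)}
        assert draws <= set(range(-5, 1))

    def test_fresh_sample_each_round(self):
        agent = _primed(Model1Agent(group_size=2), guess=10)
        draws = {agent._reaction(TOO_LOW) for _ in range(40)}
        assert len(draws) > 1  # memoryless resampling, not a held value


class TestDecayMap:
    def test_identity_before_any_advance(self):
        dm = DecayMap()
        dm.reset(random.Random(0))
        assert all(dm.apply(v) == v for v in range(-20, 21))

    def test_example_cumulative_decrease(self, stub_rng_factory):
        """An entry of +18 that has accumulated a -6 decrease yields +12."""
        dm = DecayMap()
        # advance twice: only entry +18 decays (draws 4 then 2)
        randoms, randints = [], []
        for _ in range(2):
            for v in range(-20, 21):
                if v == 0:
                    continue  # zero entries skip the rng
                randoms.append(0.0 if v == 18 else 1.0)
                if v == 18:
                    randints.append(4 if not randints else 2)
        dm.reset(stub_rng_factory(randoms=randoms, randints=randints))
        dm.advance()
        dm.advance()
        assert dm.apply(18) == 12
        assert dm.apply(17) == 17

    def test_decay_shrinks_toward_zero_without_sign_flip(self):
        dm = DecayMap()
        dm.reset(random.Random(3))
        for _ in range(10):
            prev = {v: dm.apply(v) for v in range(-20, 21)}
            dm.advance()
            for v in range(-20, 21):
                cur = dm.apply(v)
                assert abs(cur) <= abs(prev[v])
                assert cur * v >= 0

    def test_use_before_reset_raises(self):
        with pytest.raises(RuntimeError):
            DecayMap().apply(3)
        with pytest.raises(RuntimeError):
            DecayMap().advance()


class TestModel2:
    def test_reaction_is_decayed_raw_sample(self, stub_rng_factory):
        dm = DecayMap()
        dm.reset(random.Random(0))
        dm._map[18] = 12  # pretend +18 accumulated a -6 decrease
        agent = Model2Agent(dm, group_size=2)
        agent.reset(stub_rng_factory(randints=[18]), GameConfig())
        agent.current_guess = 10
        assert agent._reaction(TOO_LOW) == 12

    def test_decay_never_grows_magnitude_in_play(self):
        team = make_team("model2", 4)
        log = play_game(team, GameConfig(), seed=11)
        assert len(log.rounds) >= 1  # smoke: shared map wiring works in games


class TestModel3:
    def test_decay_arithmetic_and_floor(self, stub_rng_factory):
        agent = HeldReactivityAgent(p3=1.0, group_size=2)
        agent.reset(stub_rng_factory(randoms=[0.0, 0.0], randints=[3, 5]), GameConfig())
        agent.current_guess = 10
        agent.held_reactivity = 10
        agent.prev_direction = Direction.TOO_LOW
        assert agent._reaction(TOO_LOW) == 7  # 10 - 3
        agent.held_reactivity = 2
        assert agent._reaction(TOO_LOW) == 0  # floored at 0

    def test_sign_taken_from_current_feedback(self):
        agent = _primed(Model3Agent(group_size=2))
        agent.held_reactivity = 6
        agent.prev_direction = Direction.TOO_LOW
        assert agent._reaction(TOO_HIGH) <= 0

    def test_round2_sets_held_magnitude(self):
        agent = _primed(Model3Agent(group_size=2), guess=40)
        r = agent._reaction(TOO_HIGH)
        assert agent.held_reactivity == -r
        assert 0 <= agent.held_reactivity <= 20


class TestModel4:
    def test_holds_reactivity_while_direction_unchanged(self):
        agent = _primed(Model4Agent(group_size=2), rng=random.Random(4))
        agent.react(TOO_LOW)  # round 2: sample
        held = agent.held_reactivity
        for _ in range(6):
            agent.react(TOO_LOW)
            assert agent.held_reactivity == held

    def test_certain_decrease_on_direction_change(self, stub_rng_factory):
        agent = HeldReactivityAgent(p3=0.0, group_size=2)
        agent.reset(stub_rng_factory(randints=[4]), GameConfig())
        agent.current_guess = 10
        agent.held_reactivity = 9
        agent.prev_direction = Direction.TOO_LOW
        assert agent._reaction(TOO_HIGH) == -5  # 9 - 4, certain on change
        assert agent.held_reactivity == 5

    def test_change_decay_prob_option_recovers_gated_variant(self, stub_rng_factory):
        params = ModelParams(change_decay_prob=0.5)
        agent = HeldReactivityAgent(p3=0.0, group_size=2, params=params)
        agent.reset(stub_rng_factory(randoms=[0.9]), GameConfig())  # gate fails
        agent.current_guess = 10
        agent.held_reactivity = 9
        agent.prev_direction = Direction.TOO_LOW
        assert agent._reaction(TOO_HIGH) == -9  # decrement skipped

    def test_held_magnitude_never_increases_within_game(self):
        rng = random.Random(1)
        for _ in range(20):
            agent = Model4Agent(group_size=3)
            agent.reset(random.Random(rng.randint(0, 10**6)), GameConfig())
            agent.current_guess = 20
            agent.first_guess()
            last = None
            for _ in range(12):
                fb = TOO_LOW if rng.random() < 0.5 else TOO_HIGH
                agent.react(fb)
                if last is not None:
                    assert agent.held_reactivity <= last
                last = agent.held_reactivity


class TestMixture:
    @pytest.mark.parametrize("p3, pure_cls", [(0.0, Model4Agent), (1.0, Model3Agent)])
    def test_boundary_mixtures_reproduce_pure_models(self, p3, pure_cls):
        """p3 = 0 and p3 = 1 trace the exact trajectories of Models 4 and 3."""
        cfg = GameConfig()
        mix = HeldReactivityAgent(p3=p3, group_size=1)
        pure = pure_cls(group_size=1)
        for seed in range(5):
            for agent in (mix, pure):
                agent.reset(random.Random(seed), cfg)
                agent.current_guess = 25
            fb_rng = random.Random(seed + 100)
            for _ in range(10):
                fb = TOO_LOW if fb_rng.random() < 0.5 else TOO_HIGH
                assert mix.react(fb) == pure.react(fb)
                assert mix.held_reactivity == pure.held_reactivity

    def test_decision_frequency_matches_p3(self):
        """With a certain unit decrement, the decay rate estimates p3 = 0.5."""
        params = ModelParams(decay_prob=1.0, decay_low=1, decay_high=1)
        agent = HeldReactivityAgent(p3=0.5, group_size=1, params=params)
        agent.reset(random.Random(11), GameConfig())
        agent.current_guess = 25
        n = 10_000
        agent.held_reactivity = n  # large enough never to floor
        agent.prev_direction = Direction.TOO_LOW
        for _ in range(n):
            agent._reaction(TOO_LOW)  # unchanged direction: decay iff Model-3 rule
        freq = (n - agent.held_reactivity) / n
        assert abs(freq - 0.5) < 0.02


class TestNormative:
    def test_evenly_divisible_case_is_deterministic(self):
        rng = random.Random(0)
        assert all(
            normative_numeric_react(12, Direction.TOO_LOW, 4, rng) == 3
            for _ in range(50)
        )

    def test_zero_disparity_gives_zero(self):
        assert normative_numeric_react(0, Direction.TOO_LOW, 5, random.Random(0)) == 0

    def test_signed_by_direction(self):
        rng = random.Random(1)
        assert normative_numeric_react(12, Direction.TOO_HIGH, 4, rng) == -3

    def test_expected_total_reaction_equals_disparity(self):
        """d=17, n=5: per-member base 3 plus Bernoulli(2/5); the mean total
        group reaction over 10,000 draws is 17 within Monte-Carlo error."""
        rng = random.Random(3)
        totals = [
            sum(normative_numeric_react(17, Direction.TOO_LOW, 5, rng) for _ in range(5))
            for _ in range(10_000)
        ]
        assert abs(np.mean(totals) - 17.0) < 0.1

    def test_directional_mode_raises(self):
        agent = NormativeAgent(group_size=3)
        agent.reset(random.Random(0), GameConfig())
        agent.current_guess = 10
        with pytest.raises(ValueError):
            agent._reaction(TOO_LOW)

    def test_solves_numeric_games_quickly(self):
        team = make_team("normative", 4)
        cfg = GameConfig(feedback_mode=FeedbackMode.NUMERIC)
        solved = [play_game(team, cfg, seed=s).solved for s in range(20)]
        assert np.mean(solved) > 0.8


class TestBisectionBaseline:
    def test_closed_form_value_for_fifty_targets(self):
        assert round(solo_bisection_expected_rounds(50), 2) == 4.64

    def test_closed_form_small_cases(self):
        assert solo_bisection_expected_rounds(2) == 0.0
        assert solo_bisection_expected_rounds(1) == -1.0  # log2(1) - 1

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError):
            solo_bisection_expected_rounds(0)
        with pytest.raises(ValueError):
            solo_bisection_exact_mean(0)

    def test_exact_mean_matches_hand_enumeration(self):
        """Depth profile over 50 targets: 1x1 + 2x2 + 4x3 + 8x4 + 16x5 + 19x6."""
        assert solo_bisection_exact_mean(50) == (1 + 4 + 12 + 32 + 80 + 114) / 50
        assert solo_bisection_exact_mean(1) == 1.0


def test_sign_consistency_across_all_models():
    """Every model's realized reactivity is feedback-consistent in play."""
    from gbsearch.stats import reactivity

    for policy in ("model1", "model2", "model3", "model4", "mixture"):
        team = make_team(policy, 3)
        for seed in (0, 1):
            log = play_game(team, GameConfig(), seed=seed)
            for r in range(1, len(log.rounds)):
                d = log.rounds[r - 1].feedback.direction
                for gp, gc in zip(log.rounds[r - 1].guesses, log.rounds[r].guesses):
                    assert reactivity(gp, gc, d) >= 0


def test_unknown_policy_rejected():
    with pytest.raises(ValueError):
        make_team("model9", 2)
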