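"""Agent policies for the Group Binary Search game.

Four reactivity models share a common skeleton.  On round 1 every agent
draws an initial guess; from round 2 on it reacts to the broadcast feedback
with a signed "reactivity" — a guess change aligned with the feedback
direction (positive after "too low", negative after "too high"):

* **Model 1** — a fresh feedback-consistent reactivity every round, drawn
  uniformly from [0, 50 - g] (too low) or [-g, 0] (too high) where g is the
  current guess, rejection-sampled into [-20, +20].
* **Model 2** — as Model 1, but each sampled value is passed through a
  per-game :class:`DecayMap` in which every reactivity value in [-20, +20]
  independently shrinks toward zero (probability .5, uniform integer 0-5)
  once per round, cumulatively.
* **Model 3** — the agent holds the magnitude of a single round-2 draw and,
  on every later round, shrinks it with probability .5 by a uniform integer
  in [0, 5] (floored at 0): an annealing-style unconditional decay.
* **Model 4** — the held reactivity shrinks only on rounds where the
  broadcast direction changed (e.g. "too high" after "too low"), and then
  with certainty (the change event replaces Model 3's .5-per-round
  annealing gate; the decrement amount is still uniform on 0-5); otherwise
  the held reactivity is maintained exactly.  Set
  ``ModelParams.change_decay_prob`` below 1 to make the change-triggered
  decrement itself stochastic.

Mixture policies interpolate between Models 3 and 4; the normative
even-division policy and a solo optimal bisection searcher round out the
roster.  The human initial-guess distributions were never published, so a
configurable stand-in is used: a per-member normal centred on a fair share
of the expected target (75.5/n) — see :class:`ModelParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from random import Random

from .engine import (
    Direction,
    FeedbackMode,
    FeedbackSignal,
    GameConfig,
    Team,
)

__all__ = [
    "ModelParams",
    "DecayMap",
    "Agent",
    "Model1Agent",
    "Model2Agent",
    "HeldReactivityAgent",
    "Model3Agent",
    "Model4Agent",
    "MixtureAgent",
    "NormativeAgent",
    "BisectionAgent",
    "ConstantAgent",
    "POLICIES",
    "make_team",
    "team_factory",
    "initial_guess",
    "sample_raw_reactivity",
    "apply_reaction",
    "normative_numeric_react",
    "solo_bisection_expected_rounds",
    "solo_bisection_exact_mean",
]


@dataclass(frozen=True)
class ModelParams:
    """All model constants, plus the stand-in initial-guess distribution.

    ``clip`` (+-20), ``decay_prob`` (.5) and ``decay_low``/``decay_high``
    (0-5) are the stated reactivity constants.  ``initial_mean_total`` is the
    expected target (75.5 for a uniform 51-100 draw); each member's initial
    guess is a rounded normal with mean ``initial_mean_total / n`` and
    standard deviation ``max(initial_sigma_min, initial_sigma_frac * mean)``,
    clamped to the guess range.  ``numeric_adaptive`` additionally caps
    sampled reactivities at the broadcast magnitude in numeric games.
    """

    clip: int = 20
    decay_prob: float = 0.5
    decay_low: int = 0
    decay_high: int = 5
    change_decay_prob: float = 1.0
    mixture_p3: float = 0.5
    mixture_per_agent: bool = False
    numeric_adaptive: bool = False
    initial_mean_total: float = 75.5
    initial_sigma_frac: float = 0.4
    initial_sigma_min: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay_prob <= 1.0:
            raise ValueError("decay_prob must lie in [0, 1]")
        if not 0.0 <= self.change_decay_prob <= 1.0:
            raise ValueError("change_decay_prob must lie in [0, 1]")
        if self.decay_low > self.decay_high:
            raise ValueError("decay_low must not exceed decay_high")
        if self.clip <= 0:
            raise ValueError("clip must be positive")
        if not 0.0 <= self.mixture_p3 <= 1.0:
            raise ValueError("mixture_p3 must lie in [0, 1]")


def initial_guess(
    params: ModelParams,
    group_size: int,
    rng: Random,
    guess_low: int = 0,
    guess_high: int = 50,
) -> int:
    """Stand-in initial guess: rounded normal on a fair share of the target."""
    if group_size < 1:
        raise ValueError("group_size must be at least 1")
    mu = params.initial_mean_total / group_size
    sigma = max(params.initial_sigma_min, params.initial_sigma_frac * mu)
    g = round(rng.gauss(mu, sigma)) if sigma > 0 else round(mu)
    return min(max(g, guess_low), guess_high)


def sample_raw_reactivity(
    current_guess: int,
    direction: Direction,
    clip: int,
    rng: Random,
    magnitude_cap: int | None = None,
) -> int:
    """Feedback-consistent uniform reactivity, rejection-sampled into +-clip.

    Support is {0, ..., 50 - g} after "too low" and {-g, ..., 0} after
    "too high", intersected with [-clip, +clip]; 0 is always admissible, so
    the rejection loop terminates.  ``magnitude_cap`` optionally restricts
    the raw range further (numeric-feedback adaptive variant).
    """
    if direction is Direction.TOO_LOW:
        hi = 50 - current_guess
        if magnitude_cap is not None:
            hi = min(hi, magnitude_cap)
        while True:
            r = rng.randint(0, hi)
            if r <= clip:
                return r
    elif direction is Direction.TOO_HIGH:
        lo = -current_guess
        if magnitude_cap is not None:
            lo = max(lo, -magnitude_cap)
        while True:
            r = rng.randint(lo, 0)
            if -r <= clip:
                return r
    raise ValueError("no reactivity is sampled after correct feedback")


def apply_reaction(
    current_guess: int, reaction: int, guess_low: int = 0, guess_high: int = 50
) -> int:
    """New guess after a signed reaction, clamped to the guess bounds."""
    return min(max(current_guess + reaction, guess_low), guess_high)


class DecayMap:
    """Model 2's shared per-game table of decayed reactivity values.

    Maps each integer reactivity in [-clip, +clip] to its current decayed
    value.  At round 2 the map is the identity; once per subsequent round
    every entry independently shrinks toward zero with probability
    ``decay_prob`` by a uniform integer in [decay_low, decay_high], floored
    at 0 (the sign never flips), cumulatively across rounds.  One map is
    shared by all agents within one game and rebuilt for the next game.
    """

    def __init__(self, params: ModelParams | None = None) -> None:
        self.params = params or ModelParams()
        self._map: dict[int, int] | None = None
        self._rng: Random | None = None

    def reset(self, rng: Random) -> None:
        self._rng = rng
        self._map = {v: v for v in range(-self.params.clip, self.params.clip + 1)}

    def advance(self) -> None:
        if self._map is None:
            raise RuntimeError("DecayMap.advance called before reset")
        p = self.params
        rng = self._rng
        for v, cur in self._map.items():
            if cur != 0 and rng.random() < p.decay_prob:
                mag = max(0, abs(cur) - rng.randint(p.decay_low, p.decay_high))
                self._map[v] = mag if v > 0 else -mag

    def apply(self, raw: int) -> int:
        if self._map is None:
            raise RuntimeError("DecayMap.apply called before reset")
        return self._map[raw]


class Agent:
    """Base policy: owns its per-game rng, current guess and feedback memory."""

    def __init__(
        self, member_id: str = "m0", group_size: int = 1, params: ModelParams | None = None
    ) -> None:
        self.member_id = member_id
        self.group_size = group_size
        self.params = params or ModelParams()
        self.current_guess: int | None = None
        self.prev_direction: Direction | None = None
        self._rng: Random | None = None
        self._config = GameConfig()

    # -- engine protocol -------------------------------------------------
    def reset(self, rng: Random, config: GameConfig | None = None) -> None:
        """Per-game reset: fresh rng stream, cleared guess and memory."""
        self._rng = rng
        if config is not None:
            self._config = config
        self.current_guess = None
        self.prev_direction = None
        self._reset_state()

    def first_guess(self) -> int:
        g = self._first_guess()
        self.current_guess = g
        return g

    def react(self, feedback: FeedbackSignal) -> int:
        """Observe the broadcast, update state, return the new guess."""
        reaction = self._reaction(feedback)
        self.current_guess = apply_reaction(
            self.current_guess, reaction, self._config.guess_low, self._config.guess_high
        )
        self.prev_direction = feedback.direction
        return self.current_guess

    # -- hooks -----------------------------------------------------------
    def _reset_state(self) -> None:
        pass

    def _first_guess(self) -> int:
        return initial_guess(
            self.params,
            self.group_size,
            self._rng,
            self._config.guess_low,
            self._config.guess_high,
        )

    def _reaction(self, feedback: FeedbackSignal) -> int:
        raise NotImplementedError

    # -- helpers ---------------------------------------------------------
    def _magnitude_cap(self, feedback: FeedbackSignal) -> int | None:
        if self.params.numeric_adaptive and feedback.magnitude is not None:
            return feedback.magnitude
        return None


class Model1Agent(Agent):
    """Fresh feedback-consistent reactivity every round; no memory."""

    def _reaction(self, feedback: FeedbackSignal) -> int:
        return sample_raw_reactivity(
            self.current_guess,
            feedback.direction,
            self.params.clip,
            self._rng,
            self._magnitude_cap(feedback),
        )


class Model2Agent(Model1Agent):
    """Model 1 sampling passed through the game's shared decay map."""

    def __init__(self, decay_map: DecayMap, **kwargs) -> None:
        super().__init__(**kwargs)
        self.decay_map = decay_map

    def _reaction(self, feedback: FeedbackSignal) -> int:
        raw = super()._reaction(feedback)
        return self.decay_map.apply(raw)


class HeldReactivityAgent(Agent):
    """Persistent-reactivity policy; ``p3`` interpolates Models 3 and 4.

    A reactivity magnitude is sampled once on round 2.  On each later round
    a decay rule is selected per decision: with probability ``p3`` the
    Model 3 rule (shrink with probability ``decay_prob`` regardless of
    feedback), otherwise the Model 4 rule (shrink with probability
    ``change_decay_prob`` but only if the feedback direction just changed).
    ``p3 = 1`` is exactly Model 3 and ``p3 = 0`` exactly Model 4.  A shrink
    subtracts a uniform integer in [decay_low, decay_high], floored at 0.
    The held magnitude is signed by the *current* feedback direction when
    applied.
    """

    def __init__(self, p3: float, **kwargs) -> None:
        super().__init__(**kwargs)
        self.p3 = float(p3)
        self.held_reactivity: int | None = None
        self._assigned_m3: bool | None = None

    def _reset_state(self) -> None:
        self.held_reactivity = None
        if self.params.mixture_per_agent and 0.0 < self.p3 < 1.0:
            self._assigned_m3 = self._rng.random() < self.p3

    def _follows_model3(self) -> bool:
        if self.p3 >= 1.0:
            return True
        if self.p3 <= 0.0:
            return False
        if self.params.mixture_per_agent:
            return self._assigned_m3
        return self._rng.random() < self.p3

    def _maybe_decay(self, prob: float) -> None:
        p = self.params
        if prob >= 1.0 or self._rng.random() < prob:
            self.held_reactivity = max(
                0, self.held_reactivity - self._rng.randint(p.decay_low, p.decay_high)
            )

    def _reaction(self, feedback: FeedbackSignal) -> int:
        d = feedback.direction
        if self.held_reactivity is None:  # round 2: sample and hold
            raw = sample_raw_reactivity(
                self.current_guess,
                d,
                self.params.clip,
                self._rng,
                self._magnitude_cap(feedback),
            )
            self.held_reactivity = abs(raw)
        elif self._follows_model3():
            self._maybe_decay(self.params.decay_prob)
        elif d is not self.prev_direction:
            self._maybe_decay(self.params.change_decay_prob)
        return self.held_reactivity if d is Direction.TOO_LOW else -self.held_reactivity


class Model3Agent(HeldReactivityAgent):
    """Unconditional annealing of a held reactivity (p3 = 1)."""

    def __init__(self, **kwargs) -> None:
        super().__init__(p3=1.0, **kwargs)


class Model4Agent(HeldReactivityAgent):
    """Held reactivity shrinks only when the feedback direction changes (p3 = 0)."""

    def __init__(self, **kwargs) -> None:
        super().__init__(p3=0.0, **kwargs)


class MixtureAgent(HeldReactivityAgent):
    """Model 3 rule with probability ``params.mixture_p3``, else Model 4 rule."""

    def __init__(self, **kwargs) -> None:
        params = kwargs.get("params") or ModelParams()
        kwargs["params"] = params
        super().__init__(p3=params.mixture_p3, **kwargs)


def normative_numeric_react(
    magnitude: int, direction: Direction, n: int, rng: Random
) -> int:
    """One member's reaction under the normative even-division strategy.

    Every member moves by ``floor(d/n)`` plus 1 with probability
    ``(d mod n)/n``, signed by the feedback direction, so the expected total
    group reaction equals the disparity d exactly.
    """
    if n < 1:
        raise ValueError("group size must be at least 1")
    if magnitude is None:
        raise ValueError("normative strategy requires numeric feedback")
    base, rem = divmod(magnitude, n)
    mag = base + (1 if rem and rng.random() < rem / n else 0)
    if direction is Direction.TOO_HIGH:
        return -mag
    return mag


class NormativeAgent(Agent):
    """Even-division policy; only valid in numeric feedback games."""

    def _reaction(self, feedback: FeedbackSignal) -> int:
        if feedback.magnitude is None:
            raise ValueError("normative strategy requires numeric feedback")
        return normative_numeric_react(
            feedback.magnitude, feedback.direction, self.group_size, self._rng
        )


class BisectionAgent(Agent):
    """Deterministic optimal solo searcher: guesses the median of the live range.

    Needs a config whose guess range covers the target range (a lone member
    cannot reach targets above 50 under the standard bounds).
    """

    def _reset_state(self) -> None:
        self._lo = self._config.target_low
        self._hi = self._config.target_high

    def _first_guess(self) -> int:
        return (self._lo + self._hi) // 2

    def react(self, feedback: FeedbackSignal) -> int:
        if feedback.direction is Direction.TOO_LOW:
            self._lo = self.current_guess + 1
        elif feedback.direction is Direction.TOO_HIGH:
            self._hi = self.current_guess - 1
        self.current_guess = (self._lo + self._hi) // 2
        self.prev_direction = feedback.direction
        return self.current_guess


class ConstantAgent(Agent):
    """Always guesses a fixed value; handy as a degenerate test policy."""

    def __init__(self, value: int = 0, **kwargs) -> None:
        super().__init__(**kwargs)
        self.value = value

    def _first_guess(self) -> int:
        return self.value

    def _reaction(self, feedback: FeedbackSignal) -> int:
        return 0


def solo_bisection_expected_rounds(range_size: int) -> float:
    """Closed-form average rounds for an optimal individual searcher: log2(N) - 1."""
    if range_size < 1:
        raise ValueError("range_size must be at least 1")
    return math.log2(range_size) - 1


def solo_bisection_exact_mean(range_size: int) -> float:
    """Exact mean guesses of median bisection, enumerated over all N targets.

    Companion oracle to the closed form: counts guesses of a floor-median
    binary search for every target and averages.  For N = 50 this discrete
    expectation (4.86) differs from the closed-form log2(N) - 1 (4.64); both
    are reported, neither is asserted equal to the other.
    """
    if range_size < 1:
        raise ValueError("range_size must be at least 1")
    total = 0
    for t in range(range_size):
        lo, hi = 0, range_size - 1
        guesses = 0
        while True:
            mid = (lo + hi) // 2
            guesses += 1
            if mid == t:
                break
            if mid < t:
                lo = mid + 1
            else:
                hi = mid - 1
        total += guesses
    return total / range_size


POLICIES = ("model1", "model2", "model3", "model4", "mixture", "normative", "bisection")


def make_team(
    policy: str,
    group_size: int,
    params: ModelParams | None = None,
    member_prefix: str = "m",
) -> Team:
    """Build a team of ``group_size`` same-policy agents (shared state included)."""
    params = params or ModelParams()
    ids = [f"{member_prefix}{i}" for i in range(group_size)]
    common = dict(group_size=group_size, params=params)
    if policy == "model1":
        agents = [Model1Agent(member_id=m, **common) for m in ids]
        return Team(agents)
    if policy == "model2":
        shared = DecayMap(params)
        agents = [Model2Agent(shared, member_id=m, **common) for m in ids]
        return Team(agents, shared=shared)
    if policy == "model3":
        return Team([Model3Agent(member_id=m, **common) for m in ids])
    if policy == "model4":
        return Team([Model4Agent(member_id=m, **common) for m in ids])
    if policy == "mixture":
        return Team([MixtureAgent(member_id=m, **common) for m in ids])
    if policy == "normative":
        return Team([NormativeAgent(member_id=m, **common) for m in ids])
    if policy == "bisection":
        return Team([BisectionAgent(member_id=m, **common) for m in ids])
    raise ValueError(f"unknown policy {policy!r}; choose one of {POLICIES}")


def team_factory(policy: str, params: ModelParams | None = None):
    """A ``(group_size, group_id) -> Team`` factory for :func:`play_session`."""

    def factory(group_size: int, group_id: str = "g0") -> Team:
        return make_team(policy, group_size, params, member_prefix=f"{group_id}_m")

    return factory
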