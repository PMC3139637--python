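"""Synthetic human-like game-log corpus for exercising the statistics stack.

No human GBS logs were ever deposited, so the analysis pipeline is tested
against a synthetic corpus with the behavioral structure the analyses
assume: feedback-aligned reactivities that shrink when the feedback
direction changes (Model-4-style play), occasional guess noise and
non-reactions, members who freeze once their reactivity is nearly spent
(role differentiation near the solution), and improvement across games.
Every knob is explicit in :class:`FixtureSpec`; the corpus is synthetic and
stands in for unavailable human data — it is not a reproduction of it.

Across-game improvement is modelled generator-side: in later games the
initial guesses are drawn closer to a fair share of the *actual* target
(the generator, like the experimenter, knows the target; the agents still
only see the broadcast feedback).  This emulates groups starting closer to
the goal with practice, which is what drives their falling solution times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from random import Random

from ._rng import derive_seed, substream
from .agents import HeldReactivityAgent, ModelParams, initial_guess
from .comparison import REFERENCE_GROUP_SIZES
from .engine import (
    FeedbackMode,
    FeedbackSignal,
    GameConfig,
    GameLog,
    Team,
    alternating_schedule,
    play_game,
    sample_target,
)

__all__ = ["FixtureSpec", "FixtureAgent", "generate_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    """Roster and behavioral knobs of the synthetic corpus."""

    group_sizes: tuple[int, ...] = REFERENCE_GROUP_SIZES
    n_games: int = 10
    max_rounds: int = 15
    first_mode: FeedbackMode = FeedbackMode.DIRECTIONAL
    mixture_p3: float = 0.0  # base policy: Model-4-style held reactivity
    guess_noise_sd: float = 1.5
    noise_prob: float = 0.25  # chance a reaction picks up rounding jitter
    dropout_prob: float = 0.5  # chance a nearly-spent member freezes this round
    dropout_threshold: int = 2  # held magnitude at or below which freezing can occur
    improvement_rate: float = 0.08  # per-game shift of initial guesses toward target
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_prob", "dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("group fixtures require group sizes >= 2")


class FixtureAgent(HeldReactivityAgent):
    """Held-reactivity agent with human-like noise, freezing and skill.

    ``init_center`` (a per-game total) replaces the expected-target center of
    the stand-in initial distribution; the generator moves it toward the true
    target in later games to emulate practice effects.
    """

    def __init__(self, spec: FixtureSpec, **kwargs) -> None:
        super().__init__(p3=spec.mixture_p3, **kwargs)
        self.spec = spec
        self.init_center: float | None = None
        self.skill: float = 0.0  # 0 = naive; 1 = starts on target, reacts gently

    def _first_guess(self) -> int:
        params = self.params
        if self.init_center is not None:
            damp = 1.0 - self.skill  # practice tightens the initial spread too
            params = replace(
                params,
                initial_mean_total=self.init_center,
                initial_sigma_frac=params.initial_sigma_frac * damp,
                initial_sigma_min=max(1.0, params.initial_sigma_min * damp),
            )
        return initial_guess(
            params,
            self.group_size,
            self._rng,
            self._config.guess_low,
            self._config.guess_high,
        )

    def _reaction(self, feedback: FeedbackSignal) -> int:
        fresh = self.held_reactivity is None
        base = super()._reaction(feedback)
        if fresh and self.skill > 0:
            # experienced members react more gently, damping overshoot
            self.held_reactivity = round(self.held_reactivity * (1.0 - self.skill))
            base = self.held_reactivity if base >= 0 else -self.held_reactivity
        spec = self.spec
        if (
            self.held_reactivity is not None
            and self.held_reactivity <= spec.dropout_threshold
            and self._rng.random() < spec.dropout_prob
        ):
            return 0  # member drops out: stops reacting near the solution
        if spec.guess_noise_sd > 0 and self._rng.random() < spec.noise_prob:
            base += round(self._rng.gauss(0.0, spec.guess_noise_sd))
        return base


def generate_fixtures(spec: FixtureSpec | None = None) -> list[GameLog]:
    """Full synthetic corpus: every group plays its session of games."""
    spec = spec or FixtureSpec()
    params = ModelParams(mixture_p3=spec.mixture_p3)
    schedule = alternating_schedule(spec.n_games, spec.first_mode)
    logs: list[GameLog] = []
    for gi, n in enumerate(spec.group_sizes):
        group_id = f"g{gi:02d}"
        team = Team(
            [
                FixtureAgent(
                    spec,
                    member_id=f"{group_id}_m{k:02d}",
                    group_size=n,
                    params=params,
                )
                for k in range(n)
            ]
        )
        for game_index, mode in enumerate(schedule, start=1):
            config = GameConfig(feedback_mode=mode, max_rounds=spec.max_rounds)
            game_seed = derive_seed(spec.seed, "group", gi, "game", game_index)
            target = sample_target(config, substream(game_seed, "target"))
            # skill: later games start closer to a fair share of the target
            kappa = min(0.9, spec.improvement_rate * (game_index - 1))
            center = (1.0 - kappa) * 75.5 + kappa * target
            for agent in team.agents:
                agent.init_center = center
                agent.skill = kappa
            logs.append(
                play_game(
                    team,
                    config,
                    seed=game_seed,
                    group_id=group_id,
                    game_index=game_index,
                    target=target,
                )
            )
    return logs
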