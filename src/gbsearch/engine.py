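"""Game mechanics for the Group Binary Search (GBS) coordination game.

A computer server draws a hidden target in [51, 100]; each of the n group
members privately submits an integer guess in [0, 50]; the server compares
the guess sum S to the target T and broadcasts the same feedback to every
member — either directional ("too high" / "too low") or numeric ("too low
by 17").  Members adjust and the game continues until S = T or a round cap
(15 by default, 30 in extended games) is reached.

This module implements the mechanics only — target sampling, feedback,
the round/game/session loop — independent of any agent policy.  Policies
(see :mod:`gbsearch.agents`) plug in through a tiny protocol: ``reset``,
``first_guess`` and ``react``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from random import Random
from typing import Callable, Sequence

from ._rng import derive_seed, substream

__all__ = [
    "Direction",
    "FeedbackMode",
    "FeedbackSignal",
    "GameConfig",
    "RoundRecord",
    "GameLog",
    "SessionConfig",
    "Team",
    "size_class",
    "alternating_schedule",
    "sample_target",
    "compute_feedback",
    "play_game",
    "play_session",
]


class Direction(str, Enum):
    """Sign of the broadcast feedback."""

    TOO_HIGH = "too_high"
    TOO_LOW = "too_low"
    CORRECT = "correct"

    def __str__(self) -> str:  # plain value in CSV / messages
        return self.value


class FeedbackMode(str, Enum):
    DIRECTIONAL = "directional"
    NUMERIC = "numeric"

    def __str__(self) -> str:
        return self.value


def size_class(n: int) -> str:
    """Size class of an n-member group: small (2-3), large (>=10), else medium."""
    if n <= 3:
        return "small"
    if n >= 10:
        return "large"
    return "medium"


@dataclass(frozen=True)
class FeedbackSignal:
    """The only information agents receive.

    ``magnitude`` is the absolute disparity ``|T - S|`` and is present iff the
    game runs in numeric mode and the group has not yet hit the target.
    """

    direction: Direction
    magnitude: int | None = None

    def __post_init__(self) -> None:
        if self.magnitude is not None and self.magnitude < 0:
            raise ValueError("feedback magnitude must be non-negative")
        if self.direction is Direction.CORRECT and self.magnitude not in (None, 0):
            raise ValueError("correct feedback carries no magnitude")


def compute_feedback(group_sum: int, target: int, mode: FeedbackMode) -> FeedbackSignal:
    """Feedback the server broadcasts after comparing the guess sum to the target."""
    if group_sum < 0:
        raise ValueError("group_sum must be non-negative")
    disparity = target - group_sum
    if disparity == 0:
        return FeedbackSignal(Direction.CORRECT)
    direction = Direction.TOO_LOW if disparity > 0 else Direction.TOO_HIGH
    mode = FeedbackMode(mode)
    magnitude = abs(disparity) if mode is FeedbackMode.NUMERIC else None
    return FeedbackSignal(direction, magnitude)


@dataclass(frozen=True)
class GameConfig:
    """Static parameters of one game."""

    feedback_mode: FeedbackMode = FeedbackMode.DIRECTIONAL
    target_low: int = 51
    target_high: int = 100
    guess_low: int = 0
    guess_high: int = 50
    max_rounds: int = 15

    def __post_init__(self) -> None:
        object.__setattr__(self, "feedback_mode", FeedbackMode(self.feedback_mode))
        if self.target_low > self.target_high:
            raise ValueError("target_low must not exceed target_high")
        if self.guess_low > self.guess_high:
            raise ValueError("guess_low must not exceed guess_high")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be at least 1")


def sample_target(config: GameConfig, rng: Random) -> int:
    """Uniform integer target on [target_low, target_high], both ends inclusive."""
    return rng.randint(config.target_low, config.target_high)


@dataclass(frozen=True)
class RoundRecord:
    round_index: int  # 1-based
    guesses: tuple[int, ...]  # one per member, fixed member order
    group_sum: int
    feedback: FeedbackSignal

    def __post_init__(self) -> None:
        if self.group_sum != sum(self.guesses):
            raise ValueError("group_sum must equal the sum of guesses")


@dataclass(frozen=True)
class GameLog:
    """Complete round-by-round record of one game."""

    group_id: str
    group_size: int
    game_index: int  # 1-based within session
    feedback_mode: FeedbackMode
    target: int
    member_ids: tuple[str, ...]
    rounds: tuple[RoundRecord, ...]
    solved: bool
    rounds_to_solution: int

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("a game log must contain at least one round")
        if len(self.member_ids) != self.group_size:
            raise ValueError("member_ids length must equal group_size")
        last_correct = self.rounds[-1].feedback.direction is Direction.CORRECT
        if self.solved != last_correct:
            raise ValueError("solved flag inconsistent with final feedback")

    @property
    def size_class(self) -> str:
        return size_class(self.group_size)


class Team:
    """A set of agents plus optional per-game shared state (e.g. a decay map).

    ``shared`` must expose ``reset(rng)`` and ``advance()``; the engine resets
    it at each game start and advances it once per reaction round from round 3
    on, so that the shared state is an identity at round 2.
    """

    def __init__(self, agents: Sequence, shared=None) -> None:
        self.agents = list(agents)
        self.shared = shared

    def __len__(self) -> int:
        return len(self.agents)


def _as_team(agents) -> Team:
    return agents if isinstance(agents, Team) else Team(agents)


def play_game(
    agents: Team | Sequence,
    config: GameConfig,
    seed: int,
    *,
    group_id: str = "g0",
    game_index: int = 1,
    target: int | None = None,
) -> GameLog:
    """Play one game to completion (correct sum or round cap).

    Round 1 uses each agent's initial-guess policy; every later round each
    agent reacts to the single broadcast :class:`FeedbackSignal`.  ``target``
    may be forced (fixture generation, replay); otherwise it is drawn
    uniformly from the configured range.
    """
    team = _as_team(agents)
    n = len(team)
    if n == 0:
        raise ValueError("play_game requires at least one agent")
    if n * config.guess_high < config.target_high:
        raise ValueError(
            f"target {config.target_high} unreachable by {n} guesses of at most "
            f"{config.guess_high}"
        )
    if target is None:
        target = sample_target(config, substream(seed, "target"))
    elif not (config.target_low <= target <= config.target_high):
        raise ValueError("forced target outside the configured range")

    if team.shared is not None:
        team.shared.reset(substream(seed, "shared"))
    for i, agent in enumerate(team.agents):
        agent.reset(substream(seed, "agent", i), config)

    guesses = [agent.first_guess() for agent in team.agents]
    rounds: list[RoundRecord] = []
    solved = False
    for r in range(1, config.max_rounds + 1):
        s = sum(guesses)
        fb = compute_feedback(s, target, config.feedback_mode)
        rounds.append(RoundRecord(r, tuple(guesses), s, fb))
        if fb.direction is Direction.CORRECT:
            solved = True
            break
        if r == config.max_rounds:
            break
        if team.shared is not None and r >= 2:
            team.shared.advance()
        guesses = [agent.react(fb) for agent in team.agents]

    return GameLog(
        group_id=group_id,
        group_size=n,
        game_index=game_index,
        feedback_mode=config.feedback_mode,
        target=target,
        member_ids=tuple(getattr(a, "member_id", f"m{i}") for i, a in enumerate(team.agents)),
        rounds=tuple(rounds),
        solved=solved,
        # Unsolved games score at the cap: they tie up the full round budget.
        rounds_to_solution=len(rounds) if solved else config.max_rounds,
    )


def alternating_schedule(
    n_games: int, first: FeedbackMode = FeedbackMode.DIRECTIONAL
) -> tuple[FeedbackMode, ...]:
    """Strictly alternating feedback schedule, ``first`` mode leading."""
    other = (
        FeedbackMode.NUMERIC
        if FeedbackMode(first) is FeedbackMode.DIRECTIONAL
        else FeedbackMode.DIRECTIONAL
    )
    return tuple(FeedbackMode(first) if i % 2 == 0 else other for i in range(n_games))


@dataclass(frozen=True)
class SessionConfig:
    """One group's session: a sequence of games under a common base config.

    The default schedule alternates directional and numeric feedback games,
    directional first; pass an explicit ``schedule`` (e.g. all directional)
    to override.
    """

    group_size: int
    n_games: int = 10
    schedule: tuple[FeedbackMode, ...] | None = None
    first_mode: FeedbackMode = FeedbackMode.DIRECTIONAL
    game: GameConfig = field(default_factory=GameConfig)
    seed: int = 0
    group_id: str = "g0"

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be at least 1")
        if self.n_games < 1:
            raise ValueError("n_games must be at least 1")
        if self.schedule is not None:
            if len(self.schedule) != self.n_games:
                raise ValueError("schedule length must equal n_games")
            object.__setattr__(
                self, "schedule", tuple(FeedbackMode(m) for m in self.schedule)
            )

    def resolved_schedule(self) -> tuple[FeedbackMode, ...]:
        if self.schedule is not None:
            return self.schedule
        return alternating_schedule(self.n_games, self.first_mode)


def play_session(
    team_factory: Callable[[int, str], Team],
    config: SessionConfig,
) -> list[GameLog]:
    """Play a full session of games with one persistent team.

    The factory is called once, so agents keep their identity across games;
    per-game state (guess, held reactivity, decay map) is reset by
    :func:`play_game` at each game start.  A fresh target is drawn per game.
    """
    team = team_factory(config.group_size, config.group_id)
    team = _as_team(team)
    logs = []
    base = config.game
    for i, mode in enumerate(config.resolved_schedule(), start=1):
        game_cfg = replace(base, feedback_mode=mode)
        logs.append(
            play_game(
                team,
                game_cfg,
                seed=derive_seed(config.seed, "game", i),
                group_id=config.group_id,
                game_index=i,
            )
        )
    return logs
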