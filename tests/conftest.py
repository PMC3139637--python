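"""Shared fixtures and log-building helpers."""

from __future__ import annotations

import pytest

from gbsearch.engine import (
    FeedbackMode,
    GameLog,
    RoundRecord,
    compute_feedback,
)


def build_log(
    target: int,
    guess_rounds: list[tuple[int, ...]],
    mode: FeedbackMode = FeedbackMode.DIRECTIONAL,
    group_id: str = "g0",
    game_index: int = 1,
    member_ids: tuple[str, ...] | None = None,
) -> GameLog:
    """Assemble a valid GameLog from per-round guess tuples.

    Feedback and sums are computed from the rules; the last round decides
    the solved flag, and unsolved games are scored at their round count
    (i.e. the implied cap).
    """
    n = len(guess_rounds[0])
    records = []
    for r, guesses in enumerate(guess_rounds, start=1):
        s = sum(guesses)
        records.append(RoundRecord(r, tuple(guesses), s, compute_feedback(s, target, mode)))
    solved = records[-1].group_sum == target
    return GameLog(
        group_id=group_id,
        group_size=n,
        game_index=game_index,
        feedback_mode=FeedbackMode(mode),
        target=target,
        member_ids=member_ids or tuple(f"{group_id}_m{i}" for i in range(n)),
        rounds=tuple(records),
        solved=solved,
        rounds_to_solution=len(records),
    )


class StubRandom:
    """Scripted stand-in for random.Random: pops pre-set outcomes in order."""

    def __init__(self, randoms=(), randints=(), gausses=()):
        self._randoms = list(randoms)
        self._randints = list(randints)
        self._gausses = list(gausses)

    def random(self):
        return self._randoms.pop(0)

    def randint(self, a, b):
        v = self._randints.pop(0)
        assert a <= v <= b, f"scripted randint {v} outside [{a}, {b}]"
        return v

    def gauss(self, mu, sigma):
        return self._gausses.pop(0)


@pytest.fixture
def stub_rng_factory():
    return StubRandom
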