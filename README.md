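# gbsearch

A seeded simulator and analysis toolkit for the **Group Binary Search
(GBS)** coordination game: a round-based group task in which *n* members
each submit an integer guess in [0, 50], trying to make the group sum hit a
hidden target drawn uniformly from [51, 100]. After every round all members
receive the same broadcast feedback — directional ("Too high" / "Too low")
or numeric ("Too low by 17") — and the game runs until the sum equals the
target or a round cap (15, or 30 in extended games) is reached. The game is
a minimal test bed for *pure* group coordination: the shared goal is the
only incentive, the goal is unknown, and complementary actions (one member
moving while others hold still) are what make groups succeed.

The package is aimed at computational social scientists and
collective-behavior researchers who want to simulate agent strategies for
this class of task, analyze round-by-round game logs, and compare candidate
strategies against reference data by Monte-Carlo likelihood.

## The models

A member's **reactivity** at round *r* is its feedback-aligned guess change

> ρ_r = (G_r − G_{r−1}) if the group was too low after round r−1,
> ρ_r = (G_{r−1} − G_r) if it was too high,

where G_r is the member's guess at round r. Agents draw raw reactivities
uniformly from [0, 50 − G] (too low) or [−G, 0] (too high),
rejection-sampled into [−20, +20]. Four policies differ in how reactivity
evolves:

| model | rule |
|---|---|
| 1 | fresh feedback-consistent draw every round (no memory) |
| 2 | as 1, passed through a shared per-game decay map: each value in [−20, 20] shrinks toward 0 with prob .5 by U{0..5} per round, cumulatively |
| 3 | holds the magnitude of a single round-2 draw; every later round it shrinks with prob .5 by U{0..5} (annealing) |
| 4 | holds the round-2 magnitude; it shrinks (by U{0..5}) only on rounds where the broadcast direction just changed |

Mixture policies follow the Model 3 rule with probability p₃ and the
Model 4 rule otherwise. Two baselines complete the roster: the normative
even-division policy for numeric feedback (every member moves by ⌊d/n⌋
plus 1 with probability (d mod n)/n, so the expected total movement equals
the disparity d), and the optimal solo bisection searcher, whose
closed-form expected solution time over N targets is log₂(N) − 1 (4.64
rounds for N = 50).

Model comparison builds, for each policy, a smoothed rounds-to-solution
PMF per group-size class from thousands of replicate sessions, scores a
reference log set by log likelihood under each PMF, and compares model
pairs by χ² = 2·|ΔLL| with df = 1.

## Worked example

Simulate one 10-member group playing ten directional games under Model 4
and look at how its members react to feedback changes:

```python
from gbsearch import SessionConfig, play_session
from gbsearch.agents import team_factory
from gbsearch.engine import FeedbackMode, GameConfig
from gbsearch.stats import feedback_change_test

cfg = SessionConfig(group_size=10, n_games=10, seed=7,
                    schedule=(FeedbackMode.DIRECTIONAL,) * 10,
                    game=GameConfig(max_rounds=15))
logs = play_session(team_factory("model4"), cfg)
print([log.rounds_to_solution for log in logs])
report = feedback_change_test(logs)
print("decrease on change:", round(report["mean_decrease_change"].estimate, 2),
      "| no change:", round(report["mean_decrease_same"].estimate, 2))
```

prints

```
[15, 15, 15, 15, 15, 15, 4, 5, 9, 14]
decrease on change: 0.95 | no change: 0.13
```

Four of the ten games are solved (unsolved games score at the 15-round
cap), and the members' reactivity magnitudes drop when the feedback flips
direction (0.95 on average) but barely move otherwise (0.13) — the
signature of the flexible, change-triggered adjustment that makes Model 4
the fastest coordinator.

The same workflows are available from the shell via the `gbs` console
script (`gbs simulate`, `gbs analyze`, `gbs compare`, `gbs fixtures`); each
run writes a JSON manifest sufficient to replay it bit-exactly.

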