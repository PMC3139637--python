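"""Statistics battery over Group Binary Search game logs.

Every statistic operates identically on simulated logs, synthetic fixture
logs, or (hypothetical) human logs.  The central derived quantity is a
member's *reactivity* at round r: the guess change (G_r - G_{r-1}) signed so
that movement in the direction the previous round's feedback called for is
positive.  Conventions used throughout (see docs/methods.md):

* the reactivity at round r is defined against the feedback broadcast
  after round r-1 — the signal the member saw before choosing G_r;
* trend and variance analyses use reactivity magnitudes; the
  reaction-vs-disparity fit uses the signed group reaction;
* population (divide-by-N) variances by default, configurable via ``ddof``;
* standardized regression slopes (beta) are computed on z-scored variables
  and therefore equal the Pearson correlation of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import Direction, FeedbackMode, GameLog, size_class

__all__ = [
    "Stat",
    "StatReport",
    "reactivity",
    "reactivity_frame",
    "mean_rounds_table",
    "learning_trend",
    "reaction_response_fit",
    "reactivity_round_trend",
    "feedback_change_test",
    "variance_trends",
    "proportion_changing",
    "divisible_round_stats",
    "full_battery",
]

SIZE_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class Stat:
    """One named scalar statistic with its sample size and uncertainty."""

    estimate: float | None
    n: int
    dispersion: float | None = None
    p: float | None = None


@dataclass
class StatReport:
    """A named bundle of :class:`Stat` values, optionally with a table."""

    name: str
    stats: dict[str, Stat] = field(default_factory=dict)
    table: pd.DataFrame | None = None

    def __getitem__(self, key: str) -> Stat:
        return self.stats[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "report": self.name,
                "stat": key,
                "estimate": s.estimate,
                "n": s.n,
                "dispersion": s.dispersion,
                "p": s.p,
            }
            for key, s in self.stats.items()
        ]
        return pd.DataFrame(rows)


def reactivity(g_prev: int, g_cur: int, prev_direction: Direction) -> int:
    """Signed feedback-aligned guess change: (G_r - G_{r-1}) after "too low",
    (G_{r-1} - G_r) after "too high"."""
    prev_direction = Direction(prev_direction)
    if prev_direction is Direction.CORRECT:
        raise ValueError("no reactivity is defined after correct feedback")
    delta = g_cur - g_prev
    return delta if prev_direction is Direction.TOO_LOW else -delta


def reactivity_frame(logs: list[GameLog]) -> pd.DataFrame:
    """Tidy per-(member, round >= 2) reactivity table for a set of logs.

    ``direction_changed`` compares the broadcast driving round r with the one
    driving round r-1 and is undefined (NA) at r = 2.  ``rounds_before_solution``
    is only defined for solved games.
    """
    rows = []
    for log in logs:
        cls = log.size_class
        for r in range(2, len(log.rounds) + 1):
            prev = log.rounds[r - 2]
            cur = log.rounds[r - 1]
            d_prev = prev.feedback.direction
            changed = (
                None if r == 2 else d_prev is not log.rounds[r - 3].feedback.direction
            )
            rbs = log.rounds_to_solution - r if log.solved else None
            for m, (gp, gc) in enumerate(zip(prev.guesses, cur.guesses)):
                rows.append(
                    (
                        log.group_id,
                        log.group_size,
                        cls,
                        log.game_index,
                        str(log.feedback_mode),
                        log.member_ids[m],
                        r,
                        reactivity(gp, gc, d_prev),
                        gc != gp,
                        str(d_prev),
                        changed,
                        rbs,
                        log.solved,
                        log.rounds_to_solution,
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "group_size",
            "size_class",
            "game_index",
            "feedback_mode",
            "member_id",
            "round",
            "reactivity",
            "guess_changed",
            "prev_direction",
            "direction_changed",
            "rounds_before_solution",
            "solved",
            "rounds_to_solution",
        ],
    )
    frame["direction_changed"] = frame["direction_changed"].astype("boolean")
    return frame


def _games_frame(logs: list[GameLog]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [l.group_id for l in logs],
            "group_size": [l.group_size for l in logs],
            "size_class": [l.size_class for l in logs],
            "game_index": [l.game_index for l in logs],
            "feedback_mode": [str(l.feedback_mode) for l in logs],
            "rounds_to_solution": [l.rounds_to_solution for l in logs],
            "solved": [l.solved for l in logs],
        }
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> Stat:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return Stat(None, len(x))
    r, p = sps.pearsonr(x, y)
    return Stat(float(r), len(x), p=float(p))


def mean_rounds_table(logs: list[GameLog], ddof: int = 0) -> StatReport:
    """Mean (and SD) of rounds-to-solution per size class x feedback mode.

    The group is the unit of analysis: each group's games are averaged first,
    and the cell SD is taken over group means (absent for single-group cells).
    """
    if not logs:
        raise ValueError("mean_rounds_table requires at least one log")
    games = _games_frame(logs)
    per_group = (
        games.groupby(["size_class", "feedback_mode", "group_id"], observed=True)[
            "rounds_to_solution"
        ]
        .mean()
        .reset_index()
    )
    report = StatReport("mean_rounds_table")
    rows = []
    for (cls, mode), cell in per_group.groupby(["size_class", "feedback_mode"]):
        vals = cell["rounds_to_solution"].to_numpy()
        sd = float(np.std(vals, ddof=ddof)) if len(vals) > 1 else None
        report.stats[f"{cls}/{mode}"] = Stat(float(vals.mean()), len(vals), sd)
        rows.append(
            {"size_class": cls, "feedback_mode": mode, "mean": vals.mean(), "sd": sd,
             "n_groups": len(vals)}
        )
    report.table = pd.DataFrame(rows)
    return report


def learning_trend(logs: list[GameLog]) -> StatReport:
    """Pearson correlation between game number and rounds to solution.

    Reported overall and per size class; undefined (absent) on constant input.
    """
    games = _games_frame(logs)
    if games["game_index"].nunique() < 2:
        raise ValueError("learning_trend requires logs spanning >= 2 game indices")
    report = StatReport("learning_trend")
    report.stats["overall"] = _pearson(
        games["game_index"], games["rounds_to_solution"]
    )
    for cls, sub in games.groupby("size_class"):
        report.stats[cls] = _pearson(sub["game_index"], sub["rounds_to_solution"])
    return report


def _group_reactions(logs: list[GameLog], mode: FeedbackMode):
    """(disparity magnitude before round r, total group reaction at round r) pairs."""
    mode = FeedbackMode(mode)
    xs, ys = [], []
    for log in logs:
        if log.feedback_mode is not mode:
            continue
        for r in range(2, len(log.rounds) + 1):
            prev, cur = log.rounds[r - 2], log.rounds[r - 1]
            d = prev.feedback.direction
            if d is Direction.CORRECT:
                continue
            # In numeric games the magnitude is the broadcast; in directional
            # games it is the (server-known) true disparity read off the log.
            xs.append(abs(log.target - prev.group_sum))
            ys.append(reactivity(prev.group_sum, cur.group_sum, d))
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


def reaction_response_fit(logs: list[GameLog], mode: FeedbackMode) -> StatReport:
    """Least-squares fit of total group reaction on prior disparity magnitude.

    The optimal reference line is reaction = disparity (slope 1, intercept 0);
    a fitted slope below 1 flags group under-reactivity.
    """
    x, y = _group_reactions(logs, mode)
    if len(x) < 3:
        raise ValueError("reaction_response_fit requires at least 3 paired rounds")
    fit = sps.linregress(x, y)
    report = StatReport("reaction_response_fit")
    report.stats["slope"] = Stat(float(fit.slope), len(x), fit.stderr, float(fit.pvalue))
    report.stats["intercept"] = Stat(float(fit.intercept), len(x), fit.intercept_stderr)
    report.stats["under_reactive"] = Stat(float(fit.slope < 1.0), len(x))
    return report


def reactivity_round_trend(logs: list[GameLog], k: int = 6) -> StatReport:
    """Trend of mean reactivity magnitude over the last ``k`` rounds before solution.

    Solved games only; rounds are aligned by rounds-before-solution (0 = final
    round), and games shorter than the window simply contribute the rounds
    they have.  The slope is taken on the time-aligned axis, so decreasing
    reactivity approaching the solution yields a negative slope.
    """
    solved = [l for l in logs if l.solved]
    if not solved:
        raise ValueError("reactivity_round_trend requires solved games")
    frame = reactivity_frame(solved)
    frame = frame[frame["rounds_before_solution"] < k]
    per_round = (
        frame.assign(mag=frame["reactivity"].abs())
        .groupby(["group_id", "game_index", "rounds_before_solution"], observed=True)[
            "mag"
        ]
        .mean()
        .reset_index()
    )
    x = -per_round["rounds_before_solution"].to_numpy(dtype=float)
    y = per_round["mag"].to_numpy(dtype=float)
    report = StatReport("reactivity_round_trend")
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        report.stats["slope"] = Stat(0.0 if np.ptp(y) == 0 else None, len(x))
        report.stats["beta"] = Stat(0.0 if np.ptp(y) == 0 else None, len(x))
        return report
    fit = sps.linregress(x, y)
    report.stats["slope"] = Stat(float(fit.slope), len(x), fit.stderr, float(fit.pvalue))
    beta = _pearson(x, y)
    report.stats["beta"] = beta
    return report


def feedback_change_test(logs: list[GameLog]) -> StatReport:
    """Reactivity decrease after feedback-direction changes vs no changes.

    For every member and every pair of consecutive reactivity rounds, the
    decrease |reactivity_{r-1}| - |reactivity_r| is classified by whether the
    broadcast direction changed between the two signals.  Class means are
    reported over all pairs, and a paired t statistic compares the two class
    means within members (members contributing to both classes).  With fewer
    than two pairs in either class the test is reported as absent.
    """
    frame = reactivity_frame(logs)
    frame = frame.sort_values(["group_id", "game_index", "member_id", "round"])
    mag = frame["reactivity"].abs()
    same_track = (
        (frame["group_id"] == frame["group_id"].shift())
        & (frame["game_index"] == frame["game_index"].shift())
        & (frame["member_id"] == frame["member_id"].shift())
        & (frame["round"] == frame["round"].shift() + 1)
    )
    pairs = pd.DataFrame(
        {
            "member_id": frame["member_id"],
            "decrease": mag.shift() - mag,
            "changed": frame["direction_changed"],
        }
    )[same_track & frame["direction_changed"].notna()]

    report = StatReport("feedback_change_test")
    chg = pairs[pairs["changed"].astype(bool)]["decrease"]
    same = pairs[~pairs["changed"].astype(bool)]["decrease"]
    report.stats["mean_decrease_change"] = (
        Stat(float(chg.mean()), len(chg), float(chg.std(ddof=0))) if len(chg) else Stat(None, 0)
    )
    report.stats["mean_decrease_same"] = (
        Stat(float(same.mean()), len(same), float(same.std(ddof=0))) if len(same) else Stat(None, 0)
    )
    if len(chg) < 2 or len(same) < 2:
        report.stats["paired_t"] = Stat(None, 0)
        return report
    by_member = pairs.groupby(["member_id", "changed"], observed=True)["decrease"].mean().unstack()
    by_member = by_member.dropna()
    if len(by_member) < 2:
        report.stats["paired_t"] = Stat(None, len(by_member))
        return report
    t, p = sps.ttest_rel(by_member[True], by_member[False])
    report.stats["paired_t"] = Stat(float(t), len(by_member), p=float(p))
    return report


def _zbeta(x, y) -> Stat:
    """Standardized regression slope (= Pearson r for a single predictor)."""
    return _pearson(x, y)


def variance_trends(logs: list[GameLog], ddof: int = 0) -> StatReport:
    """Within- and between-individual reactivity-variance trends, by size class.

    (a) within-individual dispersion — squared deviation of a member's
    reactivity magnitude from that member's own game mean — averaged over
    members within a group-game-round, regressed on round index;
    (b) between-member variance of member mean reactivity magnitudes per
    group-game, regressed on game index (single-member groups excluded);
    (c) rounds-to-solution regressed on the between-member variance.
    All slopes are standardized (z-scored variables).
    """
    frame = reactivity_frame(logs)
    frame = frame.assign(mag=frame["reactivity"].abs())
    report = StatReport("variance_trends")

    member_mean = frame.groupby(
        ["group_id", "game_index", "member_id"], observed=True
    )["mag"].transform("mean")
    frame = frame.assign(sqdev=(frame["mag"] - member_mean) ** 2)
    within = (
        frame.groupby(["size_class", "group_id", "game_index", "round"], observed=True)[
            "sqdev"
        ]
        .mean()
        .reset_index()
    )
    for cls, sub in within.groupby("size_class"):
        report.stats[f"within_round_beta_{cls}"] = _zbeta(sub["round"], sub["sqdev"])

    multi = frame[frame["group_size"] > 1]
    per_member = (
        multi.groupby(
            ["size_class", "group_id", "game_index", "member_id"], observed=True
        )["mag"]
        .mean()
        .reset_index()
    )
    between = (
        per_member.groupby(["size_class", "group_id", "game_index"], observed=True)[
            "mag"
        ]
        .agg(lambda v: float(np.var(v, ddof=ddof)))
        .rename("between_var")
        .reset_index()
    )
    rts = (
        _games_frame(logs)
        .set_index(["group_id", "game_index"])["rounds_to_solution"]
        .to_dict()
    )
    between = between.assign(
        rounds_to_solution=[
            rts[(g, i)] for g, i in zip(between["group_id"], between["game_index"])
        ]
    )
    for cls, sub in between.groupby("size_class"):
        report.stats[f"between_games_beta_{cls}"] = _zbeta(
            sub["game_index"], sub["between_var"]
        )
        report.stats[f"solution_on_between_beta_{cls}"] = _zbeta(
            sub["between_var"], sub["rounds_to_solution"]
        )
    report.table = between
    return report


def proportion_changing(logs: list[GameLog]) -> StatReport:
    """Fraction of members changing their guess, by rounds before solution.

    Solved games only.  Reports the per-class mean proportion, the best-fit
    slope of proportion on rounds-before-solution, and a two-sample t test of
    small vs large per-round proportions.  The binned curve is attached as
    the report table.
    """
    solved = [l for l in logs if l.solved]
    frame = reactivity_frame(solved)
    report = StatReport("proportion_changing")
    if frame.empty:
        return report
    binned = (
        frame.groupby(["size_class", "rounds_before_solution"], observed=True)[
            "guess_changed"
        ]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "proportion", "size": "n_member_rounds"})
    )
    report.table = binned
    per_round = (
        frame.groupby(
            ["size_class", "group_id", "game_index", "rounds_before_solution"],
            observed=True,
        )["guess_changed"]
        .mean()
        .reset_index()
    )
    for cls, sub in per_round.groupby("size_class"):
        report.stats[f"mean_{cls}"] = Stat(
            float(sub["guess_changed"].mean()),
            len(sub),
            float(sub["guess_changed"].std(ddof=0)),
        )
        report.stats[f"slope_{cls}"] = _pearson(
            sub["rounds_before_solution"], sub["guess_changed"]
        )
    small = per_round[per_round["size_class"] == "small"]["guess_changed"]
    large = per_round[per_round["size_class"] == "large"]["guess_changed"]
    if len(small) >= 2 and len(large) >= 2:
        t, p = sps.ttest_ind(small, large, equal_var=False)
        report.stats["small_vs_large_t"] = Stat(float(t), len(small) + len(large), p=float(p))
    return report


def divisible_round_stats(logs: list[GameLog]) -> StatReport:
    """Evenly divisible numeric-feedback rounds and normative-strategy usage.

    A feedback round is *evenly divisible* when the broadcast magnitude is a
    multiple of the group size n.  On divisible rounds that were followed by
    another round, a member *employs the normative strategy* when its next
    reactivity equals exactly magnitude/n in the feedback direction.
    Directional logs contribute nothing (a warning is emitted).
    """
    numeric = [l for l in logs if l.feedback_mode is FeedbackMode.NUMERIC]
    if len(numeric) < len(logs):
        warnings.warn(
            "divisible_round_stats: directional-feedback logs contribute nothing",
            stacklevel=2,
        )
    report = StatReport("divisible_round_stats")
    div_count: dict[str, list[int]] = {}
    usage: dict[str, list[int]] = {}
    for log in numeric:
        cls = log.size_class
        n = log.group_size
        for r, rec in enumerate(log.rounds, start=1):
            m = rec.feedback.magnitude
            if m is None:
                continue
            divisible = m % n == 0
            div_count.setdefault(cls, []).append(int(divisible))
            if divisible and r < len(log.rounds):
                nxt = log.rounds[r]
                share = m // n
                for gp, gc in zip(rec.guesses, nxt.guesses):
                    used = reactivity(gp, gc, rec.feedback.direction) == share
                    usage.setdefault(cls, []).append(int(used))
    for cls, vals in div_count.items():
        report.stats[f"divisible_frac_{cls}"] = Stat(
            float(np.mean(vals)), len(vals)
        )
    for cls, vals in usage.items():
        report.stats[f"normative_frac_{cls}"] = Stat(float(np.mean(vals)), len(vals))
    return report


def full_battery(logs: list[GameLog], k: int = 6) -> list[StatReport]:
    """Run every statistic that the given log set supports."""
    reports = [mean_rounds_table(logs)]
    for fn in (
        learning_trend,
        lambda ls: reaction_response_fit(ls, FeedbackMode.NUMERIC),
        lambda ls: reaction_response_fit(ls, FeedbackMode.DIRECTIONAL),
        lambda ls: reactivity_round_trend(ls, k),
        feedback_change_test,
        variance_trends,
        proportion_changing,
        divisible_round_stats,
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports.append(fn(logs))
        except ValueError:
            continue
    # disambiguate the two response fits by mode
    names = [r.name for r in reports]
    if names.count("reaction_response_fit") == 2:
        first = names.index("reaction_response_fit")
        reports[first].name = "reaction_response_fit_numeric"
        reports[names.index("reaction_response_fit", first + 1)].name = (
            "reaction_response_fit_directional"
        )
    return reports
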