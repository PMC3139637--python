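"""Monte-Carlo likelihood model comparison for GBS agent policies.

Each candidate policy is run for many replicates of a full session design
(by default the empirical roster: 18 groups of sizes 2..17, 10 directional
games, unsolved games scored at the round cap).  The replicate outcomes
define a smoothed probability mass function over rounds-to-solution,
stratified by group size class; a reference log set is scored by its log
likelihood under each model's PMF, and model pairs are compared by a
likelihood-ratio chi-square statistic.

The likelihood construction treats game outcomes as independent given the
stratum — the simplest reading of "likelihood of the data given each
model's results" — and the mixture-vs-pure comparisons use df = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._rng import derive_seed
from .agents import ModelParams, team_factory
from .engine import (
    FeedbackMode,
    GameConfig,
    GameLog,
    SessionConfig,
    play_session,
    size_class,
)

__all__ = [
    "REFERENCE_GROUP_SIZES",
    "SessionTemplate",
    "ReplicateBatch",
    "SolutionTimePMF",
    "LRTest",
    "ComparisonResult",
    "run_replicates",
    "build_pmf",
    "log_likelihood",
    "lr_test",
    "compare_models",
    "mean_round_comparison",
]

# Empirical roster: 18 groups, 106 participants.
REFERENCE_GROUP_SIZES: tuple[int, ...] = (2, 2, 2, 2, 2, 2, 3, 3, 3, 4, 4, 4, 6, 7, 10, 16, 17, 17)


@dataclass(frozen=True)
class SessionTemplate:
    """Design shared by all replicates of a batch."""

    group_sizes: tuple[int, ...] = REFERENCE_GROUP_SIZES
    n_games: int = 10
    max_rounds: int = 15
    feedback_mode: FeedbackMode = FeedbackMode.DIRECTIONAL
    guess_low: int = 0
    guess_high: int = 50  # raise for solo designs where one member must reach the target

    def session_config(self, group_index: int, seed: int) -> SessionConfig:
        n = self.group_sizes[group_index]
        return SessionConfig(
            group_size=n,
            n_games=self.n_games,
            schedule=(FeedbackMode(self.feedback_mode),) * self.n_games,
            game=GameConfig(
                feedback_mode=self.feedback_mode,
                max_rounds=self.max_rounds,
                guess_low=self.guess_low,
                guess_high=self.guess_high,
            ),
            seed=seed,
            group_id=f"g{group_index}",
        )


@dataclass
class ReplicateBatch:
    """Rounds-to-solution of R independent full-design replicates."""

    policy: str
    params: ModelParams
    template: SessionTemplate
    rounds: np.ndarray  # shape (R, n_groups, n_games), int

    @property
    def n_replicates(self) -> int:
        return self.rounds.shape[0]

    def grand_means(self) -> np.ndarray:
        """Per-replicate grand mean over all group-games, shape (R,)."""
        return self.rounds.mean(axis=(1, 2))

    def group_means(self) -> np.ndarray:
        """Per-replicate per-group means, shape (R, n_groups)."""
        return self.rounds.mean(axis=2)


def run_replicates(
    policy: str,
    template: SessionTemplate | None = None,
    R: int = 500,
    seed: int = 0,
    params: ModelParams | None = None,
) -> ReplicateBatch:
    """Run ``R`` seeded replicates of the session design under one policy."""
    if R < 1:
        raise ValueError("R must be at least 1")
    template = template or SessionTemplate()
    params = params or ModelParams()
    n_groups = len(template.group_sizes)
    out = np.empty((R, n_groups, template.n_games), dtype=np.int64)
    factory = team_factory(policy, params)
    for r in range(R):
        for g in range(n_groups):
            cfg = template.session_config(g, derive_seed(seed, policy, "rep", r, "group", g))
            logs = play_session(factory, cfg)
            out[r, g, :] = [log.rounds_to_solution for log in logs]
    return ReplicateBatch(policy, params, template, out)


@dataclass
class SolutionTimePMF:
    """Per-stratum probability mass over rounds-to-solution 1..max_rounds."""

    max_rounds: int
    by: str  # "size_class" or "group_size"
    pmf: dict[str, np.ndarray] = field(default_factory=dict)

    def mass(self, stratum: str, rounds_to_solution: int) -> float:
        if stratum not in self.pmf:
            raise KeyError(f"stratum {stratum!r} missing from PMF")
        if not 1 <= rounds_to_solution <= self.max_rounds:
            raise ValueError("outcome outside 1..max_rounds")
        return float(self.pmf[stratum][rounds_to_solution - 1])


def _stratum_of(n: int, by: str) -> str:
    return size_class(n) if by == "size_class" else str(n)


def build_pmf(
    batch: ReplicateBatch, by: str = "size_class", epsilon: float = 1e-4
) -> SolutionTimePMF:
    """Relative outcome frequencies with additive-epsilon smoothing.

    ``epsilon`` is a pseudocount added to every outcome 1..max_rounds before
    renormalizing, so no observable outcome has zero mass.
    """
    if by not in ("size_class", "group_size"):
        raise ValueError("stratification must be 'size_class' or 'group_size'")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    max_rounds = batch.template.max_rounds
    result = SolutionTimePMF(max_rounds, by)
    strata: dict[str, np.ndarray] = {}
    for g, n in enumerate(batch.template.group_sizes):
        key = _stratum_of(n, by)
        counts = strata.setdefault(key, np.zeros(max_rounds))
        vals, freq = np.unique(batch.rounds[:, g, :], return_counts=True)
        counts[vals - 1] += freq
    for key, counts in strata.items():
        smoothed = counts + epsilon
        result.pmf[key] = smoothed / smoothed.sum()
    return result


def log_likelihood(reference_logs: list[GameLog], pmf: SolutionTimePMF) -> float:
    """Sum of log PMF mass at each reference game's outcome, within its stratum."""
    total = 0.0
    for log in reference_logs:
        stratum = _stratum_of(log.group_size, pmf.by)
        total += np.log(pmf.mass(stratum, log.rounds_to_solution))
    return float(total)


@dataclass(frozen=True)
class LRTest:
    chi2: float
    df: int
    p: float
    winner: str


def lr_test(ll_a: float, ll_b: float, df: int = 1, names: tuple[str, str] = ("A", "B")) -> LRTest:
    """Likelihood-ratio test: chi2 = 2|LL_a - LL_b|, p from chi2(df)."""
    chi2 = 2.0 * abs(ll_a - ll_b)
    p = float(sps.chi2.sf(chi2, df))
    winner = names[0] if ll_a >= ll_b else names[1]
    return LRTest(chi2, df, p, winner)


@dataclass
class ComparisonResult:
    """Per-model log likelihoods of a reference log set, plus pairwise tests."""

    log_likelihoods: dict[str, float]
    tests: dict[tuple[str, str], LRTest]
    n_reference_games: int
    R: int
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "log_likelihoods": self.log_likelihoods,
            "n_reference_games": self.n_reference_games,
            "replicates": self.R,
            "epsilon": self.epsilon,
            "tests": [
                {
                    "model_a": a,
                    "model_b": b,
                    "chi2": t.chi2,
                    "df": t.df,
                    "p": t.p,
                    "winner": t.winner,
                }
                for (a, b), t in self.tests.items()
            ],
        }


def compare_models(
    reference_logs: list[GameLog],
    model_specs: dict[str, ModelParams],
    template: SessionTemplate | None = None,
    R: int = 500,
    seed: int = 0,
    epsilon: float = 1e-4,
    by: str = "size_class",
) -> ComparisonResult:
    """Likelihood of a reference log set under each model, with pairwise LR tests."""
    lls: dict[str, float] = {}
    for name, params in model_specs.items():
        policy = name.split(":")[0]  # "mixture:0.25" -> policy "mixture"
        batch = run_replicates(policy, template, R, derive_seed(seed, name), params)
        lls[name] = log_likelihood(reference_logs, build_pmf(batch, by, epsilon))
    names = list(lls)
    tests = {
        (a, b): lr_test(lls[a], lls[b], names=(a, b))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return ComparisonResult(lls, tests, len(reference_logs), R, epsilon)


def mean_round_comparison(batch_a: ReplicateBatch, batch_b: ReplicateBatch) -> dict:
    """Mean rounds-to-solution comparison between two policies.

    Returns both a replicate-level one-sided Welch test that policy A's grand
    mean exceeds policy B's (power grows with R), and the median across
    replicates of a design-scale two-sided Welch test over the 18 per-group
    means (the power the empirical design affords).
    """
    ga, gb = batch_a.grand_means(), batch_b.grand_means()
    t_rep, p_rep = sps.ttest_ind(ga, gb, equal_var=False, alternative="greater")
    ma, mb = batch_a.group_means(), batch_b.group_means()
    n = min(ma.shape[0], mb.shape[0])
    p_design = [
        sps.ttest_ind(ma[r], mb[r], equal_var=False).pvalue for r in range(n)
    ]
    return {
        "mean_a": float(ga.mean()),
        "mean_b": float(gb.mean()),
        "t_replicate": float(t_rep),
        "p_replicate_greater": float(p_rep),
        "p_design_median": float(np.median(p_design)),
    }
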