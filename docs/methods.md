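# Methods

## Game mechanics

One game: a target T ~ Uniform{51..100}; each of n members submits an
integer guess in [0, 50]; the server broadcasts the sign of the disparity
d = T − S (S the guess sum), plus |d| in numeric-feedback mode; the game
ends when S = T or after `max_rounds` rounds (15 by default, 30 in extended
games). Unsolved games score `rounds_to_solution = max_rounds`: model means
are only comparable across policies if the games that exhaust the budget
pay for it. A session is a sequence of games (default 10) played by one
persistent team; the default schedule alternates directional and numeric
games, directional first (the alternation order is configurable because
either order is defensible). Rounds are synchronous turns — the original
task's 15-second real-time guessing window affects humans, not policies —
and targets are drawn independently per game.

All randomness flows from one master seed through a keyed hash
(`gbsearch._rng.derive_seed`), giving every replicate, group, game, agent
and shared structure its own `random.Random` stream. Adding or removing a
group therefore never perturbs another group's draws, and a (seed, config,
policy) triple determines the serialized log byte-for-byte.

## Agent policies

Reactivity sampling: uniform on [0, 50 − G] after "too low", on [−G, 0]
after "too high" (G the member's current guess), rejection-sampled until
the value lies in [−20, +20]. Zero is always admissible, so the sampler
always terminates; its support is exactly the stated range intersected
with the clip window (property-tested by enumeration).

* **Model 1** resamples fresh every round.
* **Model 2** passes each sample through a per-game `DecayMap`: every value
  in [−20, +20] independently shrinks toward zero with probability .5 by a
  uniform integer in [0, 5], once per round, cumulatively, floored at 0 and
  never crossing zero (a +18 that has accumulated −6 comes out as +12).
  The map is shared by all members of a game and rebuilt each game; it is
  the identity on round 2 and advances once per subsequent round.
* **Model 3** samples one reactivity magnitude on round 2 and holds it;
  each later round the magnitude shrinks with probability .5 by U{0..5}
  (floored at 0) regardless of feedback — an annealing schedule. The held
  magnitude is unsigned; each reaction takes its sign from the current
  broadcast direction.
* **Model 4** holds its round-2 magnitude unchanged while the feedback
  direction repeats, and shrinks it by U{0..5} — with certainty — on every
  round where the direction flips.

The Model 4 decrement is deliberately *certain* rather than fired with the
.5 gate that schedules Model 3. Read that way, the two models exchange one
annealing trigger for another (clock vs feedback change) at comparable
expected decay per triggering event, and the simulator reproduces the
reference mean solution times of all four models and of both extended-cap
runs. Under the alternative reading (the .5 gate kept and merely gated by
the change event), Model 4 decays at half the rate only during oscillation
phases — where direction flips almost every round and the two models
behave identically anyway — and its performance becomes statistically
indistinguishable from Model 3 under every initial-guess distribution we
tried, which contradicts the reference behavior this simulator targets.
`ModelParams.change_decay_prob` (default 1.0) exposes the choice; set it
to 0.5 to recover the gated variant.

Mixture policies choose, independently at each agent-round decision point,
the Model 3 rule with probability `mixture_p3` and the Model 4 rule
otherwise (`mixture_per_agent=True` instead fixes the choice per agent per
game). p₃ = 1 and p₃ = 0 trace Models 3 and 4 exactly, rng call for call.

The **normative** numeric-feedback policy moves every member by ⌊d/n⌋ plus
an independent Bernoulli((d mod n)/n) increment, signed by the direction,
so the expected total group movement equals the disparity exactly. The
**bisection** baseline is the deterministic optimal solo searcher (median
of the live target interval); its closed-form expected solution time is
log₂(N) − 1 (4.64 for N = 50). The companion exact enumeration (mean
guesses of floor-median bisection over all N targets) gives 4.86 for
N = 50; the two are different quantities and both are reported, neither
asserted equal to the other.

Reactions are added to the current guess and clamped to [0, 50]; held
reactivities are not themselves clamped, so a member at a bound can
"realize" less reactivity than it holds. Guesses and targets are integers
throughout, matching the feedback arithmetic.

### Stand-in initial-guess distribution

The original empirical initial-guess distributions (one per size class)
were never published. The stand-in used everywhere by default draws each
member's first guess from a rounded normal with mean 75.5/n — a fair share
of the expected target — and standard deviation max(2, 0.4 · mean),
clamped to [0, 50]. It is unbiased for the expected group sum, scales its
dispersion with the mean, and is fully configurable
(`ModelParams.initial_mean_total`, `initial_sigma_frac`,
`initial_sigma_min`) so sensitivity can be tested. With this stand-in and
the policies above, the reference design (18 groups at roster sizes
2,2,2,2,2,2,3,3,3,4,4,4,6,7,10,16,17,17, 10 directional games, 15-round
cap) yields grand means near 13.1 / 12.8 / 11.8 / 10.7 rounds for Models
1–4 and near 18.5 / 15.8 for Models 3–4 under the 30-round cap
(`scripts/acceptance.py` recomputes these). One known consequence of the
fair-share stand-in: model solution times vary less across group sizes
than human groups' did, so between-group variance is compressed relative
to the empirical design.

## Statistics over game logs

Conventions, applied identically to simulated, fixture, or external logs
in the CSV schema:

* The reactivity at round r is computed against the broadcast sent after
  round r − 1 (the signal the member saw before choosing G_r). Round 1 has
  no reactivity; a round after "correct" cannot occur.
* Trend, variance and proportion analyses use reactivity *magnitudes*; the
  reaction-vs-disparity fit uses the signed total group reaction. In
  directional games the fit's x-axis is the true disparity read off the
  log (known to the server, not to the members).
* Population (divide-by-N) variances by default; `ddof` is an argument
  where it matters.
* Standardized slopes (β) are slopes on z-scored variables, i.e. Pearson
  correlations for a single predictor.
* The group is the unit of analysis: games are averaged within groups
  before cell means, and member-level quantities are averaged within
  groups before regressions.
* Rounds-before-solution alignment (solved games only, window k = 6 by
  default): games shorter than the window contribute the rounds they have,
  without padding or exclusion.
* The feedback-change test classifies consecutive reactivity decreases by
  whether the driving broadcast changed direction, reports both class
  means, and compares them by a paired t test within members.
* A numeric round is "evenly divisible" when the broadcast magnitude is a
  multiple of n; a member "employs the normative strategy" on such a round
  when its next reactivity equals exactly magnitude/n in the feedback
  direction.

Degenerate inputs are explicit: single-group cells report no dispersion,
constant series report correlations as absent rather than NaN, single
member groups are excluded from between-member variance, and fewer than
two pairs in a feedback-change class suppresses the test.

## Model comparison

For each policy, R replicates (default 10,000 when matching the original
procedure; 500 in the test suite and acceptance script to keep runtimes in
minutes on one CPU) of the full session design produce a rounds-to-solution
PMF per group-size stratum, smoothed with an additive pseudocount ε
(default 10⁻⁴) so no observable outcome has zero mass. A reference log set
is scored as the sum over games of the log PMF mass at that game's outcome
in its stratum — games treated as independent, the simplest construction
consistent with scoring data against simulated outcome distributions; it
is a reconstruction, since the original likelihood was not specified.
Pairwise comparisons use χ² = 2·|ΔLL| with df = 1 (the mixtures differ
from the pure models by the single mixing weight; they are not textbook
nested, which is a recognized limitation of this convention). Recovery is
property-tested: Model-4-generated log sets score higher under Model 4's
PMF than under Model 3's in ≥95% of repeats, stably across ε from 10⁻³ to
10⁻⁵.

Mean-solution-time contrasts between policies are reported at two scales:
a one-sided Welch test over replicate grand means (power grows with R, so
any real gap separates), and the median across replicates of an unpaired
Welch test over the 18 per-group means — the power the empirical design
affords, which is the scale at which "no significant difference" among the
slower models is a meaningful statement.

## Synthetic fixture corpus

No human logs for this task were ever deposited, so the human-data
statistics are exercised on a synthetic corpus
(`gbsearch.fixtures.generate_fixtures`) with the qualitative structure the
analyses assume, produced by Model-4-style agents plus: occasional rounding
jitter on reactions (`guess_noise_sd`, `noise_prob`), members who freeze
with probability `dropout_prob` once their held reactivity is nearly spent
(`dropout_threshold`) — role differentiation near the solution — and
across-game improvement (`improvement_rate`): in later games initial
guesses center closer to a fair share of the actual target, with
proportionally tighter spread and gentler initial reactivities. The
generator (not the agents) uses the target for this, standing in for skill
the real players acquired. The corpus spans the empirical roster (18
groups, 106 distinct members) with alternating feedback schedules.

What passing fixture tests show: the statistics battery detects decreasing
reactivity after feedback changes, freezing near solutions, learning
trends, and the divisibility/normative-usage contrasts *when they are
present by construction*. They say nothing about effect sizes in real
human play, and none of the originally reported empirical values (cell
means, β, correlation or t values, divisibility percentages) is asserted
anywhere.

## Problem sizes and numerical choices

The test suite and acceptance script use 500 session replicates per model
configuration (the package's chosen balance of sampling error — about
±0.03 rounds standard error on a grand mean — against minutes-scale
runtimes) and R = 1,000 for the recovery property. Monte-Carlo tolerances
in tests are set from binomial/normal standard errors at those sizes.
Chi-square goodness-of-fit checks on samplers use α = .01. Ties in the
bisection baseline take the floor median. The CSV serializers are exact
round-trip (integers and enum strings only), and log validation rejects
rows whose sums, directions or magnitudes are mutually inconsistent,
naming the offending line.

## Known limitations

* The initial-guess distributions are stand-ins; absolute model means
  inherit an uncertainty of a round or so, and between-group variance is
  compressed relative to human groups (see above).
* The Model 4 decrement-certainty reading, while strongly constrained by
  the reference behavior, is an interpretation; the gated variant is one
  parameter away.
* The likelihood construction (independence across games, size-class
  strata, ε-smoothing) and the df = 1 convention are reconstructions.
* The normative policy's probabilistic-rounding form is itself a
  reconstruction from the even-division analysis it supports.
* Humans improve across games; the agent models deliberately do not (the
  fixture generator emulates improvement, the policies never learn).
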