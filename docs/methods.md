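# Methods

## Elicitation model and rank directions

Each ballot is a complete, tie-free ranking of one behaviour's barriers
on one attribute, on a scale `1..n` where `n` is the number of barriers.
Ballots are stored exactly as elicited (`direction="raw"`): raw rank 1 is
the *most* influential barrier, and the highest raw difficulty rank is
the *least* difficult barrier. All analysis converts to a single
canonical direction in which higher always means "better to target":
influence is reversed (`n + 1 − raw`), difficulty passes through
unchanged. Conversion happens downstream of parsing so raw files remain
auditable against the source data.

Eligibility is structural: each behaviour lists the professional groups
whose members may rank it (e.g. speech pathologists rank only the
swallow-screening barriers; bed managers only the stroke-unit transfer
barriers). A ballot from an ineligible group is a validation error by
default (`on_ineligible="drop"` downgrades it to a warning). A respondent
may skip an eligible behaviour entirely; aggregation simply uses the
ballots present. "Academic" is a demographic tag, not an eligibility
group: no behaviour grants it ballots.

## Individual summaries

Per barrier and attribute, the median and interquartile range of the
canonical ranks across ballots, sorted by descending median. Quartiles
use linear interpolation between closest ranks (numpy's default). The
bundled survey's published medians/IQRs are shipped as reference data
only: the raw ballots behind them were never published, so no quartile
convention can be confirmed against them, and they are not recomputed.

## Group ranking

The substrate is the pairwise-majority matrix: `prefer[a, b]` = number of
ballots ranking `a` strictly above `b` (canonical direction). Because
ballots are total orders, `prefer[a, b] + prefer[b, a]` equals the number
of ballots.

The consensus tool used for the bundled survey's published group ranks is
described only as a graph-theory-based voting system; its internals are
not public. The default rule here is therefore the **Schulze (beatpath)
method**: strength of the strongest path between two items in the
majority graph (widest-path computed by Floyd–Warshall relaxation, with
winning-votes edge weights) decides each pair; the induced strict
relation is transitive, Condorcet-consistent and monotone. The published
group ranks are treated as a data fixture, never as a recomputation
target. **Copeland** (wins − losses) and **exact Kemeny–Young** are
provided behind the same interface (`method=` flag); the desirability
classification depends only on the group ranks supplied to it, not on the
rule that produced them.

Tie-to-rank conversion: `rank(i) = n − #{j strictly better than i}`
(top-anchored competition ranks). Items no item beats share the top rank
`n`; a Condorcet winner holds it uniquely. Two items the strict relation
leaves incomparable may still receive different integer ranks if
different numbers of items beat them; `schulze_relation()` exposes the
underlying strict pairs when the distinction matters.

Exact Kemeny consensus minimises the summed pairwise disagreement with
the ballots. It is computed by dynamic programming over item subsets
(`O(2^n · n)` subset states), feasible to 12 items and verified in the
tests against independent exhaustive enumeration of all permutations.
Among co-optimal orders the lexicographically smallest by barrier id is
returned — a deterministic tie rule, which necessarily trades away label
neutrality in the (measure-zero) co-optimal case; Schulze, which breaks
no ties, is neutral outright.

## Desirability classification

Weak Pareto dominance: `a` dominates `b` iff `a` is at least as good on
both canonical ranks and strictly better on at least one. Weak (not
strict two-axis) dominance is deliberate: a barrier equal in influence
but harder to overcome than another is a worse target, and only the weak
form reproduces the bundled survey's published labels. Labels:

* **most desirable** — weakly dominates every other barrier;
* **desirable** — dominated by nothing, but not dominant over everything;
* **least desirable** — weakly dominated by at least one barrier.

Barriers exactly tied on both axes never dominate each other and share a
label; a barrier exactly tied with a would-be most-desirable barrier
shares the most-desirable label. That last rule is an extrapolation — no
such tie occurs in the bundled survey — chosen so that exact ties are
never split arbitrarily. The dominance relation is a strict partial
order; the classifier records the full edge list, so every
least-desirable barrier carries at least one explicit dominator. Labels
are invariant under any strictly increasing transform of either axis.
No influence-vs-difficulty trade-off weighting is attempted: the method
deliberately refuses to compare incomparable (frontier) barriers.

## Panel simulator

`simulate_panel` emulates the study design end-to-end: a panel of
(group, count) members — default 3 EN, 3 EDr, 3 SN, 3 SDr, 3 SP, 2 BM,
n = 17, matching the bundled survey — each ranking every behaviour their
group is eligible for, on both attributes, as independent Mallows draws
around a per-behaviour/attribute reference order (default: the
catalogue's barrier order).

The Mallows model, `P(π) ∝ exp(−θ · d_τ(π, ref))` with Kendall-tau
distance `d_τ`, was chosen over Plackett–Luce for its single
interpretable noise parameter with "consensus + noise" semantics.
Sampling is by repeated insertion, which is exact: inserting the i-th
reference item at position j creates exactly `i − j` inversions, so
insertion weights `exp(−θ(i − j))` factorise the target distribution.
`θ = 0` gives uniform permutations; at very large `θ` the insertion
weights underflow to the reference position, so the limit is exact rather
than approximate. The default dispersion `θ = 2` represents a panel in
broad but imperfect agreement (an adjacent transposition is `e² ≈ 7.4`
times less likely than not); at that noise level the acceptance script
measures ≥ 98% top-barrier recovery per behaviour/attribute across 200
replicates of the 17-member panel, comfortably above the 95% calibration
threshold asserted by the test suite.

What the simulator does **not** model: group-specific consensus
(all groups share one truth), respondent covariate effects, and
missing-at-random ballot dropout. Passing tests on simulated panels
therefore demonstrate correct aggregation and classification under
exchangeable noisy rankers, not robustness to systematic inter-group
disagreement.

## Numerical and design conventions

* Percentages in demographics are `100·count/n` rounded to one decimal.
* All randomness flows through an explicit `numpy` `Generator` or an
  integer seed in a config object; there is no hidden global state.
* Plot jitter for coincident points is derived from an MD5 hash of the
  barrier id (angle on a circle of radius 0.12 rank units), so figures
  are reproducible run to run; axis limits are fixed to
  `[0.5, n + 0.5]` for comparability across behaviours.
* Group-rank files and ballot files are plain delimited text with
  autodetected comma/tab separators; the catalogue also accepts a YAML
  form.
* The verification studies run at deliberately modest problem sizes —
  ≤ 6 items for the axiom suites, ≤ 5 for the exhaustive Kemeny
  comparisons, 200 simulation replicates — sizes at which exhaustive
  oracles are exact and the whole suite stays fast while estimating the
  relevant proportions to within a few percentage points.

## Known limitations

* The published group ranks of the bundled survey cannot be re-derived
  from ballots (unpublished), so the pipeline's aggregation stage is
  validated axiomatically and against oracles rather than against the
  survey itself; the classification stage, by contrast, round-trips the
  published table exactly.
* The bundled respondent table reproduces the published demographic
  *marginals*; the joint assignment of categories to individual panel
  members is synthetic (see `datasets.study_respondents`).
* Exact Kemeny aggregation is exponential in the number of items and
  capped at 12; the bundled catalogue's maximum is 9.
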