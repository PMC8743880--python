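# Methods

This note documents the statistical machinery implemented in `domstrat`, the
choices made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Data model

An interaction record holds an actor, a recipient, an interaction type, its
a-priori cost category, and the set of individuals present when the
interaction occurred. Eight interaction types map to three categories:
higher-cost aggressive (SPI, TAI, CHA — grabs, spins, chases), lower-cost
aggressive (PEC, DIS, GAP — pecks, displacements, gapes) and submissive (SUV,
SUB). For aggressive interactions the actor is the winner; for submissive
ones the actor performs the subordination signal and is therefore the loser.
The present set is mandatory: the permutation null is undefined without
subgroup composition, so records lacking it are rejected rather than imputed.
Analyses are run within one group and one category at a time; data splitting
never crosses those boundaries.

## Hierarchy inference (randomized Elo)

Sequential Elo updates the winner's and loser's scores after each
interaction by `K·(1−E)` with the logistic expectation
`E = 1/(1 + 10^((s_loser − s_winner)/400))`; total score is conserved
exactly. Because a single pass is order-dependent, the stream is replayed
under `n_orderings` uniformly random permutations and final scores are
averaged; ranks follow descending mean score, with ties broken
deterministically by individual id. Normalized scores are the min–max
rescaling of mean scores to [0, 1], which makes score-based differences
comparable across runs.

Defaults: K = 200, initial score 1000, 1000 orderings. These constants set
only the score scale; with steep hierarchies (P_w ≈ 0.9) the recovered rank
*order* is insensitive to them, and all are configurable. Individuals that
never win or lose an interaction carry no dominance information and are
excluded from the ranking with a warning.

Two diagnostics accompany inference: Spearman correlation between two
hierarchies on their shared individuals, and split-half repeatability (each
repeat optionally subsamples a fraction of the events, bisects them 50/50,
ranks each half independently and correlates the two rank vectors; the mean
rho and its empirical 95% range are reported).

## Signed hierarchy differences

For a directed dyad (actor a, recipient b), the rank difference is
`rank(a) − rank(b)`: negative when the actor outranks the recipient (an
actor ranked 4 acting on a recipient ranked 6 sits at −2). The score-based
difference uses normalized scores with the same sign convention, lying in
[−1, 1] and equal to the rank difference divided by N−1 when scores are
equally spaced.

## Permutation null and tendency to interact

The null model redraws recipients within the realized opportunity structure:
one interaction is selected uniformly, its actor removed from the list of
individuals present, and a new recipient drawn uniformly from the remainder
(possibly the original). This is iterated `n_permutations` times (default
100 000) and the dataset after the final step is the permuted dataset.
Because every redraw is independent of the chain state and only the last
redraw of an event survives, the final state is simulated exactly by drawing
the selection counts (multinomial) and giving each selected event one uniform
redraw — distribution-identical to the literal chain at any chain length,
and validated in the tests against the analytic stationary expectation
`E[count(a → b)] = Σ_{events: actor a, b present} 1/(|present| − 1)`.

The tendency to interact is the elementwise difference between observed and
permuted directed count matrices. Actors are never permuted, so per-actor
row sums of the tendency matrix are exactly zero (integer arithmetic), and
so is its grand total — conservation laws asserted in every analysis
iteration.

Counting is dyadic, not per rank difference: with N individuals there are
N−k directed dyads at difference −k, so pooling counts by difference would
manufacture structure under the null. Each directed dyad contributes one
point (difference, tendency) to the model below.

## Spline smoothing and the uncertainty band

Tendency versus signed difference is smoothed with penalized cubic B-splines
(roughness penalty = integrated squared second derivative, computed exactly;
interior knots at quantiles of the unique abscissae, at most 10). Separate
and independent fits are made for differences below and above zero: a single
spline forced through the origin would shrink a genuine close-competitor
signal at −1 toward the +1 side. A side with fewer than four distinct
abscissae is reported as absent.

The amount of smoothing is specified as a target effective degrees of
freedom per side (default 3), solved via the Demmler–Reinsch
eigendecomposition so that the smoother trace equals the target. A raw
roughness weight (default 0.04) can be supplied instead, but such weights
are implementation-specific in scale, so effective df is the portable
contract and the default criterion.

The full analysis repeats the chain — fresh uniform 30/70 split (hierarchy /
strategy; half-up rounding of the subset size), hierarchy, observed counts,
one permuted dataset, tendency, dyad series, side-split splines — for
`n_iterations` (default 500) independent iterations, evaluating predictions
on a fixed grid: integer differences ±1..±(N−1) for rank-based runs, 49
evenly spaced points per side of [−1, 1] for score-based runs (zero excluded
in both). The band is the pointwise median and empirical 2.5/97.5
percentiles across iterations; a grid point is labelled `above`/`below` when
the whole 95% range is above/below zero, `ns` otherwise. One permuted
dataset per iteration is used (not an average over permuted datasets):
uncertainty comes from the repeated outer iterations.

Two numerical choices at the tails: grid points outside an iteration's own
data range use linear extrapolation from the boundary value and slope (cubic
polynomial extrapolation is unstable exactly where dyads are sparsest), and
every grid point reports the share of iterations in which its prediction was
extrapolated, so users can discount unstable tails. Iterations that fail
(e.g. a degenerate split that leaves fewer than two rankable individuals)
are dropped and counted, not redrawn. Within an iteration, individuals not
sampled into the hierarchy subset contribute no dyads to the spline input
for that iteration; the conservation checks are computed on the full
tendency matrix before this restriction.

## Bayes-rule cost allocation

Within pooled aggressive interactions, the probability that an interaction
at signed rank difference R is higher-cost is
`P(A_h|R) = P(R|A_h)·P(A_h)/P(R)`, algebraically equal to the conditional
frequency `n_high(R)/(n_high(R)+n_low(R))` — an identity the tests assert to
1e−12. The baseline `P(A_h)` is the overall higher-cost share. Uncertainty
uses a percentile bootstrap with the interaction event as the resampling
unit, drawn with replacement from the pooled aggressive events (total count
preserved; default 1000 replicates), so the replicate-level baseline varies
as the formula's P(A_h) should. Differences absent from a replicate
contribute nothing to that replicate's percentiles. A difference is labelled
`above`/`below` when its interval lies entirely above/below the baseline.
The hierarchy feeding this analysis defaults to randomized-Elo ranks from
the pooled aggressive events of the full dataset (no split): pooling
maximizes rank precision and is neutral between the two cost categories; any
externally supplied hierarchy can be used instead.

## Agent-based simulator

The simulator emulates a closed fission–fusion group: N individuals with
fixed latent ranks 1..N meet in X subgroups and one dyadic contest occurs
per subgroup.

* Membership. Random mode: each individual enters a subgroup independently
  with probability G/N. Assorted mode: each subgroup draws a target rank z
  uniformly on 1..N; inclusion weights are the Normal(z, sd=2) density at
  each rank, rescaled by a common factor to sum to G, then capped at 1. The
  cap-and-stop rule (no re-normalization after capping) keeps the stated
  binomial process intact; at the default geometry (N=20, G=5, sd=2) the cap
  rarely binds, and realized mean subgroup sizes are logged. Subgroups are
  redrawn wholesale until they have at least two members.
* Contest. Two distinct members are drawn uniformly; the more dominant wins
  with probability `1 − (1 − P_w)^{r_d}` and is recorded as the actor, the
  loser as recipient, the subgroup as the present set.
* Strategy injection (validation only; off by default). A kernel over signed
  rank difference selects the target given a uniformly drawn initiator
  (uniform fallback when no candidate has positive weight); the contest then
  decides the actor as usual. With the kernel off, recipient identity is —
  conditional on the drawn pair — independent of rank difference: the ground
  truth the pipeline must label "no strategy".

Defaults are the standard validation scenario: N=20, X=100, G=5, P_w=0.9.
Ranks never change within a simulation; there are no bouts, escalation, or
spatial structure beyond subgroup membership.

What the simulator does *not* emulate: observation effort that varies across
individuals or time, detectability differences between interaction types,
rank dynamics, or multiple interactions per subgroup. Passing the validation
suite therefore shows that the pipeline is unconfounded by rank-assorted
opportunity and recovers injected recipient preferences at the simulated
data density — not that every field sampling artefact is handled.

## Validation contracts and problem sizes

The test-suite asserts, among others: exact conservation of tendency row
sums; Monte-Carlo convergence of permuted counts to the analytic
expectation (3 SE, elementwise); zero significant grid points under
rank-assorted null simulations in ≥9 of 10 seeded runs (100 outer
iterations, 1000 permutations each) while raw close-in-rank counts are
visibly inflated; recovery of an injected close-competitor kernel at
difference −1 in ≥8 of 10 runs; hierarchy recovery (Spearman > 0.9 versus
latent ranks) and split-half repeatability > 0.9 at ~50 participations per
individual. Heavy stochastic checks use 100–150 outer iterations, 200–500
Elo orderings and X = 500–700 subgroups — sizes chosen so the full suite
runs in well under a coffee break while keeping Monte-Carlo error far from
the asserted margins. The close-competitor recovery scenario uses X = 700
because resolving *adjacent* ranks in the 30% hierarchy subset needs roughly
20 observations per individual there.

## Known limitations

* The permutation null conditions on the realized present sets; it cannot
  disentangle strategies that operate through subgroup *choice* itself.
* Spline tails at extreme rank differences rest on one or few dyads; the
  extrapolation-share column flags, but does not fix, that sparsity.
* Score-based analyses inherit min–max normalization's sensitivity to the
  two extreme individuals.
* The bootstrap for cost allocation treats events as exchangeable; dyad-level
  dependence (repeated interactions within a dyad) is not resampled
  hierarchically.
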