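"""Randomized-Elo dominance hierarchy inference and rank diagnostics.

Elo scoring is order-dependent: the same set of wins and losses yields
different final scores depending on the sequence they are processed in. The
randomized variant removes this dependence by replaying the interaction
stream under many uniformly random orderings and averaging each individual's
final score across orderings; ranks are assigned by descending mean score.

Winner extraction is centralized here: for aggressive interactions the actor
is the winner; for submissive interactions the actor (the individual
performing the subordination signal) is the loser, so the winner is the
recipient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data import SUBMISSIVE, InteractionDataset, InteractionEvent
from .errors import InsufficientDataError, ParameterError, UnrankedIndividualError

__all__ = [
    "EloConfig",
    "Hierarchy",
    "EloExclusionWarning",
    "elo_update",
    "winner_loser",
    "randomized_elo_ranks",
    "rank_difference",
    "score_difference",
    "hierarchy_correlation",
    "repeatability",
    "RepeatabilityResult",
]


class EloExclusionWarning(UserWarning):
    """Raised when individuals without interactions are dropped from ranking."""


@dataclass(frozen=True)
class EloConfig:
    """Randomized-Elo parameters.

    K is the per-interaction update magnitude and init_score the common
    starting score; with the classic base-10/scale-400 logistic expectation
    these only set the score scale, and with steep hierarchies the resulting
    rank order is insensitive to them. n_orderings controls how many random
    replays are averaged.
    """

    k: float = 200.0
    init_score: float = 1000.0
    n_orderings: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.k <= 0:
            raise ParameterError("K must be positive")
        if self.n_orderings < 1:
            raise ParameterError("n_orderings must be >= 1")


@dataclass(frozen=True)
class Hierarchy:
    """Inferred hierarchy: integer ranks (1 = most dominant) and scores.

    norm_score is the min–max rescaling of mean_score to [0, 1] (1 = most
    dominant), which makes score differences comparable across runs whose raw
    Elo ranges differ.
    """

    ids: tuple
    rank: dict
    mean_score: dict
    norm_score: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.norm_score:
            scores = np.array([self.mean_score[i] for i in self.ids])
            span = scores.max() - scores.min()
            if span > 0:
                norm = (scores - scores.min()) / span
            else:
                norm = np.full(len(scores), 0.5)
            object.__setattr__(
                self, "norm_score",
                {i: float(s) for i, s in zip(self.ids, norm)},
            )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def ordered_ids(self) -> tuple:
        """Ids sorted from most to least dominant."""
        return tuple(sorted(self.ids, key=lambda i: self.rank[i]))


def elo_update(winner_score: float, loser_score: float, k: float
               ) -> tuple[float, float]:
    """One Elo step: the winner gains k*(1-E), the loser loses the same.

    E = 1 / (1 + 10**((loser - winner)/400)) is the winner's expected score;
    total score is conserved exactly.
    """
    e = 1.0 / (1.0 + 10.0 ** ((loser_score - winner_score) / 400.0))
    delta = k * (1.0 - e)
    return winner_score + delta, loser_score - delta


def winner_loser(event: InteractionEvent) -> tuple[str, str]:
    """Map an event to (winner, loser) according to its cost category."""
    if event.category == SUBMISSIVE:
        return event.recipient, event.actor
    return event.actor, event.recipient


def randomized_elo_ranks(events: Iterable[InteractionEvent],
                         config: EloConfig | None = None,
                         rng: np.random.Generator | None = None) -> Hierarchy:
    """Infer a hierarchy by averaging Elo over random replays of the stream.

    Individuals that appear only in present sets (never as winner or loser)
    carry no dominance information and are excluded with an
    EloExclusionWarning. Ties in mean score are broken deterministically by
    individual id.
    """
    if config is None:
        config = EloConfig()
    if isinstance(events, InteractionDataset):
        universe = set(events.individuals)
        events = events.events
    else:
        events = tuple(events)
        universe = None
    pairs = [winner_loser(e) for e in events]
    ids = sorted({i for p in pairs for i in p})
    if len(ids) < 2:
        raise InsufficientDataError(
            "need interactions among at least two individuals"
        )
    if universe is not None and len(universe - set(ids)) > 0:
        warnings.warn(
            f"{len(universe - set(ids))} individual(s) with no interactions "
            "excluded from ranking",
            EloExclusionWarning,
            stacklevel=2,
        )
    idx = {v: i for i, v in enumerate(ids)}
    winners = np.array([idx[w] for w, _ in pairs])
    losers = np.array([idx[l] for _, l in pairs])

    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, n_ev, n_ind = config.n_orderings, len(pairs), len(ids)
    # One random replay per row; steps are sequential over event positions but
    # vectorized across replays.
    perms = np.argsort(rng.random((m, n_ev)), axis=1)
    scores = np.full((m, n_ind), config.init_score, dtype=float)
    rows = np.arange(m)
    for t in range(n_ev):
        ev = perms[:, t]
        w, l = winners[ev], losers[ev]
        sw, sl = scores[rows, w], scores[rows, l]
        e = 1.0 / (1.0 + 10.0 ** ((sl - sw) / 400.0))
        delta = config.k * (1.0 - e)
        scores[rows, w] = sw + delta
        scores[rows, l] = sl - delta
    mean = scores.mean(axis=0)
    order = sorted(range(n_ind), key=lambda i: (-mean[i], ids[i]))
    rank = {ids[i]: r + 1 for r, i in enumerate(order)}
    return Hierarchy(
        ids=tuple(ids),
        rank=rank,
        mean_score={ids[i]: float(mean[i]) for i in range(n_ind)},
    )


def _require_ranked(h: Hierarchy, *ids: str) -> None:
    for i in ids:
        if i not in h.rank:
            raise UnrankedIndividualError(f"individual {i!r} is not ranked")


def rank_difference(h: Hierarchy, actor: str, recipient: str) -> int:
    """Signed rank difference rank(actor) − rank(recipient).

    Negative when the actor outranks the recipient: an actor ranked 4 acting
    on a recipient ranked 6 sits at −2, and the reverse direction at +2.
    """
    _require_ranked(h, actor, recipient)
    return h.rank[actor] - h.rank[recipient]


def score_difference(h: Hierarchy, actor: str, recipient: str) -> float:
    """Signed normalized-score difference in [−1, 1] (same sign convention)."""
    _require_ranked(h, actor, recipient)
    return h.norm_score[recipient] - h.norm_score[actor]


def hierarchy_correlation(h1: Hierarchy, h2: Hierarchy) -> float:
    """Spearman rank correlation between two hierarchies (shared individuals).

    Warns if the individual sets differ; requires at least 3 shared ids.
    """
    shared = sorted(set(h1.ids) & set(h2.ids))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared individuals, got {len(shared)}"
        )
    if len(shared) < max(len(h1.ids), len(h2.ids)):
        warnings.warn(
            "hierarchies cover different individuals; using the "
            f"{len(shared)}-individual intersection",
            UserWarning,
            stacklevel=2,
        )
    r1 = [h1.rank[i] for i in shared]
    r2 = [h2.rank[i] for i in shared]
    return float(stats.spearmanr(r1, r2).statistic)


@dataclass(frozen=True)
class RepeatabilityResult:
    """Split-half repeatability of an inferred hierarchy."""

    mean_rho: float
    lo: float
    hi: float
    rhos: tuple


def repeatability(events: Sequence[InteractionEvent],
                  subset_fraction: float = 1.0,
                  n_repeats: int = 20,
                  rng: np.random.Generator | int | None = None,
                  config: EloConfig | None = None) -> RepeatabilityResult:
    """Split-half hierarchy repeatability (mean Spearman rho across repeats).

    Each repeat optionally subsamples subset_fraction of the events (without
    replacement; 1.0 uses all of them), randomly bisects the result into two
    halves, infers ranks on each half, and correlates the two rank vectors.
    Returns the mean rho with its empirical 95% range.
    """
    if not 0.0 < subset_fraction <= 1.0:
        raise ParameterError("subset_fraction must be in (0, 1]")
    events = tuple(events)
    gen = np.random.default_rng(rng)
    if config is None:
        config = EloConfig()
    rhos = []
    for _ in range(n_repeats):
        pool = events
        if subset_fraction < 1.0:
            k = int(np.floor(subset_fraction * len(events) + 0.5))
            pick = gen.choice(len(events), size=k, replace=False)
            pool = tuple(events[i] for i in pick)
        if len(pool) < 4:
            raise InsufficientDataError("too few events for split-half analysis")
        idx = gen.permutation(len(pool))
        half = len(pool) // 2
        a = [pool[i] for i in idx[:half]]
        b = [pool[i] for i in idx[half:]]
        ha = randomized_elo_ranks(a, config, rng=gen)
        hb = randomized_elo_ranks(b, config, rng=gen)
        rhos.append(hierarchy_correlation(ha, hb))
    arr = np.array(rhos)
    return RepeatabilityResult(
        mean_rho=float(arr.mean()),
        lo=float(np.percentile(arr, 2.5)),
        hi=float(np.percentile(arr, 97.5)),
        rhos=tuple(float(r) for r in arr),
    )
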