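"""Agent-based simulator of dominance interactions in a fission–fusion group.

A closed group of N individuals holds fixed latent ranks 1..N (1 = most
dominant). The group repeatedly fragments into temporary subgroups; within
each subgroup a single dyadic contest occurs between two members drawn at
random, and the more dominant contestant wins with probability

    P_win = 1 - (1 - P_w) ** r_d

where P_w is the dominant's win probability at rank difference 1 and r_d the
absolute rank difference. The winner is recorded as the actor, the loser as
the recipient, and the subgroup membership as the present set — exactly the
record structure the analysis pipeline consumes.

Subgroup membership is binomial per individual. In the *random* scenario
every individual is included with probability G/N (G = target mean subgroup
size). In the *rank-assorted* scenario each subgroup first draws a target
rank z uniformly on 1..N and inclusion weights follow a Gaussian kernel of
standard deviation 2 centred on z, rescaled to sum to G. Rank assortment
makes close-in-rank dyads co-occur more often — the confound the permutation
null must absorb.

An optional recipient-preference kernel over signed rank difference can be
injected to create a known targeting strategy for parameter-recovery tests;
it is off by default (no strategy = ground truth null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import HIGHER_COST, CATEGORY_BY_TYPE, InteractionDataset, InteractionEvent
from .errors import ParameterError

__all__ = [
    "ABMConfig",
    "SubgroupDraw",
    "assortment_weight",
    "membership_probs",
    "draw_subgroup",
    "win_probability",
    "simulate_interaction",
    "simulate_dataset",
    "individual_id",
    "true_ranks",
]

_ASSORT_SD = 2.0  # kernel sd of the rank-assortment Gaussian


@dataclass(frozen=True)
class ABMConfig:
    """Simulation parameters.

    n_individuals: N, group size; latent ranks are 1..N.
    n_subgroups:   X, number of subgroups (one interaction each).
    mean_size:     G, target mean subgroup size.
    p_win:         P_w, dominant's win probability at rank difference 1.
    assorted:      rank-assorted (True) vs random (False) subgroup membership.
    strategy:      optional recipient-preference kernel mapping signed rank
                   difference (initiator rank − target rank) to a non-negative
                   weight; None means partners are chosen uniformly.
    """

    n_individuals: int = 20
    n_subgroups: int = 100
    mean_size: float = 5.0
    p_win: float = 0.9
    assorted: bool = False
    strategy: Mapping[int, float] | None = None
    seed: int | None = None
    group_id: str = "sim"
    type_code: str = "CHA"

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ParameterError("n_individuals must be >= 2")
        if self.n_subgroups < 1:
            raise ParameterError("n_subgroups must be >= 1")
        if not 2 <= self.mean_size <= self.n_individuals:
            raise ParameterError("mean_size must be in [2, n_individuals]")
        if not 0.5 < self.p_win <= 1.0:
            raise ParameterError("p_win must be in (0.5, 1]")
        if self.type_code not in CATEGORY_BY_TYPE:
            raise ParameterError(f"unknown type_code {self.type_code!r}")
        if self.strategy is not None:
            if any(w < 0 for w in self.strategy.values()):
                raise ParameterError("strategy weights must be non-negative")


@dataclass(frozen=True)
class SubgroupDraw:
    """One realized subgroup: member ranks and the assortment target (if any)."""

    members: tuple  # ranks of members, ascending
    target_rank: int | None = None


def individual_id(rank: int) -> str:
    """Stable id for the individual holding a given latent rank."""
    return f"i{rank:03d}"


def true_ranks(n: int) -> dict:
    """Ground-truth rank mapping id -> rank for a simulated group of size n."""
    return {individual_id(r): r for r in range(1, n + 1)}


def assortment_weight(r_j: float, z: float) -> float:
    """Gaussian inclusion weight: density of Normal(z, sd=2) at rank r_j."""
    return math.exp(-((r_j - z) ** 2) / (2.0 * _ASSORT_SD ** 2)) / (
        _ASSORT_SD * math.sqrt(2.0 * math.pi)
    )


def membership_probs(config: ABMConfig, z: int | None = None) -> np.ndarray:
    """Per-individual subgroup inclusion probabilities (index = rank − 1).

    Random mode (z is None): every individual enters with probability G/N.
    Assorted mode: Gaussian weights centred on the target rank z, rescaled by
    a common factor so they sum to G, then capped at 1. The cap rarely binds
    at the default geometry (N=20, G=5, sd=2); any post-cap shortfall of the
    sum below G is accepted rather than re-normalized.
    """
    n, g = config.n_individuals, config.mean_size
    if (z is None) == config.assorted:
        raise ParameterError("target rank z must be given iff assorted")
    if z is None:
        return np.full(n, g / n)
    ranks = np.arange(1, n + 1, dtype=float)
    w = np.exp(-((ranks - z) ** 2) / (2.0 * _ASSORT_SD ** 2)) / (
        _ASSORT_SD * math.sqrt(2.0 * math.pi)
    )
    probs = w * (g / w.sum())
    return np.minimum(probs, 1.0)


def draw_subgroup(probs: np.ndarray, rng: np.random.Generator,
                  target_rank: int | None = None) -> SubgroupDraw:
    """Draw a subgroup by independent Bernoulli inclusion per individual.

    The whole subgroup is redrawn until it has at least two members, which
    preserves the stated binomial process conditionally on the minimum size.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ParameterError("inclusion probabilities must lie in [0, 1]")
    if np.count_nonzero(probs) < 2:
        raise ParameterError(
            "fewer than two individuals have positive inclusion probability; "
            "a subgroup of size >= 2 is impossible"
        )
    while True:
        inc = rng.random(probs.shape) < probs
        if inc.sum() >= 2:
            members = tuple(int(r) for r in np.nonzero(inc)[0] + 1)
            return SubgroupDraw(members=members, target_rank=target_rank)


def win_probability(p_w: float, r_d: int) -> float:
    """Probability that the more dominant contestant wins at rank distance r_d."""
    if r_d < 1 or int(r_d) != r_d:
        raise ParameterError(f"r_d must be an integer >= 1, got {r_d}")
    return 1.0 - (1.0 - p_w) ** r_d


def _choose_pair(members: Sequence[int], strategy: Mapping[int, float] | None,
                 rng: np.random.Generator) -> tuple:
    """Draw (initiator_rank, target_rank) from a subgroup.

    Without a strategy both are uniform without replacement. With a kernel the
    initiator is uniform and the target is drawn among remaining members with
    probability proportional to kernel(initiator − target); if every candidate
    has zero weight the target falls back to uniform.
    """
    members = list(members)
    if strategy is None:
        i, j = rng.choice(len(members), size=2, replace=False)
        return members[int(i)], members[int(j)]
    init = members[int(rng.integers(len(members)))]
    cands = [m for m in members if m != init]
    w = np.array([strategy.get(init - c, 0.0) for c in cands], dtype=float)
    if w.sum() <= 0:
        tgt = cands[int(rng.integers(len(cands)))]
    else:
        tgt = cands[int(rng.choice(len(cands), p=w / w.sum()))]
    return init, tgt


def simulate_interaction(members: Sequence[int], p_w: float,
                         rng: np.random.Generator,
                         strategy: Mapping[int, float] | None = None,
                         event_id: str = "e0", order: int = 0,
                         group_id: str = "sim",
                         type_code: str = "CHA") -> InteractionEvent:
    """Simulate one dyadic contest within a subgroup of latent ranks.

    Two distinct members are drawn (see _choose_pair), the more dominant wins
    with probability win_probability(p_w, r_d), and the winner is recorded as
    the actor, the loser as the recipient; present = the whole subgroup.
    """
    if len(members) < 2:
        raise ParameterError("a contest needs at least two present individuals")
    a, b = _choose_pair(members, strategy, rng)
    dominant, subordinate = (a, b) if a < b else (b, a)
    p = win_probability(p_w, abs(a - b))
    if rng.random() < p:
        winner, loser = dominant, subordinate
    else:
        winner, loser = subordinate, dominant
    return InteractionEvent(
        event_id=event_id,
        order=order,
        group_id=group_id,
        actor=individual_id(winner),
        recipient=individual_id(loser),
        type_code=type_code,
        category=CATEGORY_BY_TYPE[type_code],
        present=frozenset(individual_id(m) for m in members),
    )


def simulate_dataset(config: ABMConfig,
                     rng: np.random.Generator | None = None
                     ) -> InteractionDataset:
    """Run the full simulation: X subgroups, one interaction per subgroup.

    In assorted mode a fresh target rank z is drawn uniformly on 1..N for
    every subgroup. Event order equals the subgroup index, so the dataset is
    reproducible byte-for-byte under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = []
    for j in range(config.n_subgroups):
        if config.assorted:
            z = int(rng.integers(1, config.n_individuals + 1))
            probs = membership_probs(config, z)
        else:
            z = None
            probs = membership_probs(config)
        sg = draw_subgroup(probs, rng, target_rank=z)
        events.append(
            simulate_interaction(
                sg.members, config.p_win, rng, strategy=config.strategy,
                event_id=f"e{j:05d}", order=j, group_id=config.group_id,
                type_code=config.type_code,
            )
        )
    return InteractionDataset(tuple(events))
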