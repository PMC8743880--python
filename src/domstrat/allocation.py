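"""Bayes-rule allocation of higher- vs lower-cost aggression by rank difference.

Within the pooled aggressive interactions, the probability that an
interaction expressed at signed rank difference R is of the higher-cost kind
is computed with Bayes' rule,

    P(A_h | R) = P(R | A_h) P(A_h) / P(R),

where A_h is the higher-cost class, P(A_h) the overall higher-cost share (the
baseline), P(R | A_h) the distribution of rank differences among higher-cost
events and P(R) the same distribution over all aggressive events. The
formula reduces algebraically to the conditional frequency
n_high(R) / (n_high(R) + n_low(R)); the explicit Bayes form is kept because
the baseline P(A_h) is itself a reported quantity, and the identity doubles
as an internal consistency check in the test-suite.

Uncertainty comes from a nonparametric bootstrap over the pooled events
(resampled with replacement, preserving the total count), so the baseline
varies across replicates exactly as the formula's P(A_h) should.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import InteractionEvent
from .errors import InsufficientDataError, ParameterError
from .hierarchy import Hierarchy, rank_difference, score_difference

__all__ = [
    "CostAllocationResult",
    "prob_high_given_rankdiff",
    "bootstrap_allocation",
    "deviation_from_baseline",
]


@dataclass(frozen=True)
class CostAllocationResult:
    """P(higher-cost | rank difference) with optional bootstrap intervals."""

    rank_diffs: np.ndarray
    p_high: np.ndarray
    baseline: float
    n_high: np.ndarray
    n_low: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    n_boot: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank_diff": self.rank_diffs,
                "p_high": self.p_high,
                "n_high": self.n_high,
                "n_low": self.n_low,
            }
        )
        if self.lo is not None:
            df["lo"] = self.lo
            df["hi"] = self.hi
        df["baseline"] = self.baseline
        return df


def _event_diffs(events: Sequence[InteractionEvent], h: Hierarchy,
                 difference_kind: str) -> np.ndarray:
    fn = rank_difference if difference_kind == "rank" else score_difference
    return np.array([fn(h, e.actor, e.recipient) for e in events], dtype=float)


def _bayes_p_high(diffs_high: np.ndarray, diffs_low: np.ndarray,
                  support: np.ndarray) -> np.ndarray:
    """P(A_h | R) on a support of rank differences, via the Bayes formula."""
    n_h, n_l = len(diffs_high), len(diffs_low)
    n = n_h + n_l
    p_ah = n_h / n
    p_r_given_ah = np.array([(diffs_high == r).sum() for r in support]) / max(n_h, 1)
    all_diffs = np.concatenate([diffs_high, diffs_low])
    p_r = np.array([(all_diffs == r).sum() for r in support]) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = p_r_given_ah * p_ah / p_r
    out[p_r == 0] = np.nan
    return out


def prob_high_given_rankdiff(high_events: Sequence[InteractionEvent],
                             low_events: Sequence[InteractionEvent],
                             h: Hierarchy,
                             difference_kind: str = "rank"
                             ) -> CostAllocationResult:
    """Point estimates of P(higher-cost | R) at every observed difference R.

    Differences with no aggressive events are omitted (the conditional is
    undefined there). The baseline is the overall higher-cost share.
    """
    high_events, low_events = tuple(high_events), tuple(low_events)
    if not high_events and not low_events:
        raise InsufficientDataError("no aggressive events supplied")
    dh = _event_diffs(high_events, h, difference_kind)
    dl = _event_diffs(low_events, h, difference_kind)
    support = np.unique(np.concatenate([dh, dl]))
    p = _bayes_p_high(dh, dl, support)
    return CostAllocationResult(
        rank_diffs=support,
        p_high=p,
        baseline=len(dh) / (len(dh) + len(dl)),
        n_high=np.array([(dh == r).sum() for r in support]),
        n_low=np.array([(dl == r).sum() for r in support]),
    )


def bootstrap_allocation(high_events: Sequence[InteractionEvent],
                         low_events: Sequence[InteractionEvent],
                         h: Hierarchy,
                         n_boot: int = 1000,
                         rng: np.random.Generator | int | None = None,
                         difference_kind: str = "rank"
                         ) -> CostAllocationResult:
    """Point estimates plus percentile bootstrap 95% intervals of P(A_h | R).

    The resampling unit is the interaction event, drawn with replacement from
    the pooled aggressive events (total count preserved). A difference absent
    from a replicate contributes nothing to that replicate's percentiles.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    point = prob_high_given_rankdiff(high_events, low_events, h,
                                     difference_kind)
    gen = np.random.default_rng(rng)
    dh = _event_diffs(tuple(high_events), h, difference_kind)
    dl = _event_diffs(tuple(low_events), h, difference_kind)
    diffs = np.concatenate([dh, dl])
    is_high = np.concatenate(
        [np.ones(len(dh), dtype=bool), np.zeros(len(dl), dtype=bool)]
    )
    support = point.rank_diffs
    m = len(support)
    # map every event's difference to its support slot once; replicates then
    # reduce with bincount (== the Bayes formula, see module docstring)
    diff_idx = np.searchsorted(support, diffs)
    n = len(diffs)
    reps = np.full((n_boot, m), np.nan)
    for b in range(n_boot):
        take = gen.integers(0, n, size=n)
        di, hmask = diff_idx[take], is_high[take]
        tot = np.bincount(di, minlength=m)
        high = np.bincount(di[hmask], minlength=m)
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[b] = np.where(tot > 0, high / np.maximum(tot, 1), np.nan)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)
    return CostAllocationResult(
        rank_diffs=support,
        p_high=point.p_high,
        baseline=point.baseline,
        n_high=point.n_high,
        n_low=point.n_low,
        lo=lo,
        hi=hi,
        n_boot=n_boot,
    )


def deviation_from_baseline(result: CostAllocationResult) -> tuple:
    """Per-difference label vs the baseline: above / below / ns.

    above when the whole interval sits above the baseline higher-cost share,
    below when it sits entirely below, ns otherwise (or if intervals are
    missing at that difference).
    """
    if result.lo is None or result.hi is None:
        raise ParameterError("result has no bootstrap intervals")
    labels = []
    for l, h_ in zip(result.lo, result.hi):
        if np.isnan(l) or np.isnan(h_):
            labels.append("ns")
        elif l > result.baseline:
            labels.append("above")
        elif h_ < result.baseline:
            labels.append("below")
        else:
            labels.append("ns")
    return tuple(labels)
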