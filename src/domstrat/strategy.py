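"""Tendency-to-interact analysis: permutation null, splines, uncertainty band.

The core statistic is, for every directed dyad (actor a, recipient b), the
observed interaction count minus the count expected when recipients are
re-drawn uniformly among the individuals that were actually present when each
interaction happened. Zero means a interacts with b exactly as often as the
subgroup structure alone predicts; positive/negative values mean more/less
often. Because the permutation never touches actors, per-actor totals are
conserved and every tendency matrix has exact zero row sums.

The full analysis repeats the whole chain (random data split -> hierarchy on
one part -> observed and permuted counts on the other -> tendency -> spline
over signed hierarchy difference, fitted separately below and above zero)
many times, and summarizes the spline predictions pointwise by their median
and 95% range. A grid point whose 95% range excludes zero marks a rank
difference at which interactions are targeted non-randomly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    InteractionDataset,
    InteractionEvent,
    directed_dyad_counts,
    events_replace_recipients,
    split_dataset,
)
from .errors import InsufficientDataError, ParameterError, UnrankedIndividualError
from .hierarchy import (
    EloConfig,
    EloExclusionWarning,
    Hierarchy,
    randomized_elo_ranks,
    rank_difference,
    score_difference,
)
from .smoothing import fit_smoothing_spline

__all__ = [
    "PermutationConfig",
    "SplineConfig",
    "TendencyMatrix",
    "StrategyBand",
    "permute_recipients",
    "expected_counts_exact",
    "tendency_matrix",
    "dyad_series",
    "fit_strategy_spline",
    "run_strategy_analysis",
    "classify_band",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    """Recipient-permutation chain length and seed."""

    n_permutations: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")


@dataclass(frozen=True)
class SplineConfig:
    """Spline smoothing settings for the tendency-vs-difference relationship.

    target_df is the effective degrees of freedom per side (the portable
    smoothing contract). smoothing optionally fixes the roughness weight
    directly when criterion == "lambda"; note that roughness-weight scales are
    implementation-specific. grid, when given, must exclude zero for
    rank-based analyses; by default an integer grid (rank) or a 49-points-per-
    side grid on [-1, 1] (score) is built by the analysis driver.
    """

    target_df: float = 3.0
    smoothing: float = 0.04
    criterion: str = "df"
    grid: tuple | None = None

    def __post_init__(self):
        if self.target_df < 2:
            raise ParameterError("target_df must be >= 2")
        if self.criterion not in ("df", "lambda"):
            raise ParameterError("criterion must be 'df' or 'lambda'")
        if self.grid is not None:
            grid = tuple(float(g) for g in self.grid)
            if any(g == 0 for g in grid):
                raise ParameterError("evaluation grid must exclude 0")
            object.__setattr__(self, "grid", grid)

    @property
    def lam(self) -> float | None:
        return self.smoothing if self.criterion == "lambda" else None


@dataclass(frozen=True)
class TendencyMatrix:
    """Observed minus expected directed counts (values = observed − expected)."""

    values: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame

    @property
    def individuals(self) -> tuple:
        return tuple(self.values.index)


@dataclass(frozen=True)
class StrategyBand:
    """Pointwise summary of spline predictions across analysis iterations.

    significance is "above" where the whole 95% range sits above zero,
    "below" where it sits below, and "ns" otherwise. extrapolation_share is
    the fraction of contributing iterations whose prediction at that grid
    point lay outside the iteration's own data range (tail instability flag).
    """

    grid: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_iterations: int
    significance: tuple
    extrapolation_share: np.ndarray
    n_failed: int = 0
    max_abs_row_sum: float = 0.0
    predictions: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "difference": self.grid,
                "median": self.median,
                "lo": self.lo,
                "hi": self.hi,
                "significance": list(self.significance),
                "extrapolation_share": self.extrapolation_share,
            }
        )


def _candidate_recipients(events: Sequence[InteractionEvent]) -> list:
    return [sorted(e.present - {e.actor}) for e in events]


def _permuted_recipient_indices(n_events: int, candidates: Sequence[Sequence],
                                n_permutations: int,
                                rng: np.random.Generator) -> list:
    """Final recipient choice per event after a sequential permutation chain.

    The chain picks one event uniformly per step and re-draws its recipient
    uniformly from the individuals present minus the actor. Only the last
    re-draw of each event survives, and every re-draw is independent of the
    chain state, so the final dataset is reproduced exactly by: count how
    often each event was selected (multinomial), then give each selected
    event one uniform re-draw. Events never selected keep their original
    recipient (None below).
    """
    picks = np.bincount(
        rng.integers(0, n_events, size=n_permutations), minlength=n_events
    )
    out: list = [None] * n_events
    for i in np.nonzero(picks)[0]:
        cand = candidates[i]
        out[i] = cand[int(rng.integers(len(cand)))]
    return out


def permute_recipients(events: Iterable[InteractionEvent],
                       config: PermutationConfig | None = None,
                       rng: np.random.Generator | None = None) -> tuple:
    """One permuted dataset: recipients re-drawn among the present individuals.

    Actors, categories, present sets, ordering and the event count are all
    unchanged; only recipients move. Returns a tuple of events.
    """
    if config is None:
        config = PermutationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if isinstance(events, InteractionDataset):
        events = events.events
    else:
        events = tuple(events)
    cands = _candidate_recipients(events)
    new = _permuted_recipient_indices(len(events), cands,
                                      config.n_permutations, rng)
    recips = [e.recipient if r is None else r for e, r in zip(events, new)]
    return events_replace_recipients(events, recips)


def expected_counts_exact(events: Iterable[InteractionEvent],
                          individuals: Iterable | None = None) -> pd.DataFrame:
    """Analytic stationary expectation of the permuted directed counts.

    expected[a, b] = sum over events with actor a and b present of
    1/(|present|−1). Row sums equal the observed per-actor totals exactly.
    """
    if isinstance(events, InteractionDataset):
        base = set(events.individuals)
        events = events.events
    else:
        events = tuple(events)
        base = set()
        for e in events:
            base |= e.present
            base.add(e.actor)
    ids = sorted(base | (set(individuals) if individuals else set()))
    idx = {v: i for i, v in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for e in events:
        p = 1.0 / (len(e.present) - 1)
        a = idx[e.actor]
        for b in e.present:
            if b != e.actor:
                mat[a, idx[b]] += p
    return pd.DataFrame(mat, index=ids, columns=ids)


def tendency_matrix(observed: pd.DataFrame,
                    expected: pd.DataFrame) -> TendencyMatrix:
    """Elementwise observed − expected over a shared individual set."""
    if list(observed.index) != list(expected.index) or \
            list(observed.columns) != list(expected.columns):
        raise ParameterError(
            "observed and expected matrices must share index and columns"
        )
    values = observed.astype(float) - expected.astype(float)
    return TendencyMatrix(values=values, observed=observed, expected=expected)


def dyad_series(t: TendencyMatrix, h: Hierarchy,
                difference_kind: str = "rank",
                on_unranked: str = "error") -> np.ndarray:
    """One (signed difference, tendency) point per directed dyad.

    Returns an (n_points, 2) array over all ordered pairs (a, b), a != b. With
    on_unranked="skip", dyads involving individuals absent from the hierarchy
    are dropped (used inside the repeated-split analysis, where a random 30%
    subset may not sample every group member).
    """
    if difference_kind not in ("rank", "score"):
        raise ParameterError("difference_kind must be 'rank' or 'score'")
    if on_unranked not in ("error", "skip"):
        raise ParameterError("on_unranked must be 'error' or 'skip'")
    diff_fn = rank_difference if difference_kind == "rank" else score_difference
    ids = t.individuals
    if on_unranked == "skip":
        ids = tuple(i for i in ids if i in h.rank)
    vals = t.values
    pts = []
    for a in ids:
        for b in ids:
            if a == b:
                continue
            pts.append((diff_fn(h, a, b), vals.at[a, b]))
    return np.array(pts, dtype=float).reshape(-1, 2)


def fit_strategy_spline(points: np.ndarray, config: SplineConfig,
                        grid: np.ndarray) -> tuple:
    """Fit independent smoothing splines to the negative and positive sides.

    points is an (n, 2) array of (signed difference, tendency). Separate fits
    below and above zero avoid forcing continuity through zero, which would
    shrink a genuine close-competitor signal at difference −1 towards the +1
    side. Sides with fewer than 4 distinct abscissae yield NaN predictions.

    Returns (predictions, extrapolated) aligned with grid.
    """
    grid = np.asarray(grid, dtype=float)
    preds = np.full(grid.shape, np.nan)
    extrap = np.zeros(grid.shape, dtype=bool)
    for side in (-1, 1):
        mask = points[:, 0] * side > 0
        gmask = grid * side > 0
        if not gmask.any():
            continue
        x, y = points[mask, 0], points[mask, 1]
        if len(np.unique(x)) < 4:
            continue
        fit = fit_smoothing_spline(x, y, target_df=config.target_df,
                                   lam=config.lam)
        preds[gmask] = fit(grid[gmask])
        extrap[gmask] = fit.extrapolated(grid[gmask])
    return preds, extrap


def default_grid(n_individuals: int, difference_kind: str) -> np.ndarray:
    """Evaluation grid: integer differences ±1..±(N−1) (rank) or 49 points per
    side on [−1, 1] (score); zero is excluded on both."""
    if difference_kind == "rank":
        neg = np.arange(-(n_individuals - 1), 0)
        return np.concatenate([neg, -neg[::-1]]).astype(float)
    side = np.linspace(0, 1, 50)[1:]
    return np.concatenate([-side[::-1], side])


def run_strategy_analysis(ds: InteractionDataset,
                          n_iterations: int = 500,
                          hier_fraction: float = 0.3,
                          perm_config: PermutationConfig | None = None,
                          spline_config: SplineConfig | None = None,
                          elo_config: EloConfig | None = None,
                          rng: np.random.Generator | int | None = None,
                          difference_kind: str = "rank",
                          keep_predictions: bool = True) -> StrategyBand:
    """Full repeated-split tendency-to-interact analysis on one dataset.

    ds should hold a single group and interaction category. Each iteration:
    fresh random split -> randomized-Elo hierarchy on the hierarchy subset ->
    observed counts on the strategy subset -> one permuted dataset and its
    counts -> tendency matrix -> per-dyad points -> side-split spline
    predictions on the grid. The band is the pointwise median and 2.5/97.5
    percentiles of predictions across iterations. Iterations that fail (e.g.
    a degenerate split that ranks too few individuals) are dropped and
    counted in n_failed.
    """
    if perm_config is None:
        perm_config = PermutationConfig()
    if spline_config is None:
        spline_config = SplineConfig()
    if elo_config is None:
        elo_config = EloConfig()
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    gen = np.random.default_rng(rng)
    ids = sorted(ds.individuals)
    if spline_config.grid is not None:
        grid = np.asarray(spline_config.grid, dtype=float)
    else:
        grid = default_grid(len(ids), difference_kind)

    all_preds = np.full((n_iterations, len(grid)), np.nan)
    all_extrap = np.zeros((n_iterations, len(grid)), dtype=bool)
    n_failed = 0
    max_abs_row_sum = 0.0
    for it in range(n_iterations):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EloExclusionWarning)
                split = split_dataset(ds, hier_fraction, gen)
                h = randomized_elo_ranks(split.hierarchy_subset, elo_config,
                                         rng=gen)
                strat_events = split.strategy_subset.events
                observed = directed_dyad_counts(strat_events, individuals=ids)
                permuted = permute_recipients(strat_events, perm_config,
                                              rng=gen)
                perm_counts = directed_dyad_counts(permuted, individuals=ids)
                tend = tendency_matrix(observed, perm_counts)
                row_sums = tend.values.sum(axis=1).to_numpy()
                max_abs_row_sum = max(max_abs_row_sum,
                                      float(np.abs(row_sums).max()))
                points = dyad_series(tend, h, difference_kind,
                                     on_unranked="skip")
                preds, extrap = fit_strategy_spline(points, spline_config, grid)
        except (InsufficientDataError, UnrankedIndividualError) as exc:
            n_failed += 1
            logger.debug("iteration %d failed: %s", it, exc)
            continue
        all_preds[it] = preds
        all_extrap[it] = extrap
    if n_failed:
        logger.info("%d of %d iterations failed and were excluded",
                    n_failed, n_iterations)
    if n_failed == n_iterations:
        raise InsufficientDataError("every analysis iteration failed")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        median = np.nanmedian(all_preds, axis=0)
        lo = np.nanpercentile(all_preds, 2.5, axis=0)
        hi = np.nanpercentile(all_preds, 97.5, axis=0)
    contributed = ~np.isnan(all_preds)
    with np.errstate(invalid="ignore", divide="ignore"):
        extrap_share = np.where(
            contributed.sum(axis=0) > 0,
            (all_extrap & contributed).sum(axis=0) /
            np.maximum(contributed.sum(axis=0), 1),
            np.nan,
        )
    band = StrategyBand(
        grid=grid,
        median=median,
        lo=lo,
        hi=hi,
        n_iterations=n_iterations - n_failed,
        significance=_labels(lo, hi),
        extrapolation_share=extrap_share,
        n_failed=n_failed,
        max_abs_row_sum=max_abs_row_sum,
        predictions=all_preds if keep_predictions else None,
    )
    return band


def _labels(lo: np.ndarray, hi: np.ndarray) -> tuple:
    labels = []
    for l, h in zip(lo, hi):
        if np.isnan(l) or np.isnan(h):
            labels.append("ns")
        elif l > 0:
            labels.append("above")
        elif h < 0:
            labels.append("below")
        else:
            labels.append("ns")
    return tuple(labels)


def classify_band(band: StrategyBand) -> tuple:
    """Per-grid-point label: above / below when the 95% range excludes zero."""
    return _labels(band.lo, band.hi)
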