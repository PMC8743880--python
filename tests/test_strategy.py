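"""Permutation null, tendency matrix, dyad series, band classification."""

import numpy as np
import pandas as pd
import pytest

from domstrat import (
    ABMConfig,
    InteractionDataset,
    ParameterError,
    PermutationConfig,
    SplineConfig,
    StrategyBand,
    classify_band,
    default_grid,
    directed_dyad_counts,
    dyad_series,
    expected_counts_exact,
    fit_strategy_spline,
    permute_recipients,
    run_strategy_analysis,
    simulate_dataset,
    tendency_matrix,
)
from domstrat.errors import UnrankedIndividualError
from conftest import identity_hierarchy, make_event


class TestPermuteRecipients:
    def test_single_legal_recipient_is_forced(self):
        ev = make_event("e1", "A", "B", {"A", "B"})
        for seed in range(5):
            out = permute_recipients([ev], PermutationConfig(50, seed=seed))
            assert out[0].recipient == "B"

    def test_actors_categories_presence_untouched(self):
        rng = np.random.default_rng(0)
        events = [make_event(f"e{k}", "A", "B", {"A", "B", "C", "D"}, order=k)
                  for k in range(30)]
        out = permute_recipients(events, PermutationConfig(500), rng=rng)
        assert len(out) == 30
        for orig, perm in zip(events, out):
            assert perm.actor == orig.actor
            assert perm.category == orig.category
            assert perm.present == orig.present
            assert perm.recipient in orig.present - {orig.actor}

    def test_uniform_stationary_distribution(self):
        # one event, two legal recipients: each chosen ~50% of the time
        ev = make_event("e1", "A", "B", {"A", "B", "C"})
        n = 2000
        hits = sum(
            permute_recipients([ev], PermutationConfig(10, seed=s))[0].recipient
            == "B"
            for s in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 4 * se


class TestExpectedCounts:
    def test_uniform_over_two_candidates(self):
        ev = make_event("e1", "A", "B", {"A", "B", "C"})
        exp = expected_counts_exact([ev])
        assert exp.at["A", "B"] == pytest.approx(0.5)
        assert exp.at["A", "C"] == pytest.approx(0.5)

    def test_row_sums_equal_actor_totals(self, abm_assorted_100):
        exp = expected_counts_exact(abm_assorted_100)
        obs = directed_dyad_counts(abm_assorted_100)
        assert np.allclose(exp.sum(axis=1).to_numpy(),
                           obs.sum(axis=1).to_numpy(), atol=1e-9)

    def test_mean_permuted_counts_converge_to_exact(self):
        # Monte-Carlo oracle equivalence on a heterogeneous fixture
        ds = simulate_dataset(ABMConfig(n_individuals=8, n_subgroups=40,
                                        mean_size=4, seed=2))
        exact = expected_counts_exact(ds)
        ids = list(exact.index)
        reps = 300
        rng = np.random.default_rng(0)
        acc = np.zeros(exact.shape)
        for _ in range(reps):
            perm = permute_recipients(ds, PermutationConfig(1500), rng=rng)
            acc += directed_dyad_counts(perm, individuals=ids).to_numpy()
        mean = acc / reps
        var = np.zeros(exact.shape)
        idx = {v: i for i, v in enumerate(ids)}
        for e in ds:
            p = 1.0 / (len(e.present) - 1)
            for b in e.present - {e.actor}:
                var[idx[e.actor], idx[b]] += p * (1 - p)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(mean - exact.to_numpy()) <= 3.5 * se + 1e-12)


class TestTendency:
    def test_identical_matrices_give_zero(self, tiny_dataset):
        obs = directed_dyad_counts(tiny_dataset)
        t = tendency_matrix(obs, obs)
        assert (t.values.to_numpy() == 0).all()

    def test_hand_example(self):
        ids = ["A", "B", "C"]
        obs = pd.DataFrame(0, index=ids, columns=ids)
        obs.loc["A", "B"], obs.loc["A", "C"] = 3, 1
        perm = pd.DataFrame(0, index=ids, columns=ids)
        perm.loc["A", "B"], perm.loc["A", "C"] = 2, 2
        t = tendency_matrix(obs, perm)
        assert t.values.at["A", "B"] == 1
        assert t.values.at["A", "C"] == -1
        assert t.values.to_numpy().sum() == 0

    def test_scale_equivariance_preserves_labels(self):
        # doubling every observed and expected count doubles the tendency but
        # cannot change which side of zero an interval sits on
        lo = np.array([0.2, -0.5, -0.1])
        hi = np.array([0.9, -0.1, 0.4])
        band = StrategyBand(
            grid=np.array([-2.0, -1.0, 1.0]), median=(lo + hi) / 2,
            lo=lo, hi=hi, n_iterations=10,
            significance=("ns",) * 3,
            extrapolation_share=np.zeros(3),
        )
        doubled = StrategyBand(
            grid=band.grid, median=band.median * 2, lo=lo * 2, hi=hi * 2,
            n_iterations=10, significance=("ns",) * 3,
            extrapolation_share=np.zeros(3),
        )
        assert classify_band(band) == classify_band(doubled) == \
            ("above", "below", "ns")

    def test_mismatched_matrices_rejected(self):
        a = pd.DataFrame(0, index=["A", "B"], columns=["A", "B"])
        b = pd.DataFrame(0, index=["A", "C"], columns=["A", "C"])
        with pytest.raises(ParameterError):
            tendency_matrix(a, b)


class TestDyadSeries:
    def _tendency(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        from domstrat.abm import individual_id

        ids = [individual_id(r) for r in range(1, n + 1)]
        obs = pd.DataFrame(rng.integers(0, 5, (n, n)), index=ids, columns=ids)
        np.fill_diagonal(obs.values, 0)
        return tendency_matrix(obs, obs)  # values irrelevant to these checks

    def test_point_count_and_rank_difference_multiplicity(self):
        n = 7
        t = self._tendency(n)
        pts = dyad_series(t, identity_hierarchy(n))
        assert pts.shape == (n * (n - 1), 2)
        diffs = pts[:, 0]
        for k in range(1, n):
            assert (diffs == -k).sum() == n - k
            assert (diffs == k).sum() == n - k

    def test_total_tendency_zero(self):
        ds = simulate_dataset(ABMConfig(n_individuals=10, n_subgroups=60,
                                        mean_size=4, seed=3))
        obs = directed_dyad_counts(ds)
        perm = directed_dyad_counts(
            permute_recipients(ds, PermutationConfig(2000, seed=0)),
            individuals=list(obs.index),
        )
        t = tendency_matrix(obs, perm)
        pts = dyad_series(t, identity_hierarchy(10))
        assert pts[:, 1].sum() == pytest.approx(0.0, abs=1e-9)

    def test_unranked_individual_raises_or_skips(self):
        t = self._tendency(6)
        h5 = identity_hierarchy(5)  # i006 missing
        with pytest.raises(UnrankedIndividualError):
            dyad_series(t, h5)
        pts = dyad_series(t, h5, on_unranked="skip")
        assert pts.shape == (5 * 4, 2)


class TestStrategySpline:
    def test_sides_fit_independently(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.arange(-8, 0), np.arange(1, 9)]).astype(float)
        x = np.repeat(x, 4)
        # step function: negative side at +1, positive side at -1
        y = np.where(x < 0, 1.0, -1.0) + rng.normal(0, 0.05, x.size)
        grid = default_grid(9, "rank")
        preds, extrap = fit_strategy_spline(
            np.column_stack([x, y]), SplineConfig(), grid)
        assert np.all(preds[grid < 0] > 0.8)
        assert np.all(preds[grid > 0] < -0.8)

    def test_side_with_too_few_abscissae_absent(self):
        x = np.array([-3.0, -2, -1, 1, 2, 3, 4, 5, -4.0])
        y = np.zeros_like(x)
        pts = np.column_stack([x[:3].repeat(2), y[:3].repeat(2)])
        pos = np.column_stack([x[3:8], y[3:8]])
        preds, _ = fit_strategy_spline(
            np.vstack([pts, pos]), SplineConfig(), default_grid(6, "rank"))
        assert np.isnan(preds[default_grid(6, "rank") < 0]).all()
        assert not np.isnan(preds[default_grid(6, "rank") > 0]).any()

    def test_grid_excludes_zero(self):
        with pytest.raises(ParameterError):
            SplineConfig(grid=(-1.0, 0.0, 1.0))
        for kind in ("rank", "score"):
            assert 0.0 not in default_grid(20, kind)


class TestRunStrategyAnalysis:
    def test_null_band_overlaps_zero(self, abm_assorted_100):
        band = run_strategy_analysis(
            abm_assorted_100, n_iterations=60,
            perm_config=PermutationConfig(1000),
            elo_config=_fast_elo(), rng=0,
        )
        assert sum(s != "ns" for s in band.significance) == 0
        assert np.all(band.lo <= band.median + 1e-12)
        assert np.all(band.median <= band.hi + 1e-12)
        assert band.max_abs_row_sum == 0.0

    def test_injected_close_competitor_detected(self):
        ds = simulate_dataset(ABMConfig(n_subgroups=700, strategy={-1: 1.0},
                                        seed=0))
        band = run_strategy_analysis(
            ds, n_iterations=60, perm_config=PermutationConfig(1000),
            elo_config=_fast_elo(), rng=0,
        )
        i = list(band.grid).index(-1.0)
        assert band.significance[i] == "above"

    def test_reproducible_under_seed(self, abm_assorted_100):
        kwargs = dict(n_iterations=10, perm_config=PermutationConfig(500),
                      elo_config=_fast_elo())
        b1 = run_strategy_analysis(abm_assorted_100, rng=5, **kwargs)
        b2 = run_strategy_analysis(abm_assorted_100, rng=5, **kwargs)
        assert np.array_equal(b1.predictions, b2.predictions,
                              equal_nan=True)


def _fast_elo():
    from domstrat import EloConfig

    return EloConfig(n_orderings=150)
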