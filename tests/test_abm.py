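"""Agent-based simulator: kernels, membership, contest outcomes, datasets."""

import math

import numpy as np
import pytest
from scipy import stats

from domstrat import (
    ABMConfig,
    ParameterError,
    assortment_weight,
    draw_subgroup,
    membership_probs,
    simulate_dataset,
    simulate_interaction,
    win_probability,
)
from domstrat.abm import individual_id, true_ranks


class TestAssortmentWeight:
    def test_peak_value_at_target(self):
        assert assortment_weight(7, 7) == pytest.approx(
            1.0 / (2.0 * math.sqrt(2.0 * math.pi)), abs=1e-12
        )

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_symmetry_about_target(self, k):
        assert assortment_weight(10 + k, 10) == pytest.approx(
            assortment_weight(10 - k, 10), abs=1e-15
        )

    def test_matches_sd2_gaussian_density(self):
        # independent oracle: scipy's normal pdf with mean z, sd 2
        for r, z in [(12, 10), (1, 5), (20, 20), (3, 3.5)]:
            assert assortment_weight(r, z) == pytest.approx(
                stats.norm.pdf(r, loc=z, scale=2), abs=1e-12
            )
        assert assortment_weight(12, 10) == pytest.approx(0.12099, abs=5e-6)


class TestMembershipProbs:
    def test_random_mode_uniform_quarter(self):
        probs = membership_probs(ABMConfig())  # N=20, G=5 -> 0.25
        assert np.allclose(probs, 0.25)

    def test_assorted_sums_to_mean_size(self):
        cfg = ABMConfig(assorted=True)
        for z in (1, 5, 10, 20):
            probs = membership_probs(cfg, z)
            if probs.max() < 1.0:  # no cap binding
                assert probs.sum() == pytest.approx(5.0, abs=1e-9)

    def test_edge_target_needs_larger_scale(self):
        # half the Gaussian mass falls outside the rank range at z=1, so the
        # common rescaling factor must be larger than at a central target
        cfg = ABMConfig(assorted=True)
        w_edge = sum(assortment_weight(r, 1) for r in range(1, 21))
        w_mid = sum(assortment_weight(r, 10) for r in range(1, 21))
        assert w_edge < w_mid
        assert membership_probs(cfg, 1).max() > membership_probs(cfg, 10).max()

    def test_z_required_iff_assorted(self):
        with pytest.raises(ParameterError):
            membership_probs(ABMConfig(), z=3)
        with pytest.raises(ParameterError):
            membership_probs(ABMConfig(assorted=True))


class TestDrawSubgroup:
    def test_certain_inclusion(self):
        rng = np.random.default_rng(0)
        sg = draw_subgroup(np.ones(6), rng)
        assert sg.members == (1, 2, 3, 4, 5, 6)

    def test_two_certain_members_only(self):
        rng = np.random.default_rng(0)
        probs = np.zeros(10)
        probs[:2] = 1.0
        for _ in range(20):
            assert draw_subgroup(probs, rng).members == (1, 2)

    def test_impossible_minimum_size_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            draw_subgroup(np.zeros(5), rng)
        probs = np.zeros(5)
        probs[0] = 1.0
        with pytest.raises(ParameterError):
            draw_subgroup(probs, rng)

    def test_mean_size_matches_truncated_binomial(self):
        # conditional on >= 2 members the mean exceeds N*p slightly; compare
        # against the exact truncated-binomial expectation
        n, p, draws = 20, 0.25, 4000
        rng = np.random.default_rng(1)
        sizes = np.array([len(draw_subgroup(np.full(n, p), rng).members)
                          for _ in range(draws)])
        k = np.arange(n + 1)
        pmf = stats.binom.pmf(k, n, p)
        keep = k >= 2
        expect = (k[keep] * pmf[keep]).sum() / pmf[keep].sum()
        var = ((k[keep] - expect) ** 2 * pmf[keep]).sum() / pmf[keep].sum()
        se = math.sqrt(var / draws)
        assert abs(sizes.mean() - expect) < 3 * se


class TestWinProbability:
    def test_reference_values(self):
        assert win_probability(0.9, 1) == pytest.approx(0.90, abs=1e-12)
        assert win_probability(0.9, 2) == pytest.approx(0.99, abs=1e-12)
        assert win_probability(1.0, 7) == 1.0

    def test_monotone_in_rank_distance_and_pw(self):
        probs = [win_probability(0.9, r) for r in range(1, 20)]
        assert np.all(np.diff(probs) >= 0)  # saturates at 1 in float precision
        assert np.all(np.diff(probs[:10]) > 0)
        assert win_probability(0.95, 3) > win_probability(0.9, 3)

    def test_invalid_distance_rejected(self):
        for bad in (0, -1, 1.5):
            with pytest.raises(ParameterError):
                win_probability(0.9, bad)


class TestSimulateInteraction:
    def test_deterministic_when_pw_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e = simulate_interaction((3, 9, 14), 1.0, rng)
            assert true_ranks(20)[e.actor] < true_ranks(20)[e.recipient]

    def test_extreme_rank_gap_dominant_nearly_always_wins(self):
        # P_win(0.9, 19) = 1 - 0.1**19; over 2000 draws an upset is ~never seen
        rng = np.random.default_rng(2)
        actors = [simulate_interaction((1, 20), 0.9, rng).actor
                  for _ in range(2000)]
        assert all(a == individual_id(1) for a in actors)

    def test_adjacent_pair_win_rate_near_pw(self):
        rng = np.random.default_rng(3)
        n = 10_000
        wins = sum(simulate_interaction((5, 6), 0.9, rng).actor ==
                   individual_id(5) for _ in range(n))
        se = math.sqrt(0.9 * 0.1 / n)
        assert abs(wins / n - 0.9) < 4 * se

    def test_present_records_whole_subgroup(self):
        rng = np.random.default_rng(4)
        e = simulate_interaction((2, 5, 11, 17), 0.9, rng)
        assert e.present == frozenset(individual_id(m) for m in (2, 5, 11, 17))


class TestSimulateDataset:
    def test_one_event_per_subgroup(self):
        ds = simulate_dataset(ABMConfig(seed=0))
        assert len(ds) == 100
        assert [e.order for e in ds] == list(range(100))

    def test_two_individuals_always_same_pair(self):
        ds = simulate_dataset(ABMConfig(n_individuals=2, n_subgroups=10,
                                        mean_size=2, seed=1))
        assert all(e.present == frozenset({"i001", "i002"}) for e in ds)

    def test_seed_reproducibility(self):
        a = simulate_dataset(ABMConfig(assorted=True, seed=9))
        b = simulate_dataset(ABMConfig(assorted=True, seed=9))
        assert a == b

    def test_assortment_shrinks_within_subgroup_rank_distance(self):
        # the mechanism that inflates close-in-rank dyad counts
        def mean_pair_distance(assorted, seed):
            cfg = ABMConfig(n_subgroups=1000, assorted=assorted, seed=seed)
            ds = simulate_dataset(cfg)
            tr = true_ranks(20)
            dists = []
            for e in ds:
                ranks = sorted(tr[i] for i in e.present)
                dists.extend(abs(a - b) for i, a in enumerate(ranks)
                             for b in ranks[i + 1:])
            return np.mean(dists)

        assert mean_pair_distance(True, 5) < mean_pair_distance(False, 5)

    def test_no_strategy_recipient_independent_of_rank(self):
        # conditional on the drawn pair, which member ends up as recipient
        # depends only on the contest, not on any targeting preference:
        # P_w = 1 makes the lower-ranked member the recipient always
        ds = simulate_dataset(ABMConfig(p_win=1.0, n_subgroups=200, seed=6))
        tr = true_ranks(20)
        assert all(tr[e.actor] < tr[e.recipient] for e in ds)

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            ABMConfig(p_win=0.4)
        with pytest.raises(ParameterError):
            ABMConfig(mean_size=1.0)
        with pytest.raises(ParameterError):
            ABMConfig(n_individuals=1)
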