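"""Permutation engine: ranks, tie-breaking, determinism, wrappers, Fisher."""

import numpy as np
import pytest

from usptest import (
    ContingencyTable,
    JointDistribution,
    SampleSizeError,
    batch_pvalues,
    fisher_exact_test,
    g_perm_test,
    pearson_perm_test,
    permutation_pvalue,
    sample_table,
    usp_statistic,
    usp_test,
)
from usptest.permutation import _permuted_counts, _rank_among
from usptest.tables import pairs_from_table
from conftest import random_tables


class TestRankAndTies:
    def test_strictly_largest_original_gives_minimum_p(self):
        # maximal-dependence table: any non-identity y-permutation strictly
        # lowers the USP statistic, so rank 1 of B+1
        t = ContingencyTable(np.diag([5, 5, 5]))
        r = usp_test(t, B=3, seed=0)
        assert r.rank == 1 and r.p_value == pytest.approx(1 / 4)

    def test_pure_tie_break_p_uniform_over_seeds(self):
        # constant statistic: p is uniform on {1/(B+1), ..., 1}
        t = ContingencyTable(np.array([[2, 2], [2, 2]]))
        B = 9
        ranks = [
            permutation_pvalue(t, lambda _t: 1.0, B=B, seed=s).rank for s in range(2000)
        ]
        counts = np.bincount(ranks, minlength=B + 2)[1:]
        expected = 2000 / (B + 1)
        assert counts.min() > 0
        # each rank frequency within 5 binomial SEs of uniform
        se = np.sqrt(expected * (1 - 1 / (B + 1)))
        assert np.all(np.abs(counts - expected) <= 5 * se)

    def test_conservative_tie_break_is_deterministic_and_larger(self):
        t = ContingencyTable(np.array([[2, 2], [2, 2]]))
        r = permutation_pvalue(t, lambda _t: 1.0, B=19, seed=3, tie_break="conservative")
        assert r.p_value == 1.0  # all B+1 values tie
        rng = np.random.default_rng(0)
        vals = np.array([1.0, 2.0, 2.0, 0.5])
        assert _rank_among(2.0, vals, rng, "conservative") == 3

    def test_p_equals_rank_over_B_plus_one(self):
        rng = np.random.default_rng(2)
        for table in random_tables(rng, 10, n_range=(8, 25)):
            res = pearson_perm_test(table, B=49, seed=int(rng.integers(2**31)))
            assert res.p_value == pytest.approx(res.rank / 50)
            assert res.p_value >= 1 / 50


class TestEngine:
    def test_permuted_counts_preserve_margins(self, eye_table):
        sample = pairs_from_table(eye_table)
        counts = _permuted_counts(sample, 50, np.random.default_rng(1))
        assert np.array_equal(counts.sum(axis=2), np.tile(eye_table.row_totals, (50, 1)))
        assert np.array_equal(counts.sum(axis=1), np.tile(eye_table.col_totals, (50, 1)))

    def test_identical_seed_identical_result(self, eye_table):
        a = usp_test(eye_table, B=199, seed=11)
        b = usp_test(eye_table, B=199, seed=11)
        assert a == b

    def test_fast_path_matches_generic_engine(self):
        # the vectorized wrapper must reproduce the literal re-tabulating
        # engine draw for draw at the same seed
        rng = np.random.default_rng(4)
        for table in random_tables(rng, 8, n_range=(10, 30)):
            seed = int(rng.integers(2**31))
            fast = usp_test(table, B=99, seed=seed)
            slow = permutation_pvalue(table, usp_statistic, B=99, seed=seed, method="usp")
            assert fast.rank == slow.rank
            assert fast.statistic == pytest.approx(slow.statistic)

    def test_statistic_errors_propagate_with_context(self):
        t = ContingencyTable(np.array([[2, 2], [2, 2]]))

        def bad_stat(_table):
            raise ValueError("boom")

        with pytest.raises(ValueError, match="boom"):
            permutation_pvalue(t, bad_stat, B=9, seed=0)

    def test_usp_needs_four_observations(self):
        with pytest.raises(SampleSizeError):
            usp_test(ContingencyTable(np.array([[1, 1], [1, 0]])), B=9, seed=0)

    def test_batch_matches_single_wrappers_given_shared_seed(self, eye_table):
        batch = batch_pvalues(eye_table, ("pearson_perm",), B=99, seed=21)
        single = pearson_perm_test(eye_table, B=99, seed=21)
        assert batch["pearson_perm"] == pytest.approx(single.p_value)


class TestFisher:
    def test_exact_2x2_diagonal(self):
        p = fisher_exact_test(ContingencyTable(np.array([[3, 0], [0, 3]]))).p_value
        assert p == pytest.approx(0.1)

    def test_exact_2x2_modal_table(self):
        p = fisher_exact_test(ContingencyTable(np.array([[1, 1], [1, 1]]))).p_value
        assert p == pytest.approx(1.0)

    def test_monte_carlo_converges_to_exact_2x2(self):
        # conservative tie-break makes the MC estimate target exactly the
        # "at most as probable" tail that the exact enumeration sums
        t = ContingencyTable(np.array([[9, 3], [2, 10]]))
        exact = fisher_exact_test(t, mode="exact2x2").p_value
        mc = fisher_exact_test(t, B=40_000, seed=1, mode="montecarlo",
                               tie_break="conservative").p_value
        se = np.sqrt(exact * (1 - exact) / 40_000)
        assert abs(mc - exact) <= 4 * se + 1e-4

    def test_mode_validation(self):
        t3 = ContingencyTable(np.array([[1, 2, 3], [3, 2, 1]]))
        with pytest.raises(ValueError):
            fisher_exact_test(t3, mode="exact2x2")
        with pytest.raises(ValueError):
            fisher_exact_test(t3, mode="bogus")

    def test_auto_mode_dispatch(self, eye_table):
        r = fisher_exact_test(eye_table, B=99, seed=0)  # 2x5 -> Monte-Carlo
        assert r.B == 99 and r.rank is not None
        r2 = fisher_exact_test(ContingencyTable(np.array([[2, 1], [1, 2]])))
        assert r2.B == 0 and r2.rank is None


class TestSizeControl:
    def test_all_permutation_tests_control_size_with_near_zero_cells(self):
        # a product null with tiny cell probabilities: the regime where the
        # chi-squared-quantile tests misbehave but permutation tests must not
        joint = JointDistribution.product([0.96, 0.03, 0.01], [0.5, 0.49, 0.01])
        tests = ("usp", "pearson_perm", "g_perm", "fisher")
        rng = np.random.default_rng(123)
        reps, B, alpha = 2000, 99, 0.05
        reject = dict.fromkeys(tests, 0)
        for _ in range(reps):
            t = sample_table(joint, 40, rng)
            pv = batch_pvalues(t, tests, B=B, seed=rng)
            for k in tests:
                reject[k] += pv[k] <= alpha
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
        for k, c in reject.items():
            assert c / reps <= bound, (k, c / reps)

    def test_rank_equivalence_of_usp_and_dhat(self):
        # shared permutations and shared tie-break jitter give identical
        # ranks; statistics evaluated exactly so ties are compared exactly
        from conftest import exact_usp_and_dhat

        rng = np.random.default_rng(17)
        for table in random_tables(rng, 25, n_range=(8, 40)):
            sample = pairs_from_table(table)
            counts = _permuted_counts(sample, 30, rng)
            obs_u, obs_d = exact_usp_and_dhat(table.counts)
            perm = [exact_usp_and_dhat(c) for c in counts]
            u = np.random.default_rng(99).uniform(size=31)
            ranks = []
            for obs, idx in ((obs_u, 0), (obs_d, 1)):
                vals = [p[idx] for p in perm]
                ranks.append(
                    1
                    + sum(v > obs for v in vals)
                    + sum(v == obs and u[k + 1] > u[0] for k, v in enumerate(vals))
                )
            assert ranks[0] == ranks[1]
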