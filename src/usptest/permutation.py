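"""Permutation-test engine and the four independence tests built on it.

The engine implements the generic recipe: evaluate a statistic on the
observed table, then on B datasets obtained by uniformly permuting the
y-labels of the paired sample (which preserves both margins exactly), and
report the rank of the observed value among all B + 1, breaking ties at
random; the p-value is rank/(B + 1).  Because each permuted dataset is an
exact draw from the conditional null, the resulting test has Type I error
at most α for every sample size at which the statistic is defined.

Ties are broken by ranking (statistic, jitter) pairs with independent
uniform jitter from the same seeded generator — statistically identical to
"break ties at random" and easy to test.  A deterministic conservative
alternative, p = (1 + #{b : T_b ≥ T_obs})/(B + 1), is available via
``tie_break="conservative"`` for users who need seed-free reproducible
p-values (it can only increase p, so size control is kept).

Wrappers provide the USP test, permutation versions of Pearson's χ² and the
G-test, and Fisher's exact test (exact hypergeometric enumeration for 2×2,
Monte-Carlo under the fixed-margins null otherwise, driven by the same
y-permutation sampler).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps
from scipy.special import gammaln

from .core import _dhat_closed_values, _usp_values, usp_statistic
from .stats import chi2_quantile_pvalue, g_statistic, pearson_chi2
from .tables import (
    ContingencyTable,
    DegenerateTableError,
    PairedSample,
    SampleSizeError,
    expected_counts,
    pairs_from_table,
    table_from_pairs,
)

__all__ = [
    "TestResult",
    "permutation_pvalue",
    "usp_test",
    "pearson_perm_test",
    "g_perm_test",
    "fisher_exact_test",
]

DEFAULT_B = 999

#: tests evaluated by the shared-permutation batch runner
PERM_TESTS = ("usp", "pearson_perm", "g_perm", "fisher")
QUANTILE_TESTS = ("pearson_quantile", "g_quantile")
ALL_TESTS = PERM_TESTS + QUANTILE_TESTS


@dataclass(frozen=True)
class TestResult:
    """Outcome of one independence test.

    ``rank`` is the position of the observed statistic among the B + 1
    values in decreasing order (1 = most extreme); for permutation tests
    ``p_value = rank / (B + 1)``.  ``rank`` and ``B`` are 0/None for the
    exact (non-resampled) Fisher mode.
    """

    method: str
    statistic: float
    p_value: float
    B: int
    seed: int | None
    rank: int | None


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _rank_among(obs: float, perm_values: np.ndarray, rng: np.random.Generator,
                tie_break: str = "random") -> int:
    """Rank of ``obs`` among {obs} ∪ perm_values in decreasing order."""
    if tie_break == "conservative":
        return 1 + int(np.count_nonzero(perm_values >= obs))
    if tie_break != "random":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    u = rng.uniform(size=perm_values.size + 1)
    greater = int(np.count_nonzero(perm_values > obs))
    tied_above = int(np.count_nonzero((perm_values == obs) & (u[1:] > u[0])))
    return 1 + greater + tied_above


def _permuted_counts(sample: PairedSample, B: int, rng: np.random.Generator) -> np.ndarray:
    """Count arrays (B, I, J) for B uniform y-permutations of the sample.

    Asserts the margin invariance that makes the permutation null exact.
    """
    n, I, J = sample.n, sample.I, sample.J
    yp = np.tile(sample.y, (B, 1))
    rng.permuted(yp, axis=1, out=yp)
    idx = sample.x[None, :] * J + yp + np.arange(B)[:, None] * (I * J)
    counts = np.bincount(idx.ravel(), minlength=B * I * J).reshape(B, I, J)
    base = table_from_pairs(sample)
    if not (
        np.array_equal(counts.sum(axis=2), np.broadcast_to(base.row_totals, (B, I)))
        and np.array_equal(counts.sum(axis=1), np.broadcast_to(base.col_totals, (B, J)))
    ):
        raise AssertionError("permutation failed to preserve table margins")
    return counts


# --- vectorized statistic evaluators over stacked count arrays ----------

def _pearson_values(counts: np.ndarray, e: np.ndarray) -> np.ndarray:
    o = counts.astype(float)
    safe = np.where(e > 0, e, 1.0)
    return np.where(e > 0, (o - e) ** 2 / safe, 0.0).sum(axis=(-2, -1))


def _g_values(counts: np.ndarray, e: np.ndarray) -> np.ndarray:
    o = counts.astype(float)
    safe_o = np.where(o > 0, o, 1.0)
    safe_e = np.where(e > 0, e, 1.0)
    return 2.0 * np.where(o > 0, o * np.log(safe_o / safe_e), 0.0).sum(axis=(-2, -1))


def _fisher_neg_log_prob(counts: np.ndarray, log_margin_const: float) -> np.ndarray:
    """−log multivariate-hypergeometric probability of each table given its
    margins; larger means less probable, i.e. more extreme."""
    return gammaln(counts + 1.0).sum(axis=(-2, -1)) + log_margin_const


def _fisher_log_const(table: ContingencyTable) -> float:
    """Margin-only part −log[(Π_i o_i+!)(Π_j o_+j!)/n!] of −log P(table | margins)."""
    return float(
        gammaln(table.n + 1.0)
        - gammaln(table.row_totals + 1.0).sum()
        - gammaln(table.col_totals + 1.0).sum()
    )


def permutation_pvalue(
    sample: PairedSample | ContingencyTable,
    statistic: Callable[[ContingencyTable], float],
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    tie_break: str = "random",
    method: str = "custom",
) -> TestResult:
    """Generic permutation test for an arbitrary table statistic.

    The statistic is evaluated on the observed table and on B re-tabulated
    y-permuted datasets; larger values are treated as more extreme.
    Reproducible given an integer seed.
    """
    if isinstance(sample, ContingencyTable):
        sample = pairs_from_table(sample)
    if B < 1:
        raise ValueError("B must be a positive integer")
    if sample.n < 1:
        raise SampleSizeError("permutation test needs at least one observation")
    rng = _as_rng(seed)
    obs_table = table_from_pairs(sample)
    try:
        obs = float(statistic(obs_table))
    except Exception as err:  # re-raise with context per engine contract
        raise type(err)(f"statistic failed on observed table: {err}") from err
    perm_counts = _permuted_counts(sample, B, rng)
    perm_values = np.array([float(statistic(ContingencyTable(c))) for c in perm_counts])
    rank = _rank_among(obs, perm_values, rng, tie_break)
    return TestResult(
        method=method,
        statistic=obs,
        p_value=rank / (B + 1),
        B=B,
        seed=seed if isinstance(seed, int) else None,
        rank=rank,
    )


def _fast_perm_test(
    table: ContingencyTable,
    method: str,
    B: int,
    seed: int | np.random.Generator | None,
    tie_break: str,
) -> TestResult:
    """Shared fast path: tabulate all permutations at once and evaluate the
    statistic vectorized (expected counts are margin-only, hence constant
    across permutations)."""
    pvals = batch_pvalues(table, (method,), B=B, seed=seed, tie_break=tie_break,
                          _return_details=True)
    obs, rank, p = pvals[method]
    return TestResult(
        method=method,
        statistic=obs,
        p_value=p,
        B=B,
        seed=seed if isinstance(seed, int) else None,
        rank=rank,
    )


def usp_test(
    table: ContingencyTable,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    tie_break: str = "random",
) -> TestResult:
    """USP permutation test of independence (requires n ≥ 4)."""
    if table.n < 4:
        raise SampleSizeError(f"USP test requires n >= 4 observations, got {table.n}")
    return _fast_perm_test(table, "usp", B, seed, tie_break)


def pearson_perm_test(
    table: ContingencyTable,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    tie_break: str = "random",
) -> TestResult:
    """Permutation version of Pearson's χ² test."""
    return _fast_perm_test(table, "pearson_perm", B, seed, tie_break)


def g_perm_test(
    table: ContingencyTable,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    tie_break: str = "random",
) -> TestResult:
    """Permutation version of the G-test."""
    return _fast_perm_test(table, "g_perm", B, seed, tie_break)


def fisher_exact_test(
    table: ContingencyTable,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    mode: str = "auto",
    tie_break: str = "random",
) -> TestResult:
    """Two-sided Fisher's exact test.

    ``exact2x2`` enumerates the hypergeometric null of a 2×2 table (summing
    probabilities of tables no more probable than the observed one);
    ``montecarlo`` samples B tables from the fixed-margins null via uniform
    y-permutations and ranks the observed table by its null probability,
    with the same random tie-break convention as the permutation tests.
    ``auto`` picks exact for 2×2, Monte-Carlo otherwise.  The reported
    statistic is −log of the observed table's null probability.
    """
    if table.n < 1:
        raise DegenerateTableError("Fisher's exact test needs at least one observation")
    if mode == "auto":
        mode = "exact2x2" if table.counts.shape == (2, 2) else "montecarlo"
    log_const = _fisher_log_const(table)
    obs_stat = float(_fisher_neg_log_prob(table.counts, log_const))
    if mode == "exact2x2":
        if table.counts.shape != (2, 2):
            raise ValueError("exact2x2 mode requires a 2x2 table")
        p = float(_sps.fisher_exact(table.counts)[1])
        return TestResult("fisher", obs_stat, p, 0,
                          seed if isinstance(seed, int) else None, None)
    if mode != "montecarlo":
        raise ValueError(f"unknown Fisher mode {mode!r}")
    return _fast_perm_test(table, "fisher", B, seed, tie_break)


def batch_pvalues(
    table: ContingencyTable,
    tests: Sequence[str],
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    tie_break: str = "random",
    _return_details: bool = False,
) -> Mapping[str, float] | Mapping[str, tuple[float, int | None, float]]:
    """p-values for several tests evaluated on one shared set of permutations.

    The simulation studies' workhorse: the B permuted tables are tabulated
    once and every requested statistic is evaluated on them vectorized.
    χ²-quantile versions ('pearson_quantile', 'g_quantile') need no
    permutations and are computed directly.

    Returns {test: p}; with ``_return_details`` returns
    {test: (observed statistic, rank, p)} (rank None for quantile tests).
    """
    unknown = set(tests) - set(ALL_TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    rng = _as_rng(seed)
    n = table.n
    e = expected_counts(table)
    out: dict[str, tuple[float, int | None, float]] = {}

    perm_tests = [t for t in tests if t in PERM_TESTS]
    if perm_tests:
        if "usp" in perm_tests and n < 4:
            raise SampleSizeError(f"USP test requires n >= 4 observations, got {n}")
        sample = pairs_from_table(table)
        log_const = _fisher_log_const(table)

        def values(counts: np.ndarray) -> dict[str, np.ndarray]:
            vals: dict[str, np.ndarray] = {}
            if "usp" in perm_tests:
                vals["usp"] = np.atleast_1d(_usp_values(counts, e, n))
            if "pearson_perm" in perm_tests:
                vals["pearson_perm"] = np.atleast_1d(_pearson_values(counts, e))
            if "g_perm" in perm_tests:
                vals["g_perm"] = np.atleast_1d(_g_values(counts, e))
            if "fisher" in perm_tests:
                vals["fisher"] = np.atleast_1d(_fisher_neg_log_prob(counts, log_const))
            return vals

        obs_vals = {k: float(v[0]) for k, v in values(table.counts[None]).items()}
        # chunk so the tiled permutation matrix stays modest in memory
        chunk = max(1, min(B, 2_000_000 // max(n, 1)))
        perm_vals: dict[str, list[np.ndarray]] = {t: [] for t in perm_tests}
        done = 0
        while done < B:
            b = min(chunk, B - done)
            counts = _permuted_counts(sample, b, rng)
            for t, v in values(counts).items():
                perm_vals[t].append(v)
            done += b
        for t in perm_tests:
            allv = np.concatenate(perm_vals[t])
            rank = _rank_among(obs_vals[t], allv, rng, tie_break)
            out[t] = (obs_vals[t], rank, rank / (B + 1))

    for t in tests:
        if t == "pearson_quantile":
            stat = pearson_chi2(table)
            out[t] = (stat, None, chi2_quantile_pvalue(stat, table.I, table.J))
        elif t == "g_quantile":
            stat = g_statistic(table)
            out[t] = (stat, None, chi2_quantile_pvalue(stat, table.I, table.J))

    if _return_details:
        return out
    return {t: out[t][2] for t in tests}
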