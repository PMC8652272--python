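"""Classical independence-test statistics and χ²-quantile p-values.

Pearson's χ² and the likelihood-ratio G statistic, together with the
asymptotic p-value obtained by referring either statistic to the χ²
distribution with (I−1)(J−1) degrees of freedom.  Cells with zero expected
count contribute 0 to χ² (they force a zero observed count), and zero
observed counts contribute 0 to G (the x log x → 0 limit); both conventions
keep the statistics defined on tables with empty cells, rows or columns, so
that their permutation versions are always computable.

Degrees of freedom always use the declared table dimensions, including
zero-total rows/columns — the quantile-version tests deliberately inherit
the classical behaviour they are compared against.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

from .core import JointDistribution
from .tables import ContingencyTable, DegenerateTableError, expected_counts

__all__ = [
    "pearson_chi2",
    "g_statistic",
    "chi2_divergence",
    "chi2_quantile_pvalue",
]


def pearson_chi2(table: ContingencyTable) -> float:
    """Pearson's χ² = Σ_ij (o_ij − e_ij)² / e_ij over cells with e_ij > 0."""
    e = expected_counts(table)  # raises on the all-zero table
    o = table.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    return float(terms.sum())


def g_statistic(table: ContingencyTable) -> float:
    """Likelihood-ratio statistic G = 2 Σ_ij o_ij ln(o_ij / e_ij).

    Natural logarithm; cells with o_ij = 0 contribute 0.
    """
    e = expected_counts(table)
    o = table.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(np.where(o > 0, o, 1.0) / np.where(e > 0, e, 1.0)), 0.0)
    return float(2.0 * terms.sum())


def chi2_divergence(P: JointDistribution | np.ndarray, Pprime: JointDistribution | np.ndarray) -> float:
    """χ² divergence χ²(P, P′) = Σ_ij (p_ij − p′_ij)² / p′_ij.

    Asymmetric in its arguments; requires p′_ij > 0 wherever p_ij > 0.
    """
    p = P.probs if isinstance(P, JointDistribution) else np.asarray(P, dtype=float)
    pp = Pprime.probs if isinstance(Pprime, JointDistribution) else np.asarray(Pprime, dtype=float)
    if p.shape != pp.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {pp.shape}")
    if np.any((p > 0) & (pp == 0)):
        raise ValueError("P' must be positive wherever P is (support violation)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pp > 0, (p - pp) ** 2 / np.where(pp > 0, pp, 1.0), 0.0)
    return float(terms.sum())


def chi2_quantile_pvalue(stat: float, I: int, J: int) -> float:  # noqa: E741
    """Upper-tail χ² p-value at ``stat`` with (I−1)(J−1) degrees of freedom."""
    if I < 2 or J < 2:
        raise ValueError("chi-squared quantile p-value needs I >= 2 and J >= 2 (df > 0)")
    if stat < 0:
        raise ValueError("statistic must be non-negative")
    return float(_sps.chi2.sf(stat, (I - 1) * (J - 1)))
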