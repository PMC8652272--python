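"""The dependence measure D, its U-statistic estimator D̂, and the USP statistic Û.

Writing p_ij for the joint cell probabilities and q_i, r_j for the marginals,
the population measure of dependence is

    D = Σ_ij (p_ij − q_i r_j)² ,

which is zero if and only if X and Y are independent.  Unlike the χ²
divergence it has no cell-probability denominators, so it weighs departures
in high- and low-probability cells equally.

D is estimated by a fourth-order U-statistic: the kernel

    h((x1,y1),…,(x4,y4)) = Σ_ij ( 1{x1=i,y1=j} 1{x2=i,y2=j}
                                  − 2·1{x1=i,y1=j} 1{x2=i} 1{y3=j}
                                  + 1{x1=i} 1{y2=j} 1{x3=i} 1{y4=j} )

has expectation Σ_ij (p_ij² − 2 p_ij q_i r_j + q_i² r_j²) = D over four iid
pairs, and D̂ is the average of h over all ordered 4-tuples of distinct
observation indices.  D̂ is the unique minimum-variance unbiased estimator
of D.  The part of D̂ that varies under permutations of the y-labels is the
USP test statistic (n ≥ 4)

    Û = Σ_ij (o_ij − e_ij)² / (n(n−3))  −  4 Σ_ij o_ij e_ij / (n(n−2)(n−3)) ;

D̂ − Û depends only on the row and column totals, which every y-permutation
preserves, so Û and D̂ always have the same rank across permuted datasets
and yield identical permutation tests.

``dhat_brute`` is the literal tuple-enumeration definition (the oracle,
feasible for n ≲ 12); ``dhat_closed_form`` is an algebraically equivalent
O(IJ) counts-only formula, validated against the brute force in the test
suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .tables import ContingencyTable, PairedSample, SampleSizeError, expected_counts

__all__ = [
    "JointDistribution",
    "dependence_D",
    "kernel_h",
    "dhat_brute",
    "usp_statistic",
    "dhat_closed_form",
]


@dataclass(frozen=True)
class JointDistribution:
    """Joint cell probabilities p_ij on an I×J category space."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("probs must be a non-empty 2-d array")
        if np.any(p < 0):
            raise ValueError("cell probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities must sum to 1 (got {total!r})")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def I(self) -> int:  # noqa: E743
        return self.probs.shape[0]

    @property
    def J(self) -> int:
        return self.probs.shape[1]

    @property
    def q(self) -> np.ndarray:
        """Row marginal probabilities q_i = Σ_j p_ij."""
        return self.probs.sum(axis=1)

    @property
    def r(self) -> np.ndarray:
        """Column marginal probabilities r_j = Σ_i p_ij."""
        return self.probs.sum(axis=0)

    @classmethod
    def product(cls, q: np.ndarray, r: np.ndarray) -> "JointDistribution":
        """The independent joint q ⊗ r with the given marginals."""
        return cls(np.outer(np.asarray(q, float), np.asarray(r, float)))


def dependence_D(joint: JointDistribution) -> float:
    """D = Σ_ij (p_ij − q_i r_j)²; non-negative, zero iff independent."""
    p = joint.probs
    return float(((p - np.outer(joint.q, joint.r)) ** 2).sum())


def kernel_h(
    p1: tuple[int, int],
    p2: tuple[int, int],
    p3: tuple[int, int],
    p4: tuple[int, int],
    I: int,  # noqa: E741
    J: int,
) -> float:
    """The fourth-order kernel, evaluated as the literal indicator double sum.

    Kept definitional (no algebraic simplification) so it can serve as the
    oracle for everything downstream.
    """
    (x1, y1), (x2, y2), (x3, y3), (x4, y4) = p1, p2, p3, p4
    total = 0
    for i in range(I):
        for j in range(J):
            total += (
                (x1 == i and y1 == j) * (x2 == i and y2 == j)
                - 2 * (x1 == i and y1 == j) * (x2 == i) * (y3 == j)
                + (x1 == i) * (y2 == j) * (x3 == i) * (y4 == j)
            )
    return float(total)


def dhat_brute(sample: PairedSample) -> float:
    """D̂ by direct enumeration: average of ``kernel_h`` over all
    n(n−1)(n−2)(n−3) ordered 4-tuples of distinct indices.

    O(n⁴ · IJ); intended as the ground-truth reference for small n.
    """
    n = sample.n
    if n < 4:
        raise SampleSizeError(f"D-hat requires n >= 4 observations, got {n}")
    pairs = sample.pairs
    I, J = sample.I, sample.J
    total = 0.0
    for a, b, c, d in itertools.permutations(range(n), 4):
        total += kernel_h(pairs[a], pairs[b], pairs[c], pairs[d], I, J)
    return total / (n * (n - 1) * (n - 2) * (n - 3))


def usp_statistic(table: ContingencyTable) -> float:
    """The USP test statistic Û (may be negative; defined for n ≥ 4)."""
    n = table.n
    if n < 4:
        raise SampleSizeError(f"USP statistic requires n >= 4 observations, got {n}")
    o = table.counts.astype(float)
    e = expected_counts(table)
    return float(
        ((o - e) ** 2).sum() / (n * (n - 3)) - 4.0 * (o * e).sum() / (n * (n - 2) * (n - 3))
    )


def _usp_values(counts: np.ndarray, e: np.ndarray, n: int) -> np.ndarray:
    """Vectorized Û over a stack of count arrays sharing margins/expected e."""
    o = counts.astype(float)
    t1 = ((o - e) ** 2).sum(axis=(-2, -1)) / (n * (n - 3))
    t2 = 4.0 * (o * e).sum(axis=(-2, -1)) / (n * (n - 2) * (n - 3))
    return t1 - t2


def _dhat_closed_values(counts: np.ndarray) -> np.ndarray:
    """Vectorized closed form for D̂ over a stack of count arrays.

    Derived by resolving the distinct-index constraints of the three kernel
    terms by inclusion–exclusion.  With row totals R_i, column totals C_j:

      term 1 (pairs in the same cell):
          Σ_ij o_ij(o_ij−1) / (n(n−1))
      term 2 (cell–row–column triples, all indices distinct):
          −2 Σ_ij [ o_ij R_i C_j − o_ij R_i − o_ij C_j − o_ij² + 2 o_ij ]
             / (n(n−1)(n−2))
      term 3 (row-pair × column-pair quadruples, all distinct):
          Σ_ij [ R_i(R_i−1) C_j(C_j−1) − 4 o_ij (R_i−1)(C_j−1)
                 + 2 o_ij(o_ij−1) ] / (n(n−1)(n−2)(n−3))
    """
    o = counts.astype(float)
    n = o.sum(axis=(-2, -1))
    R = o.sum(axis=-1, keepdims=True)
    C = o.sum(axis=-2, keepdims=True)
    t1 = (o * (o - 1)).sum(axis=(-2, -1)) / (n * (n - 1))
    t2 = (
        -2.0
        * (o * R * C - o * R - o * C - o**2 + 2 * o).sum(axis=(-2, -1))
        / (n * (n - 1) * (n - 2))
    )
    t3 = (
        R * (R - 1) * C * (C - 1) - 4 * o * (R - 1) * (C - 1) + 2 * o * (o - 1)
    ).sum(axis=(-2, -1)) / (n * (n - 1) * (n - 2) * (n - 3))
    return t1 + t2 + t3


def dhat_closed_form(table: ContingencyTable) -> float:
    """D̂ from counts alone in O(IJ); equals ``dhat_brute`` on the expanded
    sample, and equals ``usp_statistic`` plus a margin-only quantity."""
    if table.n < 4:
        raise SampleSizeError(f"D-hat requires n >= 4 observations, got {table.n}")
    return float(_dhat_closed_values(table.counts))
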