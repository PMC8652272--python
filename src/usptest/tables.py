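"""Contingency-table data model.

An I×J contingency table cross-classifies ``n`` paired categorical
observations (X, Y): the (i, j) cell count ``o_ij`` is the number of pairs
falling in row category ``i`` and column category ``j``.  The same data can
equivalently be carried as the ordered list of (x, y) index pairs, which is
the representation the permutation test shuffles.  This module provides both
representations, lossless conversion between them, and the margin arithmetic
(row/column totals, null-fitted expected counts ``e_ij = o_i+ o_+j / n``)
that every test statistic builds on.

Rows or columns with zero total are deliberately retained: dropping them
changes the hypothesis being tested, and the permutation tests remain
well-defined in their presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "PairedSample",
    "InvalidTableError",
    "DegenerateTableError",
    "SampleSizeError",
    "table_from_pairs",
    "pairs_from_table",
    "expected_counts",
]


class InvalidTableError(ValueError):
    """Raised when counts are negative, non-integer or non-rectangular."""


class DegenerateTableError(ValueError):
    """Raised when an operation is undefined on an all-zero (n = 0) table."""


class SampleSizeError(ValueError):
    """Raised when a statistic requires more observations than are present."""


@dataclass(frozen=True)
class ContingencyTable:
    """Immutable I×J matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        Array-like of shape (I, J) with non-negative integer entries.
    row_labels, col_labels
        Optional user-facing category labels, carried through I/O and
        reporting but never used in arithmetic.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise InvalidTableError(f"counts must be 2-dimensional, got shape {arr.shape}")
        if arr.size == 0:
            raise InvalidTableError("counts must have at least one row and one column")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.any(np.abs(arr - rounded) > 0):
                raise InvalidTableError("counts must be integers")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise InvalidTableError("counts must be non-negative")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        if self.row_labels is not None:
            object.__setattr__(self, "row_labels", tuple(str(l) for l in self.row_labels))
            if len(self.row_labels) != arr.shape[0]:
                raise InvalidTableError("row_labels length does not match row count")
        if self.col_labels is not None:
            object.__setattr__(self, "col_labels", tuple(str(l) for l in self.col_labels))
            if len(self.col_labels) != arr.shape[1]:
                raise InvalidTableError("col_labels length does not match column count")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol for row count
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        """o_i+ for each row."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """o_+j for each column."""
        return self.counts.sum(axis=0)

    def expected(self) -> np.ndarray:
        """Null-fitted expected counts e_ij = o_i+ o_+j / n."""
        return expected_counts(self)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.col_labels, self.row_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and bool(np.all(self.counts == other.counts))
        )

    def __hash__(self) -> int:
        return hash((self.counts.shape, self.counts.tobytes()))


@dataclass(frozen=True)
class PairedSample:
    """Ordered paired categorical sample over {0..I-1} × {0..J-1}.

    ``x`` and ``y`` are equal-length integer index arrays; the k-th
    observation is the pair (x[k], y[k]).  Indices are 0-based internally
    (labels, where present, live on the table representation).
    """

    x: np.ndarray
    y: np.ndarray
    I: int  # noqa: E741
    J: int

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.int64)
        y = np.asarray(self.y, dtype=np.int64)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise InvalidTableError("x and y must be 1-d arrays of equal length")
        if self.I < 1 or self.J < 1:
            raise InvalidTableError("category space must have I >= 1 and J >= 1")
        if x.size and (x.min() < 0 or x.max() >= self.I):
            raise InvalidTableError("x index out of range")
        if y.size and (y.min() < 0 or y.max() >= self.J):
            raise InvalidTableError("y index out of range")
        x.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.x.tolist(), self.y.tolist()))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[int, int]], I: int, J: int  # noqa: E741
    ) -> "PairedSample":
        arr = np.array(list(pairs), dtype=np.int64).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1], I, J)


def table_from_pairs(sample: PairedSample) -> ContingencyTable:
    """Tabulate a paired sample into its contingency table of counts."""
    flat = np.bincount(sample.x * sample.J + sample.y, minlength=sample.I * sample.J)
    return ContingencyTable(flat.reshape(sample.I, sample.J))


def pairs_from_table(table: ContingencyTable) -> PairedSample:
    """Expand a table into its n observation pairs, in canonical row-major
    order with repeats contiguous (any order is statistically equivalent; a
    fixed one makes runs reproducible)."""
    flat = table.counts.ravel()
    cells = np.repeat(np.arange(flat.size), flat)
    return PairedSample(cells // table.J, cells % table.J, table.I, table.J)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence, e_ij = o_i+ o_+j / n.

    Row and column sums of the result equal those of the observed counts.
    """
    n = table.n
    if n == 0:
        raise DegenerateTableError("expected counts undefined for an all-zero table")
    return np.outer(table.row_totals, table.col_totals) / n
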