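"""Built-in example and edge-case tables.

Two small public classroom datasets used throughout the documentation and
tests — a 4×5 cross-classification of marital status by education level for
300 survey respondents, and a 2×5 cross-classification of eye colour by sex
for 167 individuals — plus degenerate fixtures (zero row/column, minimal n,
single-row) that exercise the conventions for empty cells.
"""

from __future__ import annotations

import numpy as np

from .tables import ContingencyTable

__all__ = ["marital_education", "eye_colour", "fixture_tables"]


def marital_education() -> ContingencyTable:
    """Marital status (rows) by education level (columns), n = 300."""
    return ContingencyTable(
        np.array(
            [
                [18, 36, 21, 9, 6],
                [12, 36, 45, 36, 21],
                [6, 9, 9, 3, 3],
                [3, 9, 9, 6, 3],
            ]
        ),
        row_labels=("Never married", "Married", "Divorced", "Widowed"),
        col_labels=(
            "Middle school or lower",
            "High school",
            "Bachelor's",
            "Master's",
            "PhD or higher",
        ),
    )


def eye_colour() -> ContingencyTable:
    """Eye colour (columns) by sex (rows): 85 females, 82 males, n = 167."""
    return ContingencyTable(
        np.array([[20, 30, 10, 15, 10], [25, 15, 12, 20, 10]]),
        row_labels=("female", "male"),
        col_labels=("black", "brown", "blue", "green", "grey"),
    )


def fixture_tables() -> dict[str, ContingencyTable]:
    """Named set of built-in tables, including degenerate edge cases."""
    return {
        "marital_education": marital_education(),
        "eye_colour": eye_colour(),
        "zero_row": ContingencyTable(np.array([[3, 2], [0, 0], [1, 4]])),
        "zero_column": ContingencyTable(np.array([[3, 0, 2], [1, 0, 4]])),
        "minimal_n4": ContingencyTable(np.array([[2, 0], [0, 2]])),
        "single_row": ContingencyTable(np.array([[1, 2, 3]])),
    }
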