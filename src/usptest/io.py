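"""Reading and writing contingency tables as CSV/TSV.

The reader accepts a rectangular integer matrix with an optional header row
and/or leading label column, both auto-detected by non-numeric content;
the delimiter is inferred from the filename/content or set explicitly.
The writer mirrors the reader so tables round-trip losslessly.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np

from .tables import ContingencyTable, InvalidTableError

__all__ = ["read_table", "write_table"]


def _is_int(token: str) -> bool:
    try:
        int(token.strip())
        return True
    except ValueError:
        return False


def _sniff_delimiter(text: str, path: str | Path | None) -> str:
    if path is not None and str(path).lower().endswith((".tsv", ".tab")):
        return "\t"
    first = text.splitlines()[0] if text.splitlines() else ""
    if "\t" in first:
        return "\t"
    if ";" in first and "," not in first:
        return ";"
    return ","


def read_table(path: str | Path, delimiter: str | None = None) -> ContingencyTable:
    """Parse a CSV/TSV count matrix into a :class:`ContingencyTable`.

    Raises :class:`InvalidTableError` naming the offending row/column on
    ragged, negative or non-integer input.
    """
    text = Path(path).read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text, path)
    rows = [row for row in csv.reader(_io.StringIO(text), delimiter=delimiter)
            if any(cell.strip() for cell in row)]
    if not rows:
        raise InvalidTableError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise InvalidTableError(f"{path}: ragged rows (widths {sorted(widths)})")

    # header row present if any cell after the first is non-integer
    has_header = any(not _is_int(c) for c in rows[0][1:])
    body = rows[1:] if has_header else rows
    if not body:
        raise InvalidTableError(f"{path}: header but no data rows")
    # label column present if any first cell of the body is non-integer,
    # or a header is present whose first cell is blank
    has_labels = any(not _is_int(r[0]) for r in body) or (
        has_header and not rows[0][0].strip()
    )

    col_labels = None
    if has_header:
        col_labels = [c.strip() for c in (rows[0][1:] if has_labels else rows[0])]
    row_labels = [r[0].strip() for r in body] if has_labels else None

    counts = []
    for ridx, r in enumerate(body):
        cells = r[1:] if has_labels else r
        row = []
        for cidx, cell in enumerate(cells):
            if not _is_int(cell):
                raise InvalidTableError(
                    f"{path}: non-integer count {cell!r} at data row {ridx + 1}, column {cidx + 1}"
                )
            v = int(cell)
            if v < 0:
                raise InvalidTableError(
                    f"{path}: negative count {v} at data row {ridx + 1}, column {cidx + 1}"
                )
            row.append(v)
        counts.append(row)
    return ContingencyTable(
        np.array(counts, dtype=np.int64),
        tuple(row_labels) if row_labels else None,
        tuple(col_labels) if col_labels else None,
    )


def write_table(table: ContingencyTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a table as CSV/TSV, emitting labels when the table carries them."""
    if delimiter is None:
        delimiter = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        if table.col_labels is not None:
            head = list(table.col_labels)
            if table.row_labels is not None:
                head = [""] + head
            w.writerow(head)
        for i in range(table.I):
            row = [int(v) for v in table.counts[i]]
            if table.row_labels is not None:
                row = [table.row_labels[i]] + row
            w.writerow(row)
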