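"""Reading and writing joint rating tables as annotated CSV.

A table file is a 9 x 9 (generally square) CSV body preceded by a small
``#``-prefixed key-value header declaring how to interpret the numbers::

    # order: self_first
    # kind: percent
    # n: 775
    r1,r2,r3,r4,r5,r6,r7,r8,r9
    11,1,0,0,0,0,0,0,0
    ...

``kind`` is one of ``percent`` (integer or fractional percentages, as
tables are usually printed), ``proportion`` or ``count``.  The scale is
always declared, never guessed.  Percent tables are divided by 100 and, if
the result deviates from 1 by more than 2%, renormalised with a logged
warning (printed tables carry rounding error).

An optional ``rows`` key declares what the file's rows index:
``first_question`` (the package's in-memory convention, default),
``self`` or ``other``.  Published tables conventionally print self
ratings on the rows for *both* question orders, so an other-first table
with ``rows: self`` is transposed on reading to the in-memory
first-question-rows convention.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .prediction import JointTable

__all__ = ["TableFormatError", "read_table", "write_table"]

logger = logging.getLogger(__name__)

_FILE_KINDS = ("percent", "proportion", "count")


class TableFormatError(ValueError):
    """Raised when a table file cannot be parsed or is inconsistent."""


def _parse_header_line(line: str) -> tuple[str, str]:
    body = line.lstrip("#").strip()
    if ":" not in body:
        raise TableFormatError(f"malformed metadata line: {line!r}")
    key, _, value = body.partition(":")
    return key.strip().lower(), value.strip()


def read_table(path: str | Path) -> JointTable:
    """Read an annotated CSV table file into a :class:`JointTable`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path, newline="") as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, value = _parse_header_line(line)
                meta[key] = value
                continue
            fields = next(csv.reader([line]))
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                if rows:
                    raise TableFormatError(
                        f"{path}: non-numeric row after data started: {line!r}"
                    )
                continue  # header row such as r1,...,r9

    for key in ("order", "kind"):
        if key not in meta:
            raise TableFormatError(f"{path}: missing required metadata '# {key}: ...'")
    kind = meta["kind"]
    if kind not in _FILE_KINDS:
        raise TableFormatError(f"{path}: kind must be one of {_FILE_KINDS}, got {kind!r}")

    if not rows:
        raise TableFormatError(f"{path}: no data rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise TableFormatError(f"{path}: ragged rows with widths {sorted(widths)}")
    cells = np.asarray(rows, dtype=float)
    if cells.shape[0] != cells.shape[1]:
        raise TableFormatError(
            f"{path}: expected a square table, got {cells.shape[0]} rows x "
            f"{cells.shape[1]} columns"
        )

    rows = meta.get("rows", "first_question")
    if rows not in ("first_question", "self", "other"):
        raise TableFormatError(f"{path}: rows must be first_question, self or other")
    if rows != "first_question":
        first_question = "self" if meta["order"] == "self_first" else "other"
        if rows != first_question:
            cells = cells.T

    n = float(meta["n"]) if "n" in meta else None
    if kind == "count":
        return JointTable(order=meta["order"], cells=cells, kind="count", n=n)
    if kind == "percent":
        cells = cells / 100.0
    total = cells.sum()
    if abs(total - 1.0) > 0.02:
        logger.warning(
            "%s: cells sum to %.4f; renormalising to 1 (rounding in the source?)",
            path,
            total,
        )
        cells = cells / total
    return JointTable(order=meta["order"], cells=cells, kind="relative_frequency", n=n)


def write_table(table: JointTable, path: str | Path, digits: int = 12) -> None:
    """Write a :class:`JointTable` in the annotated CSV format.

    Proportion-scale tables round-trip losslessly at the default 12
    significant digits.
    """
    path = Path(path)
    kind = "count" if table.kind == "count" else "proportion"
    r = table.n_ratings
    lines = [f"# order: {table.order}", f"# kind: {kind}", "# rows: first_question"]
    if table.n is not None:
        lines.append(f"# n: {table.n:g}")
    lines.append(",".join(f"r{k}" for k in range(1, r + 1)))
    for row in table.cells:
        lines.append(",".join(f"{v:.{digits}g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
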