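"""Joint rating tables, the non-judgemental mixture, and summary predictions.

A :class:`JointTable` holds the joint distribution of the two ratings given
on one trial, conditioned on question order.  The first (row) index is
always the rating given to the question asked *first*; in the
``self_first`` order rows are self ratings, in the ``other_first`` order
rows are other ratings.

The non-judgemental mixture models trials on which the judge skips the
evaluation process and simply reports the scale midpoint for both
questions: with probability ``lambda`` the walk model produces the pair of
ratings, with probability ``1 - lambda`` the pair is fixed at the midpoint
cell (5, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ORDERS",
    "JointTable",
    "apply_mixture",
    "table_means",
    "order_effect_summary",
    "OrderEffectSummary",
]

ORDERS = ("self_first", "other_first")

_KINDS = ("probability", "relative_frequency", "count")

#: Sum tolerance for tables that are supposed to be normalised.
_NORM_TOL = 1e-10
#: Printed relative-frequency tables carry rounding error; anything beyond
#: this is treated as a malformed table rather than rounding.
_FREQ_TOL = 0.02


@dataclass(frozen=True)
class JointTable:
    """Joint distribution of (first rating, second rating) for one order.

    Parameters
    ----------
    order
        ``"self_first"`` or ``"other_first"``; rows always index the first
        question asked.
    cells
        Square array of non-negative values (9 x 9 for the standard scale).
    kind
        ``"probability"`` (sums to 1), ``"relative_frequency"`` (proportions
        from data, sums to 1 up to rounding) or ``"count"``.
    n
        Sample size.  Required for counts (defaults to the cell total) and
        for relative frequencies that will be converted to counts.
    """

    order: str
    cells: np.ndarray = field(repr=False)
    kind: str = "probability"
    n: float | None = None

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}, got {self.order!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        cells = np.asarray(self.cells, dtype=float)
        if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
            raise ValueError(f"cells must be a square matrix, got shape {cells.shape}")
        if np.any(cells < 0) or not np.all(np.isfinite(cells)):
            raise ValueError("cells must be finite and non-negative")
        object.__setattr__(self, "cells", cells)
        total = cells.sum()
        if self.kind == "probability" and abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"probability table must sum to 1, got {total!r}")
        if self.kind == "relative_frequency" and abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"relative-frequency table sums to {total!r}; expected 1 within "
                f"{_FREQ_TOL} (is it on a percent scale?)"
            )
        if self.kind == "count" and self.n is None:
            object.__setattr__(self, "n", float(total))

    @property
    def n_ratings(self) -> int:
        return self.cells.shape[0]

    def as_probability(self) -> "JointTable":
        """Renormalised copy with ``kind="probability"``.

        Printed relative-frequency tables carry rounding error, so they are
        renormalised to sum exactly to one before analysis.
        """
        total = self.cells.sum()
        if total <= 0:
            raise ValueError("cannot normalise a table with zero total")
        return replace(self, cells=self.cells / total, kind="probability")

    def to_counts(self, n: float | None = None) -> "JointTable":
        """Convert to a count table with total ``n`` (may be non-integral).

        Counts reconstructed from printed percentages are fractional by
        construction; they enter the likelihood as multinomial weights.
        """
        if self.kind == "count":
            return self
        if n is None:
            n = self.n
        if n is None:
            raise ValueError("sample size n is required to form counts")
        probs = self.as_probability().cells
        return replace(self, cells=probs * n, kind="count", n=float(n))


def apply_mixture(table: JointTable, lam: float) -> JointTable:
    """Mix a walk-model table with the non-judgemental midpoint response.

    Every cell is multiplied by ``lam`` and the remaining ``1 - lam`` mass
    is added to the midpoint cell, so normalisation is preserved.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"mixture weight must lie in [0, 1], got {lam}")
    if table.kind != "probability":
        raise ValueError("mixture applies to probability tables")
    cells = lam * table.cells
    mid = (table.n_ratings + 1) // 2 - 1
    cells[mid, mid] += 1.0 - lam
    return replace(table, cells=cells)


def table_means(table: JointTable) -> tuple[float, float]:
    """Mean rating of the first and second question, ``(mean_first, mean_second)``.

    ``mean_first`` is the expectation of the row index (first question
    asked) under the row marginal, ``mean_second`` the expectation of the
    column index under the column marginal.
    """
    if table.kind == "count":
        raise ValueError("table_means expects probabilities or relative frequencies")
    probs = table.as_probability().cells
    ratings = np.arange(1, table.n_ratings + 1)
    mean_first = float(probs.sum(axis=1) @ ratings)
    mean_second = float(probs.sum(axis=0) @ ratings)
    return mean_first, mean_second


class OrderEffectSummary(NamedTuple):
    """Self-minus-other mean differences within each order and their interaction."""

    diff_self_first: float
    diff_other_first: float
    interaction: float


def order_effect_summary(
    t_self_first: JointTable, t_other_first: JointTable
) -> OrderEffectSummary:
    """Mean self-other difference within each question order.

    In the self-first table the self rating is the first (row) index; in
    the other-first table it is the second (column) index.  The interaction
    is the change of the self-other difference across orders — the
    signature of the question-order effect on the means.
    """
    if t_self_first.order != "self_first" or t_other_first.order != "other_first":
        raise ValueError("tables must be passed as (self_first, other_first)")
    self_1, other_1 = table_means(t_self_first)
    other_2, self_2 = table_means(t_other_first)
    diff_sf = self_1 - other_1
    diff_of = self_2 - other_2
    return OrderEffectSummary(diff_sf, diff_of, diff_sf - diff_of)
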