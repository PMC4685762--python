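"""Likelihood-ratio test for question-order effects on joint rating tables.

The saturated model gives every cell of every order-conditioned table its
own probability (``2 * (k - 1)`` free parameters for two tables of ``k``
cells); the restricted model assumes a single joint distribution for both
orders (``k - 1`` free parameters), whose maximum-likelihood estimate is
the pooled proportion.  ``G^2 = -2 [lnL(restricted) - lnL(saturated)]`` is
referred to a chi-square distribution with ``k - 1`` degrees of freedom
(80 for two 9 x 9 tables).

The chi-square reference assumes independent observations; when trials
are pooled over participants and stimuli that assumption is an
approximation, which the result records rather than corrects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .prediction import JointTable

__all__ = ["OrderTestResult", "order_effect_g2", "chi2_upper_tail"]


@dataclass(frozen=True)
class OrderTestResult:
    """Saturated-vs-restricted test outcome."""

    g2: float
    df: int
    p_value: float
    n_self_first: float
    n_other_first: float
    n_free_saturated: int
    n_free_restricted: int
    note: str = (
        "chi-square reference assumes independent observations; trials pooled "
        "over participants and stimuli only approximate this"
    )


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the chi-square distribution."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be non-negative, got {x}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return float(chi2.sf(x, df))


def order_effect_g2(t1: JointTable, t2: JointTable) -> OrderTestResult:
    """Test whether the two question orders share one joint distribution.

    ``t1`` and ``t2`` are the count tables for the self-first and
    other-first orders, rows indexing the first question asked.  The null
    hypothesis concerns the joint distribution of (self, other) rating
    pairs, so the other-first table is transposed to align self with self
    before pooling.  Cells with zero count contribute nothing to a
    table's log-likelihood; no continuity correction is applied.
    """
    if {t1.order, t2.order} != {"self_first", "other_first"}:
        raise ValueError("need one table per question order")
    if t1.order == "other_first":
        t1, t2 = t2, t1
    c1 = t1.to_counts().cells
    c2 = t2.to_counts().cells.T  # align to self-rows x other-columns
    if c1.shape != c2.shape:
        raise ValueError("tables must have the same shape")
    n1, n2 = c1.sum(), c2.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both tables must have positive totals")
    pooled = (c1 + c2) / (n1 + n2)
    g2 = 0.0
    for c, n in ((c1, n1), (c2, n2)):
        mask = c > 0
        g2 += 2.0 * float((c[mask] * np.log((c[mask] / n) / pooled[mask])).sum())
    k = c1.size
    df = k - 1
    return OrderTestResult(
        g2=g2,
        df=df,
        p_value=chi2_upper_tail(max(g2, 0.0), df),
        n_self_first=float(n1),
        n_other_first=float(n2),
        n_free_saturated=2 * (k - 1),
        n_free_restricted=k - 1,
    )
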