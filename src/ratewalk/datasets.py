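"""Packaged reference data: the published joint rating tables and estimates.

The bundled fixtures are the two order-conditioned 9 x 9 joint relative
frequency tables from the self/other message-effectiveness rating
experiment (131 participants x 12 public service announcements, question
order randomised per trial; 775 self-first and 797 other-first trials),
stored verbatim as the integer percentages they were published at, plus
the quantum-model predicted tables published alongside them.  Because the
cells are rounded to whole percent, statistics recomputed from these
fixtures approximate, rather than equal, values computed from the raw
trial data (see the methods note for how large that gap can be for
likelihood-ratio statistics).

``REFERENCE_ESTIMATES`` carries the parameter estimates published for
these data under both objectives, and ``REFERENCE_MEANS`` the observed
and model-predicted mean ratings per question order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib.resources import as_file, files

from .io import read_table
from .markov import MarkovParams
from .prediction import JointTable
from .quantum import QuantumParams

__all__ = [
    "load_observed_table",
    "load_observed_tables",
    "load_predicted_table",
    "ReferenceEstimate",
    "REFERENCE_ESTIMATES",
    "REFERENCE_MEANS",
    "ORDER_TEST_REFERENCE",
]

_FIXTURES = {
    ("observed", "self_first"): (
        "observed_self_first.csv",
        "e95c3a0ddb376141811f066e77a0a91f9f541d7c8e9a7da1b58bfc78d6b695e9",
    ),
    ("observed", "other_first"): (
        "observed_other_first.csv",
        "a7452ca6e01a8a8c9fadb2781a690f6301e8ff11fdf670f18c12c0ce3b720dd0",
    ),
    ("predicted", "self_first"): (
        "predicted_quantum_self_first.csv",
        "092ed5d70e00476d07fe3a5cc746c95742730e7088b08e33d5d1ef8b77c67965",
    ),
    ("predicted", "other_first"): (
        "predicted_quantum_other_first.csv",
        "f630f81b58fb1dede30a13ebf066b21801658461ac6964ad2b1b4324cf08eece",
    ),
}


def _load(which: str, order: str) -> JointTable:
    try:
        name, digest = _FIXTURES[(which, order)]
    except KeyError:
        raise ValueError(f"no fixture for ({which!r}, {order!r})") from None
    resource = files("ratewalk.data").joinpath(name)
    data = resource.read_bytes()
    actual = hashlib.sha256(data).hexdigest()
    if actual != digest:
        raise RuntimeError(f"fixture {name} is corrupted (sha256 {actual})")
    with as_file(resource) as path:
        return read_table(path)


def load_observed_table(order: str) -> JointTable:
    """Observed joint relative-frequency table for one question order."""
    return _load("observed", order)


def load_observed_tables() -> tuple[JointTable, JointTable]:
    """Both observed tables, ``(self_first, other_first)``."""
    return _load("observed", "self_first"), _load("observed", "other_first")


def load_predicted_table(order: str) -> JointTable:
    """Published quantum-model predicted table (integer percent) for one order."""
    return _load("predicted", order)


@dataclass(frozen=True)
class ReferenceEstimate:
    """A published parameter estimate and its accompanying fit statistic."""

    model: str
    objective: str
    params: MarkovParams | QuantumParams
    mixture: float
    statistic_name: str
    statistic: float


#: Published 5-parameter estimates for the bundled data, keyed by
#: (objective, model).  The SSE rows minimise squared error over both
#: tables; the likelihood rows minimise G^2 against the saturated model.
REFERENCE_ESTIMATES: dict[tuple[str, str], ReferenceEstimate] = {
    ("sse", "markov"): ReferenceEstimate(
        "markov", "sse", MarkovParams(339.53, 330.37, 419.82, 402.93), 0.90, "r2", 0.54
    ),
    ("sse", "quantum"): ReferenceEstimate(
        "quantum", "sse", QuantumParams(99.24, -14.57, 89.53, -16.74), 0.94, "r2", 0.90
    ),
    ("likelihood", "markov"): ReferenceEstimate(
        "markov", "likelihood", MarkovParams(317.63, 313.72, 283.87, 270.94), 0.91, "g2", 1190.0
    ),
    ("likelihood", "quantum"): ReferenceEstimate(
        "quantum", "likelihood", QuantumParams(114.58, -13.28, 92.43, -17.56), 0.91, "g2", 839.0
    ),
}

#: Mean ratings per question order as (mean of first question asked, mean
#: of second question asked).  "observed" are the data; "quantum_sse" are
#: the model predictions published for the SSE-row parameters.
REFERENCE_MEANS = {
    "observed": {"self_first": (4.64, 4.14), "other_first": (3.88, 4.11)},
    "quantum_sse": {"self_first": (4.36, 4.25), "other_first": (4.21, 4.29)},
}

#: Published saturated-vs-restricted order test on the raw trial counts.
ORDER_TEST_REFERENCE = {"g2": 110.19, "df": 80, "p_value": 0.0143}

#: Published Markov single-table SSE fits (each order fitted separately).
SINGLE_TABLE_R2_REFERENCE = {"markov": {"self_first": 0.92, "other_first": 0.92}}
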