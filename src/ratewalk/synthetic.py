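"""Trial-level synthetic experiments drawn from either walk model.

Emulates the design of the motivating experiment: each participant rates
every stimulus once, the question order of each trial is randomised
independently (Bernoulli with probability ``order_probability`` of
self-first), and the pair of ratings is a single multinomial draw from the
generating model's mixture-adjusted joint table for that trial's order.

Participants are homogeneous and the stimulus identity does not change the
generating parameters — the models under study pool all trials, so the
participant and stimulus ids exist to give records a realistic shape, not
to carry effects.  One seeded pseudo-random stream drives an experiment:
the order draws are consumed first (one per trial, in record order), then
one uniform per trial is mapped through the inverse CDF of that trial's
order-specific joint table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lattice import LatticeSpec
from .markov import MarkovParams, markov_joint
from .prediction import JointTable, apply_mixture
from .quantum import QuantumParams, quantum_joint

__all__ = [
    "TrialRecord",
    "ExperimentConfig",
    "generating_tables",
    "simulate_experiment",
    "aggregate_tables",
    "write_records",
    "read_records",
]

RECORD_COLUMNS = ("participant", "stimulus", "order", "r_first", "r_second")


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One synthetic trial: who, what, in which order, and the two ratings."""

    participant: int
    stimulus: int
    order: str
    r_first: int
    r_second: int


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and generating process of one synthetic experiment.

    Defaults reproduce the reference design: 131 participants, 12 stimuli
    each, question order randomised with equal probability.
    """

    params: MarkovParams | QuantumParams
    model: str = "quantum"
    mixture: float = 1.0
    n_participants: int = 131
    n_stimuli: int = 12
    order_probability: float = 0.5
    seed: int = 0
    spec: LatticeSpec = field(default_factory=LatticeSpec)

    def __post_init__(self) -> None:
        if self.model not in ("markov", "quantum"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_participants < 1 or self.n_stimuli < 1:
            raise ValueError("participant and stimulus counts must be positive")
        if not 0.0 <= self.order_probability <= 1.0:
            raise ValueError("order_probability must lie in [0, 1]")
        expected = MarkovParams if self.model == "markov" else QuantumParams
        if not isinstance(self.params, expected):
            raise ValueError(
                f"params must be {expected.__name__} for model {self.model!r}"
            )

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.n_stimuli


def generating_tables(config: ExperimentConfig) -> dict[str, JointTable]:
    """Mixture-adjusted joint tables of the generating model, per order."""
    joint = markov_joint if config.model == "markov" else quantum_joint
    return {
        order: apply_mixture(joint(config.spec, config.params, order), config.mixture)
        for order in ("self_first", "other_first")
    }


def simulate_experiment(config: ExperimentConfig) -> list[TrialRecord]:
    """Draw one full experiment; deterministic given ``config.seed``."""
    tables = generating_tables(config)
    r = config.spec.n_ratings
    cdf = {o: np.cumsum(t.cells.ravel()) for o, t in tables.items()}
    for c in cdf.values():
        c[-1] = 1.0  # guard against round-off at the top of the CDF

    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    self_first = rng.random(n) < config.order_probability
    u = rng.random(n)
    cells = np.where(
        self_first,
        np.searchsorted(cdf["self_first"], u, side="right"),
        np.searchsorted(cdf["other_first"], u, side="right"),
    )
    r_first = cells // r + 1
    r_second = cells % r + 1

    records = []
    for i in range(n):
        records.append(
            TrialRecord(
                participant=i // config.n_stimuli + 1,
                stimulus=i % config.n_stimuli + 1,
                order="self_first" if self_first[i] else "other_first",
                r_first=int(r_first[i]),
                r_second=int(r_second[i]),
            )
        )
    return records


def aggregate_tables(
    records: Sequence[TrialRecord], n_ratings: int = 9
) -> tuple[JointTable, JointTable]:
    """Pool trials into one count table per question order.

    Rows index the rating of the first question asked, exactly as in the
    model tables; the two totals sum to the number of records.
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    counts = {
        "self_first": np.zeros((n_ratings, n_ratings)),
        "other_first": np.zeros((n_ratings, n_ratings)),
    }
    for rec in records:
        if not (1 <= rec.r_first <= n_ratings and 1 <= rec.r_second <= n_ratings):
            raise ValueError(f"rating out of range in record {rec}")
        counts[rec.order][rec.r_first - 1, rec.r_second - 1] += 1
    return (
        JointTable(order="self_first", cells=counts["self_first"], kind="count"),
        JointTable(order="other_first", cells=counts["other_first"], kind="count"),
    )


def write_records(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trial records as CSV with the standard header."""
    frame = pd.DataFrame(
        [(r.participant, r.stimulus, r.order, r.r_first, r.r_second) for r in records],
        columns=RECORD_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_records(path: str | Path) -> list[TrialRecord]:
    """Read trial records written by :func:`write_records`."""
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"record file {path} is missing columns {sorted(missing)}")
    return [
        TrialRecord(
            participant=int(row.participant),
            stimulus=int(row.stimulus),
            order=str(row.order),
            r_first=int(row.r_first),
            r_second=int(row.r_second),
        )
        for row in frame.itertuples(index=False)
    ]
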