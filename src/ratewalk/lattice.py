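"""Evaluation-state lattice shared by the Markov and quantum walk models.

Both models assume that a judge evaluates a stimulus on a fine internal
scale of ``N`` ordered evaluation states.  Consecutive blocks of
``states_per_rating`` states are mapped onto one observable rating, so a
9-point response scale with 11 states per rating gives ``N = 99`` internal
states.  The number of states per rating is odd so that every rating block
has a midpoint, and the initial state of a trial is spread uniformly over
the block of states centred on the scale midpoint (the "neutral" window).

State and rating indices are 1-based in the public contract; arrays use
0-based storage internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeSpec",
    "Projector",
    "InitialState",
    "rating_block",
    "make_projector",
    "initial_state",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the evaluation lattice.

    Parameters
    ----------
    n_ratings
        Number of observable rating levels (default 9).
    states_per_rating
        Number of internal evaluation states mapped to each rating level.
        Must be odd so each rating block has a midpoint (default 11).
    """

    n_ratings: int = 9
    states_per_rating: int = 11

    def __post_init__(self) -> None:
        if self.n_ratings < 1:
            raise ValueError("n_ratings must be a positive integer")
        if self.states_per_rating < 1:
            raise ValueError("states_per_rating must be a positive integer")
        if self.states_per_rating % 2 == 0:
            raise ValueError(
                "states_per_rating must be odd so each rating block has a midpoint"
            )

    @property
    def n_states(self) -> int:
        """Total number of evaluation states ``N``."""
        return self.n_ratings * self.states_per_rating

    @property
    def neutral_rating(self) -> int:
        """Rating level whose block carries the initial state (middle of the scale)."""
        return (self.n_ratings + 1) // 2

    @property
    def neutral_center(self) -> int:
        """1-based index of the midpoint state of the neutral rating block."""
        first, last = rating_block(self, self.neutral_rating)
        return (first + last) // 2


def rating_block(spec: LatticeSpec, k: int) -> tuple[int, int]:
    """1-based inclusive state-index range ``(first, last)`` mapped to rating ``k``.

    Rating ``k`` owns the contiguous block
    ``(k-1)*states_per_rating + 1 .. k*states_per_rating``.
    """
    if not 1 <= k <= spec.n_ratings:
        raise ValueError(
            f"rating {k} out of range 1..{spec.n_ratings}"
        )
    first = (k - 1) * spec.states_per_rating + 1
    return first, k * spec.states_per_rating


@dataclass(frozen=True)
class Projector:
    """Diagonal 0/1 indicator of the states mapped to one rating.

    ``diag`` is the length-``N`` diagonal; the full matrix is available via
    :attr:`matrix`.  Applying the projector to a probability vector keeps
    the mass on the rating's block; applying it to an amplitude vector
    collapses the state onto that block (before renormalisation).
    """

    rating: int
    diag: np.ndarray = field(repr=False)

    @property
    def matrix(self) -> np.ndarray:
        return np.diag(self.diag)

    @property
    def trace(self) -> float:
        return float(self.diag.sum())

    def apply(self, vector: np.ndarray) -> np.ndarray:
        return self.diag * vector


def make_projector(spec: LatticeSpec, k: int) -> Projector:
    """Projector onto the evaluation states that report rating ``k``."""
    first, last = rating_block(spec, k)
    diag = np.zeros(spec.n_states)
    diag[first - 1 : last] = 1.0
    return Projector(rating=k, diag=diag)


@dataclass(frozen=True)
class InitialState:
    """Initial distribution over evaluation states at the start of a trial.

    ``kind`` is ``"probability"`` (Markov: entries sum to one) or
    ``"amplitude"`` (quantum: squared magnitudes sum to one).  The support
    is the ``states_per_rating`` consecutive states centred on the neutral
    midpoint state.
    """

    kind: str
    vector: np.ndarray = field(repr=False)


def initial_state(spec: LatticeSpec, kind: str = "probability") -> InitialState:
    """Uniform neutral start: equal weight on the neutral rating's block.

    For the default 9 x 11 lattice this puts ``1/11`` (probability) or
    ``sqrt(1/11)`` (amplitude, real and non-negative — the global phase is
    unobservable) on states 45..55 around the neutral midpoint state 50.
    """
    if kind not in ("probability", "amplitude"):
        raise ValueError(f"unknown initial-state kind {kind!r}")
    half = (spec.states_per_rating - 1) // 2
    center = spec.neutral_center
    vec = np.zeros(spec.n_states, dtype=float if kind == "probability" else complex)
    weight = 1.0 / spec.states_per_rating
    if kind == "amplitude":
        weight = np.sqrt(weight)
    vec[center - 1 - half : center + half] = weight
    return InitialState(kind=kind, vector=vec)
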