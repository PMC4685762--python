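"""Birth-death Markov random walk over the evaluation lattice.

The evaluation state evolves as a continuous-time birth-death chain with
reflecting boundaries.  Its generator (intensity matrix) ``K`` is
tridiagonal in the column-stochastic convention ``T[i, j] = p(i | j)``:

* superdiagonal ``K[i-1, i] = alpha`` — intensity of stepping one state
  *down* the lattice (towards "completely ineffective"),
* subdiagonal ``K[i+1, i] = beta`` — intensity of stepping one state *up*,
* diagonal ``-(alpha + beta)`` in the interior; the two boundary columns
  only lose the rate that actually exits (``-beta`` at state 1, ``-alpha``
  at state N), which is the conservative generator of the reflected chain.

So the mean drift of the rating is proportional to ``beta - alpha`` and the
diffusion to ``alpha + beta``.  The transition matrix solves the Kolmogorov
forward equation and equals ``expm(K * t)``; the processing time ``t`` is
fixed at 1 and absorbed into the intensities.

A trial answers two questions in sequence.  The state first evolves under
the transition matrix of the question asked first; observing rating ``j``
collapses (filters) the distribution onto rating ``j``'s block — the
anchor; the filtered, un-renormalised distribution then evolves under the
second question's transition matrix and is read out again.  Chaining the
two filters yields the joint probability of the rating pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .lattice import LatticeSpec, initial_state
from .prediction import ORDERS, JointTable

__all__ = [
    "MarkovParams",
    "build_intensity",
    "propagator",
    "markov_joint",
    "posterior_state",
]

#: Intensities above this produce a fully mixed chain at t=1 and only slow
#: the matrix exponential down; the fit treats them as out of bounds.
MAX_RATE = 1e6


@dataclass(frozen=True)
class MarkovParams:
    """Birth-death intensities for the self and other evaluation periods.

    ``alpha_*`` is the downward intensity, ``beta_*`` the upward intensity;
    both absorb the processing time of the question.  All four rates must
    be non-negative.
    """

    alpha_s: float
    beta_s: float
    alpha_o: float
    beta_o: float

    def __post_init__(self) -> None:
        for name in ("alpha_s", "beta_s", "alpha_o", "beta_o"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a non-negative finite rate, got {value}")


def build_intensity(spec: LatticeSpec, alpha: float, beta: float) -> np.ndarray:
    """Tridiagonal birth-death generator with reflecting boundaries.

    Every column sums to zero exactly.  ``alpha`` sits on the
    superdiagonal (down-steps), ``beta`` on the subdiagonal (up-steps).
    """
    if not np.isfinite(alpha) or alpha < 0 or not np.isfinite(beta) or beta < 0:
        raise ValueError(f"intensities must be non-negative, got alpha={alpha}, beta={beta}")
    n = spec.n_states
    K = np.zeros((n, n))
    idx = np.arange(n - 1)
    K[idx, idx + 1] = alpha
    K[idx + 1, idx] = beta
    # Diagonal = negative exit rate of each column, so columns sum to zero
    # exactly (no floating-point residue); the end columns keep only the
    # rate that actually exits — the reflecting boundary.
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


def propagator(K: np.ndarray, *, validate: bool = True) -> np.ndarray:
    """Column-stochastic transition matrix ``expm(K)`` at unit time."""
    K = np.asarray(K, dtype=float)
    if validate:
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("generator must be a square matrix")
        off = K - np.diag(np.diag(K))
        if np.any(off < -1e-12):
            raise ValueError("generator off-diagonal entries must be non-negative")
        col_sums = K.sum(axis=0)
        if np.max(np.abs(col_sums)) > 1e-8 * max(1.0, np.max(np.abs(K))):
            raise ValueError("generator columns must sum to zero")
    return expm(K)


def _transition_matrices(spec: LatticeSpec, params: MarkovParams) -> tuple[np.ndarray, np.ndarray]:
    t_self = propagator(build_intensity(spec, params.alpha_s, params.beta_s), validate=False)
    t_other = propagator(build_intensity(spec, params.alpha_o, params.beta_o), validate=False)
    return t_self, t_other


def markov_joint(spec: LatticeSpec, params: MarkovParams, order: str) -> JointTable:
    """Joint distribution of the two ratings for one question order.

    Cell ``(j, k)`` is the probability of rating ``j`` on the first
    question asked and ``k`` on the second: the initial distribution
    evolves under the first question's transition matrix, is filtered on
    rating ``j``'s block, evolves under the second question's matrix and is
    summed over rating ``k``'s block.  The filter is left un-renormalised
    so the chain rule gives joint rather than conditional probabilities.
    """
    if order not in ORDERS:
        raise ValueError(f"order must be one of {ORDERS}, got {order!r}")
    t_self, t_other = _transition_matrices(spec, params)
    t_first, t_second = (t_self, t_other) if order == "self_first" else (t_other, t_self)

    p0 = initial_state(spec, "probability").vector
    p1 = t_first @ p0
    m = spec.states_per_rating
    r = spec.n_ratings
    cells = np.empty((r, r))
    for j in range(r):
        filtered = np.zeros_like(p1)
        filtered[j * m : (j + 1) * m] = p1[j * m : (j + 1) * m]
        p2 = t_second @ filtered
        cells[j] = p2.reshape(r, m).sum(axis=1)
    total = cells.sum()
    if abs(total - 1.0) > 1e-6:
        raise RuntimeError(f"propagator lost stochasticity (cells sum to {total})")
    # expm at large intensities carries ~1e-10 round-off; renormalise.
    cells = np.maximum(cells, 0.0) / cells.sum()
    return JointTable(order=order, cells=cells, kind="probability", n=None)


def posterior_state(
    spec: LatticeSpec, params: MarkovParams, order: str, first_rating: int
) -> np.ndarray:
    """Normalised distribution over states right after the first answer.

    Diagnostic accessor: the anchor used by the second-question evolution,
    renormalised to a proper conditional distribution.
    """
    if order not in ORDERS:
        raise ValueError(f"order must be one of {ORDERS}, got {order!r}")
    t_self, t_other = _transition_matrices(spec, params)
    t_first = t_self if order == "self_first" else t_other
    p1 = t_first @ initial_state(spec, "probability").vector
    first, last = (first_rating - 1) * spec.states_per_rating, first_rating * spec.states_per_rating
    if not 1 <= first_rating <= spec.n_ratings:
        raise ValueError(f"rating {first_rating} out of range 1..{spec.n_ratings}")
    filtered = np.zeros_like(p1)
    filtered[first:last] = p1[first:last]
    total = filtered.sum()
    if total <= 0:
        raise ValueError(f"first rating {first_rating} has zero probability")
    return filtered / total
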