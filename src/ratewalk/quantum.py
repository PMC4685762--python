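"""Quantum walk over the evaluation lattice (tight-binding crystal model).

The judge's evaluation state is a complex amplitude vector over the same
lattice used by the Markov model.  Each question has its own orthonormal
basis; the unitary ``U = expm(-1j * H)`` built from that question's
Hamiltonian maps neutral-basis coordinates to question-basis coordinates
(``U[i, j]`` is the amplitude of question-state ``i`` given neutral state
``j``).  The Hamiltonian is tridiagonal: a constant off-diagonal coupling
``alpha`` lets amplitude diffuse to adjacent states, and a linear
potential ``beta * i / N`` on the diagonal exerts a constant force along
the lattice (negative ``beta`` pushes the packet towards the low end of
the scale).  The band simply truncates at the lattice ends; no boundary
modification is needed because unitarity is automatic.  Processing time is
absorbed into ``alpha`` and ``beta``.

Sequential measurement works by projection and basis change: the first
question's unitary is applied, the amplitude is collapsed onto the block
of the observed rating, the result is carried back to the neutral basis
with the inverse unitary, transformed into the second question's basis,
and projected again.  Because the two questions use different bases the
joint distribution depends on the order — the model's account of
question-order effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .lattice import LatticeSpec, initial_state
from .prediction import ORDERS, JointTable

__all__ = [
    "QuantumParams",
    "build_hamiltonian",
    "unitary",
    "quantum_joint",
    "basis_change_kernel",
]


@dataclass(frozen=True)
class QuantumParams:
    """Hamiltonian parameters for the self and other questions.

    ``alpha_*`` is the off-diagonal coupling (diffusion of amplitude),
    ``beta_*`` the endpoint value of the linear diagonal potential (its
    sign sets the direction of the constant force).  Any finite real
    values are admissible.
    """

    alpha_s: float
    beta_s: float
    alpha_o: float
    beta_o: float

    def __post_init__(self) -> None:
        for name in ("alpha_s", "beta_s", "alpha_o", "beta_o"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be a finite real number")


def build_hamiltonian(spec: LatticeSpec, alpha: float, beta: float) -> np.ndarray:
    """Real symmetric tridiagonal Hamiltonian with a linear potential.

    Off-diagonals are all ``alpha``; the diagonal is ``beta * i / N`` for
    1-based state index ``i`` (1-based indexing matches the lattice's
    state labels; shifting the whole diagonal by a constant only changes
    an unobservable global phase).
    """
    if not np.isfinite(alpha) or not np.isfinite(beta):
        raise ValueError("Hamiltonian parameters must be finite")
    n = spec.n_states
    H = np.zeros((n, n))
    i = np.arange(1, n + 1)
    np.fill_diagonal(H, beta * i / n)
    idx = np.arange(n - 1)
    H[idx, idx + 1] = alpha
    H[idx + 1, idx] = alpha
    return H


def unitary(H: np.ndarray) -> np.ndarray:
    """Unitary propagator ``expm(-1j * H)`` at unit time.

    Computed from the spectral decomposition of the Hermitian ``H``,
    which is exactly unitary up to round-off.
    """
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("Hamiltonian must be a square matrix")
    if np.max(np.abs(H - H.conj().T)) > 1e-10 * max(1.0, np.max(np.abs(H))):
        raise ValueError("Hamiltonian must be Hermitian")
    eigvals, eigvecs = np.linalg.eigh(H)
    return (eigvecs * np.exp(-1j * eigvals)) @ eigvecs.conj().T


def _tridiagonal_unitary(spec: LatticeSpec, alpha: float, beta: float) -> np.ndarray:
    # Fast path used by the joint: eigendecomposition of the symmetric
    # tridiagonal Hamiltonian without materialising it.
    n = spec.n_states
    diag = beta * np.arange(1, n + 1) / n
    off = np.full(n - 1, float(alpha))
    if alpha == 0.0:
        return np.diag(np.exp(-1j * diag))
    eigvals, eigvecs = eigh_tridiagonal(diag, off)
    return (eigvecs * np.exp(-1j * eigvals)) @ eigvecs.T


def quantum_joint(spec: LatticeSpec, params: QuantumParams, order: str) -> JointTable:
    """Joint distribution of the two ratings for one question order.

    Cell ``(i, j)``: apply the first question's unitary to the initial
    amplitude, project onto rating ``i``'s block, return to the neutral
    basis with the inverse unitary, apply the second question's unitary,
    project onto rating ``j``'s block, and take the squared norm.  The
    projected amplitude is left un-renormalised so squared norms are joint
    probabilities; completeness of the projectors and unitarity make the
    81 cells sum to one.
    """
    if order not in ORDERS:
        raise ValueError(f"order must be one of {ORDERS}, got {order!r}")
    u_self = _tridiagonal_unitary(spec, params.alpha_s, params.beta_s)
    u_other = _tridiagonal_unitary(spec, params.alpha_o, params.beta_o)
    u_first, u_second = (u_self, u_other) if order == "self_first" else (u_other, u_self)

    psi0 = initial_state(spec, "amplitude").vector
    psi1 = u_first @ psi0
    # Basis change through neutral: U_second @ U_first^dagger.
    change = u_second @ u_first.conj().T
    m = spec.states_per_rating
    r = spec.n_ratings
    cells = np.empty((r, r))
    for i in range(r):
        collapsed = np.zeros_like(psi1)
        collapsed[i * m : (i + 1) * m] = psi1[i * m : (i + 1) * m]
        psi2 = change @ collapsed
        cells[i] = (np.abs(psi2) ** 2).reshape(r, m).sum(axis=1)
    return JointTable(order=order, cells=cells, kind="probability", n=None)


def basis_change_kernel(spec: LatticeSpec, params: QuantumParams) -> np.ndarray:
    """Squared-magnitude transition kernel between the two question bases.

    Entry ``(i, j)`` is ``|<G_i|F_j>|**2``, the probability of other-state
    ``i`` given self-state ``j``.  Unlike the Markov transition matrix this
    kernel is doubly stochastic: both rows and columns sum to one.
    """
    u_self = _tridiagonal_unitary(spec, params.alpha_s, params.beta_s)
    u_other = _tridiagonal_unitary(spec, params.alpha_o, params.beta_o)
    return np.abs(u_other @ u_self.conj().T) ** 2
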