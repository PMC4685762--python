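"""Independent reference implementations used only by the tests.

Everything here recomputes quantities through a different route than the
package (explicit matrix products, alternative matrix-exponential
algorithms, event-driven simulation) so agreement is informative.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def generator_matrix(n: int, alpha: float, beta: float) -> np.ndarray:
    """Birth-death generator assembled entry by entry (column convention).

    ``alpha`` is the intensity of the step towards state 1, ``beta``
    towards state n; reflecting boundaries.
    """
    K = np.zeros((n, n))
    for j in range(n):  # from-state (column)
        if j > 0:
            K[j - 1, j] = alpha
        if j < n - 1:
            K[j + 1, j] = beta
        K[j, j] = -(alpha * (j > 0) + beta * (j < n - 1))
    return K


def expm_symmetrized(K: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Matrix exponential of a birth-death generator via symmetrisation.

    ``D K D^{-1}`` with ``D = diag((alpha/beta)^{i/2})`` is symmetric
    tridiagonal, so ``expm(K) = D^{-1} V exp(L) V^T D`` from its
    eigendecomposition — an independent alternative to Pade/squaring.
    Requires strictly positive rates of comparable size.
    """
    n = K.shape[0]
    log_c = 0.5 * (np.log(alpha) - np.log(beta))
    d = np.exp(log_c * np.arange(n))
    S = (d[:, None] * K) / d[None, :]
    S = (S + S.T) / 2
    eigvals, eigvecs = np.linalg.eigh(S)
    E = (eigvecs * np.exp(eigvals)) @ eigvecs.T
    return (E / d[:, None]) * d[None, :]


def gillespie_transition_matrix(
    n: int,
    alpha: float,
    beta: float,
    t: float,
    n_traj: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical transition matrix of the reflected birth-death chain.

    Event-driven simulation: from every start state, ``n_traj``
    trajectories are run to time ``t`` by drawing exponential waiting
    times and jump directions.  Returns (transition frequency matrix,
    Monte-Carlo standard error matrix), both column-indexed by the start
    state like the analytic propagator.
    """
    rng = np.random.default_rng(seed)
    freq = np.zeros((n, n))
    se = np.zeros((n, n))
    for start in range(n):
        state = np.full(n_traj, start)
        now = np.zeros(n_traj)
        active = np.ones(n_traj, dtype=bool)
        while active.any():
            idx = np.nonzero(active)[0]
            s = state[idx]
            rate_down = np.where(s > 0, alpha, 0.0)
            rate_up = np.where(s < n - 1, beta, 0.0)
            total = rate_down + rate_up
            stuck = total <= 0
            wait = np.full(idx.shape, np.inf)
            wait[~stuck] = rng.exponential(1.0 / total[~stuck])
            arrived = now[idx] + wait
            done = arrived >= t
            go = ~done
            move_down = rng.random(go.sum()) * total[go] < rate_down[go]
            state[idx[go]] = s[go] + np.where(move_down, -1, 1)
            now[idx[go]] = arrived[go]
            active[idx[done]] = False
        counts = np.bincount(state, minlength=n).astype(float)
        p = counts / n_traj
        freq[:, start] = p
        se[:, start] = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_traj)
    return freq, se


def brute_markov_joint(
    n_ratings: int,
    states_per_rating: int,
    alpha_s: float,
    beta_s: float,
    alpha_o: float,
    beta_o: float,
    order: str,
) -> np.ndarray:
    """Joint rating table by explicit full-matrix products.

    Builds the projector matrices densely and evaluates
    ``L M_k T2 M_j T1 p0`` cell by cell with scipy's expm.
    """
    n = n_ratings * states_per_rating
    t_s = scipy.linalg.expm(generator_matrix(n, alpha_s, beta_s))
    t_o = scipy.linalg.expm(generator_matrix(n, alpha_o, beta_o))
    t1, t2 = (t_s, t_o) if order == "self_first" else (t_o, t_s)
    p0 = np.zeros(n)
    center = (n_ratings // 2) * states_per_rating + (states_per_rating + 1) // 2  # 1-based
    half = (states_per_rating - 1) // 2
    p0[center - 1 - half : center + half] = 1.0 / states_per_rating
    ones = np.ones(n)
    projectors = []
    for k in range(n_ratings):
        m = np.zeros((n, n))
        for i in range(k * states_per_rating, (k + 1) * states_per_rating):
            m[i, i] = 1.0
        projectors.append(m)
    joint = np.zeros((n_ratings, n_ratings))
    for j in range(n_ratings):
        for k in range(n_ratings):
            joint[j, k] = ones @ (projectors[k] @ (t2 @ (projectors[j] @ (t1 @ p0))))
    return joint


def brute_quantum_joint(
    n_ratings: int,
    states_per_rating: int,
    alpha_s: float,
    beta_s: float,
    alpha_o: float,
    beta_o: float,
    order: str,
) -> np.ndarray:
    """Joint rating table via expm(-iH) and explicit projector products."""
    n = n_ratings * states_per_rating

    def hamiltonian(alpha, beta):
        H = np.zeros((n, n))
        for i in range(n):
            H[i, i] = beta * (i + 1) / n
            if i + 1 < n:
                H[i, i + 1] = alpha
                H[i + 1, i] = alpha
        return H

    u_s = scipy.linalg.expm(-1j * hamiltonian(alpha_s, beta_s))
    u_o = scipy.linalg.expm(-1j * hamiltonian(alpha_o, beta_o))
    u1, u2 = (u_s, u_o) if order == "self_first" else (u_o, u_s)
    psi0 = np.zeros(n, dtype=complex)
    center = (n_ratings // 2) * states_per_rating + (states_per_rating + 1) // 2
    half = (states_per_rating - 1) // 2
    psi0[center - 1 - half : center + half] = np.sqrt(1.0 / states_per_rating)
    projectors = []
    for k in range(n_ratings):
        m = np.zeros((n, n))
        for i in range(k * states_per_rating, (k + 1) * states_per_rating):
            m[i, i] = 1.0
        projectors.append(m)
    joint = np.zeros((n_ratings, n_ratings))
    for i in range(n_ratings):
        for j in range(n_ratings):
            amp = projectors[j] @ (u2 @ (u1.conj().T @ (projectors[i] @ (u1 @ psi0))))
            joint[i, j] = float(np.vdot(amp, amp).real)
    return joint
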