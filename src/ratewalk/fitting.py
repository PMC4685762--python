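"""Parameter estimation for both walk models.

Two objectives are supported, mirroring how such models are compared on
order-conditioned joint rating tables:

* **SSE** — sum of squared differences between observed relative
  frequencies and predicted probabilities over all cells of the supplied
  tables, summarised as ``R^2 = 1 - SSE/TSS`` with the total sum of
  squares taken around each table's own mean cell value.
* **likelihood** — multinomial log-likelihood of the observed counts,
  summarised as the ``G^2`` lack-of-fit statistic against the saturated
  model (one free probability per cell per table),
  ``G^2 = 2 * sum n_cell * ln(p_hat / p_model)``.

Counts reconstructed from tables printed as integer percentages are
fractional; they enter the log-likelihood as multinomial weights, so the
resulting ``G^2`` approximates what the raw data would give.

The optimizer is a multi-start Nelder-Mead simplex.  Because the quantum
objective oscillates in the coupling parameters, starting points combine
two sources: (i) a large Latin hypercube over documented ranges,
screened by a single objective evaluation, and (ii) profile starts
obtained by first fitting each question's ``(alpha, beta)`` (with the
mixture weight) to the first-question marginal of its table — a cheap
low-dimensional subproblem, since the marginal of the question asked
first is unaffected by the second question's parameters.  The simplex is
run from the best ``restarts`` candidates and the winner is polished
with a second simplex run.  Markov intensities are searched in log space
(keeping them positive), the mixture weight through a logistic transform
(keeping it in [0, 1]), and quantum parameters untransformed.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .lattice import LatticeSpec
from .markov import MAX_RATE, MarkovParams, markov_joint
from .prediction import JointTable, apply_mixture
from .quantum import QuantumParams, quantum_joint

__all__ = [
    "FitOptions",
    "FitResult",
    "predict_tables",
    "sse_objective",
    "g2_statistic",
    "saturated_log_likelihood",
    "fit",
]

MODELS = ("markov", "quantum")
OBJECTIVES = ("sse", "likelihood")

#: Probabilities below this are floored before entering a log.
PROB_FLOOR = 1e-12

_PENALTY = 1e9


def predict_tables(
    model: str,
    params: MarkovParams | QuantumParams,
    mixture: float,
    orders: Sequence[str],
    spec: LatticeSpec | None = None,
) -> tuple[JointTable, ...]:
    """Mixture-adjusted model joint tables for the requested orders."""
    spec = spec or LatticeSpec()
    joint = markov_joint if model == "markov" else quantum_joint
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return tuple(apply_mixture(joint(spec, params, o), mixture) for o in orders)


def _check_aligned(obs: Sequence[JointTable], pred: Sequence[JointTable]) -> None:
    if len(obs) != len(pred):
        raise ValueError("observed and predicted table lists differ in length")
    for o, p in zip(obs, pred):
        if o.order != p.order:
            raise ValueError(f"order mismatch: observed {o.order}, predicted {p.order}")
        if o.cells.shape != p.cells.shape:
            raise ValueError("observed and predicted tables differ in shape")


def sse_objective(
    obs: Sequence[JointTable], pred: Sequence[JointTable]
) -> tuple[float, float]:
    """Sum of squared errors and ``R^2`` over one or more table pairs.

    All tables must be on the proportion scale; TSS is computed around the
    mean cell value of each observed table separately, so ``R^2 = 0``
    corresponds to predicting every cell at its table's mean.
    """
    _check_aligned(obs, pred)
    sse = 0.0
    tss = 0.0
    for o, p in zip(obs, pred):
        if o.kind == "count" or p.kind == "count":
            raise ValueError(
                "sse_objective expects proportion-scale tables, not counts"
            )
        oc = o.as_probability().cells
        pc = p.as_probability().cells
        sse += float(((oc - pc) ** 2).sum())
        tss += float(((oc - oc.mean()) ** 2).sum())
    return sse, 1.0 - sse / tss


def saturated_log_likelihood(obs_counts: Sequence[JointTable]) -> float:
    """Log-likelihood of the per-table saturated model (``p_hat = n_cell / n``)."""
    total = 0.0
    for table in obs_counts:
        c = table.to_counts().cells
        n = c.sum()
        mask = c > 0
        total += float((c[mask] * np.log(c[mask] / n)).sum())
    return total


def g2_statistic(
    obs_counts: Sequence[JointTable], pred: Sequence[JointTable]
) -> float:
    """``G^2`` lack of fit of model probabilities against observed counts.

    Cells with zero observed count contribute nothing; model probabilities
    are floored at :data:`PROB_FLOOR`, and a model probability of exactly
    zero on a cell with positive count yields ``inf``.
    """
    _check_aligned(obs_counts, pred)
    g2 = 0.0
    for o, p in zip(obs_counts, pred):
        c = o.to_counts().cells
        n = c.sum()
        if n <= 0:
            raise ValueError("count table has zero total")
        probs = p.as_probability().cells
        mask = c > 0
        if np.any(probs[mask] <= 0):
            return float("inf")
        probs = np.maximum(probs, PROB_FLOOR)
        g2 += 2.0 * float((c[mask] * np.log((c[mask] / n) / probs[mask])).sum())
    return g2


@dataclass(frozen=True)
class FitOptions:
    """Multi-start optimizer settings.

    Start ranges follow the scales on which the two models live: Markov
    intensities are drawn log-uniformly from ``rate_range``, quantum
    couplings uniformly from ``coupling_range``, potential slopes from
    ``potential_range`` and the mixture weight from ``mixture_range``.
    """

    restarts: int = 20
    seed: int = 20160113
    maxiter: int = 1000
    #: Latin-hypercube candidates screened (one evaluation each) to pick
    #: the simplex starting points; at least ``restarts``.
    screen: int = 200
    #: Basin-hopping rounds after the restart stage: seeded perturbations
    #: of the incumbent, accepted only on improvement.
    hops: int = 12
    #: Use per-question marginal fits to seed the simplex (disable for
    #: quick fits where restart noise is acceptable).
    profile: bool = True
    include_mixture: bool = True
    rate_range: tuple[float, float] = (1.0, 1000.0)
    coupling_range: tuple[float, float] = (1.0, 300.0)
    potential_range: tuple[float, float] = (-100.0, 100.0)
    mixture_range: tuple[float, float] = (0.5, 1.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a model fit."""

    model: str
    objective: str
    params: MarkovParams | QuantumParams
    mixture: float
    objective_value: float
    statistic_name: str
    statistic: float
    n_restarts: int
    converged: bool
    seed: int
    n_evaluations: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "objective": self.objective,
            "alpha_s": self.params.alpha_s,
            "beta_s": self.params.beta_s,
            "alpha_o": self.params.alpha_o,
            "beta_o": self.params.beta_o,
            "mixture": self.mixture,
            "objective_value": self.objective_value,
            self.statistic_name: self.statistic,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
        }
        return d

    def report(self) -> str:
        lines = [f"{self.model} model fitted by {self.objective}"]
        lines += [f"  {k} = {v}" for k, v in self.to_dict().items() if k not in ("model", "objective")]
        return "\n".join(lines)


def _unpack(model: str, z: np.ndarray, include_mixture: bool):
    """Map an unconstrained optimizer vector to (params, mixture, penalty)."""
    if model == "markov":
        if np.any(z[:4] > np.log(MAX_RATE)):
            return None, None, _PENALTY * (1.0 + float(np.sum(np.maximum(z[:4] - np.log(MAX_RATE), 0.0))))
        params = MarkovParams(*np.exp(z[:4]))
    else:
        if np.any(np.abs(z[:4]) > 1e4):
            return None, None, _PENALTY * (1.0 + float(np.sum(np.maximum(np.abs(z[:4]) - 1e4, 0.0))))
        params = QuantumParams(*z[:4])
    lam = float(expit(z[4])) if include_mixture and len(z) > 4 else 1.0
    return params, lam, 0.0


def _starts(model: str, opts: FitOptions) -> np.ndarray:
    dim = 5 if opts.include_mixture else 4
    sampler = qmc.LatinHypercube(d=dim, seed=opts.seed)
    u = sampler.random(max(opts.screen, opts.restarts))
    starts = np.empty_like(u)
    if model == "markov":
        lo, hi = np.log(opts.rate_range[0]), np.log(opts.rate_range[1])
        starts[:, :4] = lo + u[:, :4] * (hi - lo)
    else:
        a_lo, a_hi = opts.coupling_range
        b_lo, b_hi = opts.potential_range
        starts[:, 0] = a_lo + u[:, 0] * (a_hi - a_lo)
        starts[:, 2] = a_lo + u[:, 2] * (a_hi - a_lo)
        starts[:, 1] = b_lo + u[:, 1] * (b_hi - b_lo)
        starts[:, 3] = b_lo + u[:, 3] * (b_hi - b_lo)
    if opts.include_mixture:
        m_lo, m_hi = opts.mixture_range
        lam = m_lo + u[:, 4] * (m_hi - m_lo)
        starts[:, 4] = logit(np.clip(lam, 1e-6, 1 - 1e-6))
    return starts


def _first_question_marginal(model: str, spec: LatticeSpec, alpha: float, beta: float) -> np.ndarray:
    """Distribution of the first answer; depends only on that question's parameters."""
    if model == "markov":
        from .markov import build_intensity, propagator
        from .lattice import initial_state

        p1 = propagator(build_intensity(spec, alpha, beta), validate=False) @ initial_state(
            spec, "probability"
        ).vector
        return p1.reshape(spec.n_ratings, spec.states_per_rating).sum(axis=1)
    from .quantum import _tridiagonal_unitary
    from .lattice import initial_state

    psi1 = _tridiagonal_unitary(spec, alpha, beta) @ initial_state(spec, "amplitude").vector
    return (np.abs(psi1) ** 2).reshape(spec.n_ratings, spec.states_per_rating).sum(axis=1)


def _profile_starts(
    model: str,
    obs: Sequence[JointTable],
    opts: FitOptions,
    spec: LatticeSpec,
) -> list[np.ndarray]:
    """Candidate full starts built from per-question marginal fits.

    For each observed table, fit ``(alpha, beta, lambda)`` of the first
    question to the table's first-answer marginal by least squares with a
    small screened multi-start; combine the best solutions per question
    role into full parameter vectors.  Questions without a marginal
    anchor (the second question of a single-table fit) reuse the other
    question's solutions.
    """
    mid = (spec.n_ratings + 1) // 2 - 1
    per_role: dict[str, list[np.ndarray]] = {}
    for table in obs:
        target = table.as_probability().cells.sum(axis=1)
        role = "self" if table.order == "self_first" else "other"

        def marginal_sse(z: np.ndarray) -> float:
            if model == "markov":
                if np.any(z[:2] > np.log(MAX_RATE)):
                    return _PENALTY
                alpha, beta = np.exp(z[:2])
            else:
                if np.any(np.abs(z[:2]) > 1e4):
                    return _PENALTY
                alpha, beta = z[:2]
            lam = float(expit(z[2]))
            marg = lam * _first_question_marginal(model, spec, alpha, beta)
            marg[mid] += 1.0 - lam
            return float(((marg - target) ** 2).sum())

        # Deterministic coarse grid: the marginal objective oscillates in
        # the coupling, so cover it densely before descending.
        if model == "markov":
            lo, hi = np.log(opts.rate_range[0]), np.log(opts.rate_range[1])
            a_grid = b_grid = np.linspace(lo, hi, 14)
        else:
            a_grid = np.linspace(opts.coupling_range[0] + 4, opts.coupling_range[1], 25)
            b_grid = np.linspace(opts.potential_range[0] + 10, opts.potential_range[1] - 10, 9)
        lam_grid = logit(np.array([0.8, 0.95]))
        cand = np.array(
            [(a, b, l) for a in a_grid for b in b_grid for l in lam_grid]
        )
        scores = np.array([marginal_sse(z) for z in cand])
        ranked = cand[np.argsort(scores, kind="stable")]
        # Descend from the best candidates that are mutually distinct in
        # the first coordinate, keeping several distinct solutions.
        solutions: list[tuple[float, np.ndarray]] = []
        seen: list[float] = []
        spread = (a_grid[-1] - a_grid[0]) / 12
        for z0 in ranked:
            if any(abs(z0[0] - s) < spread for s in seen):
                continue
            seen.append(z0[0])
            res = minimize(
                marginal_sse, z0, method="Nelder-Mead", options=dict(maxiter=400, xatol=1e-5, fatol=1e-12)
            )
            solutions.append((res.fun, res.x))
            if len(solutions) >= 8:
                break
        solutions.sort(key=lambda item: item[0])
        distinct: list[np.ndarray] = []
        for _, x in solutions:
            if all(abs(x[0] - d[0]) > spread / 2 for d in distinct):
                distinct.append(x)
            if len(distinct) >= 3:
                break
        per_role[role] = distinct

    if not per_role:
        return []
    self_sols = per_role.get("self") or per_role.get("other")
    other_sols = per_role.get("other") or per_role.get("self")
    starts = []
    for zs in self_sols:
        for zo in other_sols:
            z = np.array([zs[0], zs[1], zo[0], zo[1], (zs[2] + zo[2]) / 2.0])
            starts.append(z if opts.include_mixture else z[:4])
    return starts


def fit(
    model: str,
    objective: str,
    obs: Sequence[JointTable] | JointTable,
    options: FitOptions | None = None,
    spec: LatticeSpec | None = None,
) -> FitResult:
    """Fit a model's parameters to one or two order-conditioned tables.

    ``obs`` may be a single table (single-order fit) or a sequence of
    tables with distinct orders; the objective sums over all of them.
    SSE fits use proportion-scale tables; likelihood fits need counts (or
    tables carrying a sample size ``n`` from which counts are formed).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}, got {objective!r}")
    opts = options or FitOptions()
    spec = spec or LatticeSpec()
    if isinstance(obs, JointTable):
        obs = (obs,)
    obs = tuple(obs)
    if not obs:
        raise ValueError("at least one observed table is required")
    orders = [t.order for t in obs]
    if objective == "sse":
        obs_eval = tuple(t.as_probability() for t in obs)
    else:
        obs_eval = tuple(t.to_counts() for t in obs)

    n_evals = 0

    def objective_fn(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        params, lam, penalty = _unpack(model, z, opts.include_mixture)
        if penalty:
            return penalty
        pred = predict_tables(model, params, lam, orders, spec)
        if objective == "sse":
            return sse_objective(obs_eval, pred)[0]
        value = g2_statistic(obs_eval, pred)
        return value if np.isfinite(value) else _PENALTY

    fatol = 1e-12 if objective == "sse" else 1e-5
    nm_options = dict(maxiter=opts.maxiter, xatol=1e-5, fatol=fatol)
    # Profile starts always get a simplex run; the screened hypercube
    # fills the remaining restart budget.
    profile = _profile_starts(model, obs_eval, opts, spec) if opts.profile else []
    lhs = list(_starts(model, opts))
    scores = np.array([objective_fn(z) for z in lhs])
    chosen = profile + [lhs[i] for i in np.argsort(scores, kind="stable")[: opts.restarts]]
    best = None
    any_success = False
    for z0 in chosen:
        result = minimize(objective_fn, z0, method="Nelder-Mead", options=nm_options)
        any_success = any_success or bool(result.success)
        if best is None or result.fun < best.fun:
            best = result
    # Basin hopping: the quantum objective has narrow isolated basins, so
    # perturb the incumbent and descend again, keeping improvements only.
    if model == "markov":  # perturbations act on log-rates
        step = np.array([0.6, 0.6, 0.6, 0.6, 0.3])
    else:
        step = np.array([25.0, 6.0, 25.0, 6.0, 0.3])
    hop_rng = np.random.default_rng(opts.seed + 977)
    for _ in range(opts.hops):
        z = best.x + hop_rng.normal(0.0, step[: best.x.size])
        result = minimize(objective_fn, z, method="Nelder-Mead", options=nm_options)
        any_success = any_success or bool(result.success)
        if result.fun < best.fun:
            best = result
    # Polish the winner from its own optimum.
    polish = minimize(objective_fn, best.x, method="Nelder-Mead", options=nm_options)
    if polish.fun < best.fun:
        best = polish
    any_success = any_success or bool(polish.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimizer starts failed to produce a finite objective")

    params, lam, _ = _unpack(model, best.x, opts.include_mixture)
    pred = predict_tables(model, params, lam, orders, spec)
    if objective == "sse":
        value, r2 = sse_objective(obs_eval, pred)
        statistic_name, statistic = "r2", r2
    else:
        value = g2_statistic(obs_eval, pred)
        statistic_name, statistic = "g2", value
    return FitResult(
        model=model,
        objective=objective,
        params=params,
        mixture=lam,
        objective_value=float(value),
        statistic_name=statistic_name,
        statistic=float(statistic),
        n_restarts=opts.restarts,
        converged=any_success,
        seed=opts.seed,
        n_evaluations=n_evals,
        diagnostics={"orders": orders, "best_message": str(best.message)},
    )
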