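# Methods

## The modelling problem

A judge rates the same stimulus twice in a row — "how effective is this
message for you?" and "how effective is it for your friends?" — on a
9-point scale, with the order of the two questions randomised per trial.
Empirically the pair of answers depends on the order; in particular the
self-other gap is larger when self is asked first.  `ratewalk` implements
two competing process models of this situation and the machinery to fit
and compare them on order-conditioned 9 x 9 joint rating tables.

Both models share the measurement assumptions:

* an internal lattice of `N = n_ratings x states_per_rating` evaluation
  states ordered from "completely ineffective" to "completely effective"
  (default 9 x 11 = 99; `states_per_rating` odd so each rating block has a
  midpoint);
* rating `k` is read out by a projector `M_k` onto the block of
  `states_per_rating` consecutive states assigned to it;
* the trial starts in a uniform distribution (or uniform real amplitude)
  over the `states_per_rating` states centred on the lattice midpoint —
  the neutral window, which coincides with rating 5's block;
* answering the first question collapses the state onto the observed
  rating's block (un-renormalised, so chained readouts give joint
  probabilities), and the collapsed state is the anchor from which the
  second evaluation proceeds.

## Markov birth-death walk

The evaluation state performs a continuous-time birth-death walk with
reflecting boundaries.  In the column-stochastic convention
`T[i, j] = p(i | j)`, the generator `K` has `alpha` on the superdiagonal
and `beta` on the subdiagonal; the interior diagonal is `-(alpha + beta)`
and the two end columns keep only the rate that actually exits.  `alpha`
is therefore the intensity of *down*-steps and `beta` of *up*-steps: the
mean drift of the rating is proportional to `beta - alpha`, the diffusion
to `alpha + beta`.  (Conventions differ across the literature; this
orientation is the one under which the published parameter estimates for
the bundled data reproduce the published fit quality and mean ratings —
with the opposite orientation they produce means on the wrong side of the
scale midpoint and near-zero R².)  The transition matrix is
`expm(K t)` with `t = 1`; the processing time is absorbed into the
intensities, so each question contributes two free parameters,
`(alpha_S, beta_S)` and `(alpha_O, beta_O)`.  Both questions share one
basis, so the second evaluation continues directly from the collapsed
distribution.

## Quantum walk

The quantum model keeps the same lattice but gives each question its own
basis.  A question's unitary is `U = expm(-i H)` with a tridiagonal
Hamiltonian: constant off-diagonal coupling `alpha` (amplitude diffusion)
and a linear potential `beta * i / N` on the diagonal (constant force;
the sign of `beta` sets its direction; adding a constant to the diagonal
is an unobservable global phase, so 0- versus 1-based indexing of the
potential does not matter).  After the first answer collapses the
amplitude in the first question's basis, the state is carried back to the
neutral basis with `U_1^dagger` and into the second question's basis with
`U_2`; probabilities are squared norms of the doubly projected amplitude.
The squared-magnitude kernel `|U_O U_S^dagger|^2` between the two
question bases is doubly stochastic — a signature that separates the
quantum from the Markov transition kernel (column-stochastic only).
Complex arithmetic is kept throughout; with a real Hamiltonian and real
initial amplitudes the sign of the exponent in `expm(±iH)` is
unobservable (complex conjugation).

## Non-judgemental mixture

Some trials skip the evaluation and report the scale midpoint for both
questions.  With probability `lambda` the walk model generates the rating
pair; with probability `1 - lambda` the pair is (5, 5).  One shared
`lambda` applies to both question orders, giving each model 5 free
parameters.

## Table conventions

In memory, a `JointTable`'s rows always index the rating of the question
asked *first*.  Published tables conventionally print self ratings on the
rows for *both* orders, so the bundled other-first fixtures declare
`rows: self` and are transposed on reading.  This matters: under the
transposed reading the published quantum predictions match 80 of 81
rounded cells in each table and the published parameters reproduce
R² = 0.902 ≈ 0.90, while the untransposed reading gives 54/81 and 0.878.
The question-order test compares the joint distribution of (self, other)
pairs across orders, so it re-aligns the other-first table (transposing
it back) before pooling.

## Estimation

* **SSE / R²** — sum of squared differences between observed relative
  frequencies and predicted probabilities over all cells of the supplied
  tables; `R² = 1 - SSE/TSS` with TSS around each table's own mean cell
  value (1/81 for a normalised table).
* **Likelihood / G²** — multinomial log-likelihood of the observed
  counts; reported as the lack-of-fit statistic
  `G² = 2 Σ n_cell ln(p̂_cell / p_model)` against the per-table saturated
  model.  Model probabilities are floored at 1e-12; zero-count cells
  contribute nothing.  The saturated model has `2(81 - 1) = 160` free
  parameters for two tables (sometimes book-kept as 180 including the two
  constrained totals); the G² value itself does not depend on that
  bookkeeping.

The optimizer is multi-start Nelder-Mead over transformed parameters
(log intensities for the Markov model, logit mixture weight, raw quantum
parameters).  The quantum SSE surface oscillates in the couplings —
isolated deep basins of width ~10 in `alpha` — so plain random restarts
are unreliable.  Starting points therefore combine (i) a 200-point Latin
hypercube over documented ranges (intensities 1-1000 log-uniform,
couplings 1-300, potential endpoints -100-100, mixture 0.5-1), screened
by one objective evaluation, and (ii) profile starts: each question's
`(alpha, beta, lambda)` is first fitted to its table's *first-answer
marginal* — a cheap 3-parameter subproblem, exact in the sense that the
first marginal is unaffected by the second question's parameters,
searched over a deterministic coarse grid before descending — and the
distinct per-question solutions are combined into full starting vectors.
The simplex (maxiter 1000, xatol 1e-5) runs from every profile start
plus the best 20 hypercube candidates; 12 seeded basin-hopping rounds
(perturb the incumbent, descend, keep improvements) then jump between
neighbouring basins, and the winner is polished once more.  On the
bundled tables this pipeline reaches the published quantum optimum
(R² 0.903 at parameters within 2 units of the published estimates)
independently of the seed.  All draws are seeded; fits are
bit-reproducible.  An objective evaluation costs two 99 x 99 matrix
exponentials (~2 ms: scaling-and-squaring for the generator, tridiagonal
eigendecomposition for the Hamiltonian), so a full fit takes one to three
minutes on one core.  Intensities above 1e6 (fully mixed within a
trial) and quantum parameters above 1e4 in magnitude are rejected with a
penalty.

## Question-order test

Saturated model: one probability per cell per order-conditioned table
(160 free parameters).  Restricted model: one shared (self, other) joint
distribution (80), MLE = pooled proportions.
`G² = -2[lnL(restricted) - lnL(saturated)]` is referred to chi-square
with 80 degrees of freedom.  The chi-square reference assumes independent
observations; trials pooled over participants and stimuli violate this,
which the result object records as a caveat rather than correcting.

**Calibration caveat.**  At the study's own per-order sample sizes
(775/797 spread over 81 cells) the G²-vs-χ²₈₀ approximation is
anti-conservative under *any* null — the least-sparse possible null
(uniform, expected count 9.7 per cell) yields an empirical type-I rate of
about 0.069 at the nominal 0.05 level over 2000 replicates, and
realistic smoothed-data nulls 0.09-0.16.  At five times those sample
sizes the test calibrates (0.050 measured); the module test suite asserts
that convergence property, and the acceptance suite documents the
miscalibration at the study's n as an expected failure.

## Reproducing published statistics from rounded tables

The bundled observed tables are printed as integer percentages.  Squared
-error statistics are barely affected (R² at the published quantum SSE
estimates: 0.902 vs the published 0.90), but G²-type statistics weight
every cell by `n ln(p̂/p)` and are hypersensitive to per-mille
perturbations across 162 cells.  Recomputed from the rounded tables:
order-effect G² = 189.9 (published raw-count value 110.19), Markov
G² = 1567 (published 1190), quantum G² = 956 (published 839).  Minimising
each statistic over all raw tables consistent with the printed rounding
(a convex program over the rounding polytope) gives 10.4, 882 and 427
respectively — the published values lie comfortably inside the feasible
intervals, so the implementation is consistent with the published
analysis and the gaps are attributable to rounding alone.  Corroborating
this, refitting the quantum model by G² on the reconstructed counts
converges to essentially the published maximum-likelihood estimates
(114.4, -14.2, 92.4, -16.7, lambda 0.91).  The package reports the
honestly recomputed values without adjustment.

## Synthetic experiments

`synthetic.simulate_experiment` emulates the reference design: 131
participants x 12 stimuli, per-trial question order Bernoulli(0.5), and
each rating pair one draw from the generating model's mixture-adjusted
joint table for that trial's order.  Participants are homogeneous and the
stimulus id carries no effect, because the models under study pool all
trials; consequently, passing recovery tests says nothing about
participant or stimulus heterogeneity in real data, only about the
pooled-table pipeline.  One seeded stream per experiment: order draws
first, then one uniform per trial through the order-specific inverse CDF.
Recovery tests simulate at 20x the study size and require prediction-level
R² > 0.98 between refitted and generating tables (individual parameters
can be weakly identified even when the predicted tables are pinned down).
The model-discrimination property (quantum-generated data fitted better
by the quantum model in >= 90% of replicate experiments) uses 50
replicates at the study's size with reduced restarts (3) per fit, which
is sufficient because the G² gap between the models on quantum data is
large relative to restart noise.

## Numerical and design choices

* 1-based state and rating indices in all public contracts; arrays are
  0-based internally.
* Generator diagonals are built as the negative of the realised
  off-diagonal column sums, so columns sum to zero exactly whenever the
  rates are exactly representable.
* The generator's matrix exponential uses scipy's scaling-and-squaring;
  the unitary uses the tridiagonal eigendecomposition
  `V exp(-i Λ) V^T`, exactly unitary up to round-off.
* Degenerate inputs: zero rates give the identity propagator; `lambda`
  outside [0, 1], negative intensities, non-Hermitian Hamiltonians,
  non-generator matrices, malformed tables and empty record lists raise
  `ValueError` (or `TableFormatError`) with specific messages.
* Refining the lattice (`states_per_rating` 11 -> 21) leaves the
  predicted tables approximately unchanged when parameters are rescaled
  to preserve the continuum limits (Markov: rate difference ∝ n_k, rate
  sum ∝ n_k²; quantum: coupling ∝ n_k², potential endpoint fixed):
  measured max cell changes 1e-5 and 0.018.
* Fixture integrity is checked by sha256 at load time.

## Known limitations

* Raw trial-level data are not published; all reproductions run from the
  rounded printed tables, with the G² consequences quantified above.
  Published participant-level mean comparisons (t and Wilcoxon tests)
  cannot be recomputed at all from the printed tables and are out of
  scope.
* The published observed mean ratings average within participants first;
  trial-pooled means from the printed tables differ slightly (e.g. 3.96
  vs 4.11 for self in the other-first order) — not a defect of either
  computation, just different weighting.
* No standard errors or Bayesian uncertainty on fitted parameters; the
  objectives are non-convex and parameters (especially the couplings)
  can trade off against each other with little change in the predicted
  tables.
* Open-system dynamics (decay of the anchor back toward the neutral
  state, master-equation hybrids of the two models) are out of scope.
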