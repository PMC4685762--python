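import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratewalk import (
    LatticeSpec,
    MarkovParams,
    build_intensity,
    markov_joint,
    posterior_state,
    propagator,
)

from _oracles import (
    brute_markov_joint,
    expm_symmetrized,
    generator_matrix,
    gillespie_transition_matrix,
)

rates = st.floats(0.0, 50.0, allow_nan=False)


class TestBuildIntensity:
    def test_three_state_generator_by_hand(self):
        """alpha=2 (down), beta=1 (up) on 3 states, reflecting ends.

        Column j holds the exit rates of state j: the interior column
        loses alpha+beta, the end columns only the rate that exists.
        """
        K = build_intensity(LatticeSpec(3, 1), alpha=2.0, beta=1.0)
        expected = np.array(
            [
                [-1.0, 2.0, 0.0],
                [1.0, -3.0, 2.0],
                [0.0, 1.0, -2.0],
            ]
        )
        assert np.array_equal(K, expected)

    def test_zero_rates_give_zero_generator(self, spec):
        assert not build_intensity(spec, 0.0, 0.0).any()

    @given(alpha=rates, beta=rates)
    @settings(max_examples=25, deadline=None)
    def test_columns_sum_to_zero(self, alpha, beta):
        K = build_intensity(LatticeSpec(3, 3), alpha, beta)
        scale = max(1.0, alpha + beta)
        assert np.abs(K.sum(axis=0)).max() <= 1e-13 * scale
        off = K - np.diag(np.diag(K))
        assert np.all(off >= 0)

    @pytest.mark.parametrize("alpha,beta", [(2.0, 1.0), (0.5, 0.25), (0.0, 3.0)])
    def test_columns_sum_to_zero_exactly_for_representable_rates(self, spec, alpha, beta):
        K = build_intensity(spec, alpha, beta)
        assert np.abs(K.sum(axis=0)).max() == 0.0

    @pytest.mark.parametrize("alpha,beta", [(-1.0, 1.0), (1.0, -2.0), (np.nan, 1.0)])
    def test_invalid_rates_rejected(self, spec, alpha, beta):
        with pytest.raises(ValueError):
            build_intensity(spec, alpha, beta)
        with pytest.raises(ValueError):
            MarkovParams(alpha, beta, 1.0, 1.0)


class TestPropagator:
    def test_zero_generator_gives_identity(self, spec):
        T = propagator(np.zeros((9, 9)))
        assert np.allclose(T, np.eye(9))

    @given(alpha=rates, beta=rates)
    @settings(max_examples=25, deadline=None)
    def test_column_stochastic(self, alpha, beta):
        T = propagator(build_intensity(LatticeSpec(3, 3), alpha, beta))
        assert np.all(T >= -1e-12)
        assert np.abs(T.sum(axis=0) - 1.0).max() < 1e-10

    def test_rejects_non_generator(self):
        with pytest.raises(ValueError):
            propagator(np.array([[0.0, 1.0], [1.0, 0.0]]))  # columns don't sum to 0
        with pytest.raises(ValueError):
            propagator(np.array([[1.0, -1.0], [-1.0, 1.0]]))  # negative off-diagonal

    def test_matches_event_driven_simulation(self):
        """Analytic expm agrees with a Gillespie CTMC run to t=1."""
        alpha, beta, n = 2.0, 1.0, 3
        T = propagator(build_intensity(LatticeSpec(3, 1), alpha, beta))
        freq, se = gillespie_transition_matrix(n, alpha, beta, t=1.0, n_traj=300_000, seed=42)
        assert np.all(np.abs(T - freq) < 3 * se + 1e-9)


class TestMarkovJoint:
    def test_cells_sum_to_one(self, spec, markov_sse_estimate):
        for order in ("self_first", "other_first"):
            table = markov_joint(spec, markov_sse_estimate.params, order)
            assert table.cells.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(table.cells >= 0)

    def test_identity_second_transition_repeats_the_answer(self, spec):
        """With no evolution for the second question the rating repeats."""
        params = MarkovParams(5.0, 3.0, 0.0, 0.0)
        table = markov_joint(spec, params, "self_first")
        off_diag = table.cells - np.diag(np.diag(table.cells))
        assert np.abs(off_diag).max() < 1e-12

    def test_first_marginal_ignores_second_question_parameters(self, spec):
        a = markov_joint(spec, MarkovParams(30.0, 20.0, 40.0, 10.0), "self_first")
        b = markov_joint(spec, MarkovParams(30.0, 20.0, 5.0, 90.0), "self_first")
        assert np.allclose(a.cells.sum(axis=1), b.cells.sum(axis=1), atol=1e-12)

    def test_balanced_rates_give_symmetric_first_marginal(self, spec):
        table = markov_joint(spec, MarkovParams(25.0, 25.0, 1.0, 1.0), "self_first")
        marginal = table.cells.sum(axis=1)
        assert np.allclose(marginal, marginal[::-1], atol=1e-10)
        assert marginal @ np.arange(1, 10) == pytest.approx(5.0, abs=1e-10)

    def test_drift_direction_follows_rate_imbalance(self, spec):
        """alpha is the downward intensity: alpha > beta drags the mean below neutral."""
        ratings = np.arange(1, 10)
        down = markov_joint(spec, MarkovParams(30.0, 10.0, 1.0, 1.0), "self_first")
        up = markov_joint(spec, MarkovParams(10.0, 30.0, 1.0, 1.0), "self_first")
        assert down.cells.sum(axis=1) @ ratings < 5.0 < up.cells.sum(axis=1) @ ratings

    def test_question_order_changes_the_joint(self, spec, markov_sse_estimate):
        sf = markov_joint(spec, markov_sse_estimate.params, "self_first")
        of = markov_joint(spec, markov_sse_estimate.params, "other_first")
        assert np.abs(sf.cells - of.cells.T).max() > 1e-4

    def test_matches_symmetrised_eigendecomposition_oracle(self, spec, markov_sse_estimate):
        p = markov_sse_estimate.params
        n = spec.n_states
        t_s = expm_symmetrized(generator_matrix(n, p.alpha_s, p.beta_s), p.alpha_s, p.beta_s)
        t_o = expm_symmetrized(generator_matrix(n, p.alpha_o, p.beta_o), p.alpha_o, p.beta_o)
        p0 = np.zeros(n)
        p0[44:55] = 1 / 11
        oracle = np.zeros((9, 9))
        p1 = t_s @ p0
        for j in range(9):
            filtered = np.zeros(n)
            filtered[j * 11 : (j + 1) * 11] = p1[j * 11 : (j + 1) * 11]
            oracle[j] = (t_o @ filtered).reshape(9, 11).sum(axis=1)
        ours = markov_joint(spec, p, "self_first").cells
        assert np.abs(ours - oracle).max() < 1e-8

    def test_degenerate_lattice_matches_brute_force(self):
        """One state per rating: the joint is a plain 9-state chain product."""
        lattice = LatticeSpec(9, 1)
        frozen = markov_joint(lattice, MarkovParams(0.0, 0.0, 0.0, 0.0), "self_first").cells
        expected = np.zeros((9, 9))
        expected[4, 4] = 1.0  # no motion: both answers stay at the neutral rating
        assert np.array_equal(frozen, expected)
        for order in ("self_first", "other_first"):
            ours = markov_joint(lattice, MarkovParams(1.3, 0.7, 0.4, 2.1), order).cells
            oracle = brute_markov_joint(9, 1, 1.3, 0.7, 0.4, 2.1, order)
            assert np.abs(ours - oracle).max() < 1e-10


class TestPosteriorState:
    def test_posterior_is_normalised_and_supported_on_the_block(self, spec):
        params = MarkovParams(20.0, 25.0, 1.0, 1.0)
        post = posterior_state(spec, params, "self_first", first_rating=6)
        assert post.sum() == pytest.approx(1.0)
        assert not post[: 5 * 11].any() and not post[6 * 11 :].any()
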