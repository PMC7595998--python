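"""Invasion fitness matrix and replicator dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costrain import (
    EpidemicParameters,
    effective_k,
    integrate_replicator,
    invasion_fitness_matrix,
    mean_fitness_Q,
    mean_invasion_fitness,
    neutral_equilibrium,
    payoff_matrix_M,
    real_to_slow_time,
    replicator_rhs,
    replicator_rhs_deviation_form,
    slow_to_real_time,
)


def random_A_mu_z(seed, N=5):
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 1, (N, N))
    mu = rng.uniform(0.1, 5.0)
    z = rng.dirichlet(np.ones(N))
    return A, mu, z


class TestInvasionFitness:
    def test_neutral_A_gives_zero(self):
        np.testing.assert_array_equal(invasion_fitness_matrix(np.zeros((3, 3)), 1.0), 0.0)

    def test_hand_worked_2x2(self):
        # mu=1, alpha_12=1 only: lambda_2^1 = 2, lambda_1^2 = -1
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        L = invasion_fitness_matrix(A, 1.0)
        assert L[1, 0] == pytest.approx(2.0)
        assert L[0, 1] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(L), 0.0)

    def test_symmetric_zero_diagonal_A_gives_symmetric_lambda(self, rng):
        # K symmetric with K_ii = k: Lambda symmetric with lambda_i^j = alpha_ij
        A = rng.normal(0, 1, (4, 4))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        L = invasion_fitness_matrix(A, 2.3)
        np.testing.assert_allclose(L, A, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_diagonal_always_zero(self, seed):
        A, mu, _ = random_A_mu_z(seed)
        np.testing.assert_array_equal(np.diag(invasion_fitness_matrix(A, mu)), 0.0)


class TestPayoffMatrix:
    def test_symmetric_A_fixed_point(self, rng):
        A = rng.normal(0, 1, (4, 4))
        A = (A + A.T) / 2
        np.testing.assert_allclose(payoff_matrix_M(A, 1.7), A, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_quadratic_form_matches_A(self, seed):
        A, mu, z = random_A_mu_z(seed)
        assert z @ payoff_matrix_M(A, mu) @ z == pytest.approx(z @ A @ z, abs=1e-12)


class TestRHS:
    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_three_forms_equivalent(self, seed):
        A, mu, z = random_A_mu_z(seed)
        L = invasion_fitness_matrix(A, mu)
        via_lambda = replicator_rhs(z, L, Theta=1.3)
        via_A = replicator_rhs_deviation_form(z, A, mu, Theta=1.3)
        M = payoff_matrix_M(A, mu)
        via_M = 1.3 * z * (M @ z - z @ M @ z)
        np.testing.assert_allclose(via_lambda, via_A, atol=1e-12)
        np.testing.assert_allclose(via_lambda, via_M, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_component_sum_zero(self, seed):
        A, mu, z = random_A_mu_z(seed)
        L = invasion_fitness_matrix(A, mu)
        assert abs(replicator_rhs(z, L).sum()) < 1e-14

    def test_vertices_are_equilibria(self, rng):
        L = rng.normal(0, 1, (4, 4))
        np.fill_diagonal(L, 0.0)
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1.0
            np.testing.assert_array_equal(replicator_rhs(e, L), 0.0)


class TestIntegration:
    def test_neutral_freeze(self, rng):
        z0 = rng.dirichlet(np.ones(5))
        traj = integrate_replicator(z0, np.zeros((5, 5)), taus=np.linspace(0, 50, 20))
        assert np.max(np.abs(traj.z - z0)) < 1e-12

    def test_two_strain_interior_equilibrium(self):
        # lambda_1^2 = 1, lambda_2^1 = 3 -> z1* = 1/4 from any interior start
        L = np.array([[0.0, 1.0], [3.0, 0.0]])
        for z0 in ([0.05, 0.95], [0.9, 0.1]):
            traj = integrate_replicator(np.array(z0), L, tau_max=100.0)
            assert traj.final()[0] == pytest.approx(0.25, abs=1e-8)

    def test_simplex_maintained(self, rng):
        L = rng.uniform(-1, 1, (8, 8))
        np.fill_diagonal(L, 0.0)
        traj = integrate_replicator(rng.dirichlet(np.ones(8)), L, tau_max=200.0)
        assert traj.max_sum_drift <= 1e-9
        np.testing.assert_allclose(traj.z.sum(axis=1), 1.0, atol=1e-9)
        assert traj.z.min() >= 0.0

    def test_full_system_frequency_crosscheck_n6(self):
        # Fig-2-style regime: the reduced frequencies track the full system
        from costrain import (
            decompose_interactions,
            generate_random_K,
            integrate_full,
            on_manifold_state,
        )

        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=6)
        K = generate_random_K(6, 1.0, 0.1, seed=42)
        d = decompose_interactions(K)
        eq = neutral_equilibrium(p, d.k)
        z0 = np.random.default_rng(0).dirichlet(np.ones(6))
        times = np.linspace(0.0, 250.0, 60)
        full = integrate_full(on_manifold_state(z0, eq), p, K, times)
        L = invasion_fitness_matrix(d.A, eq.mu)
        red = integrate_replicator(z0, L, Theta=eq.Theta, taus=d.epsilon * times)
        assert np.max(np.abs(full.frequencies() - red.z)) < 5 * d.epsilon


class TestDiagnostics:
    def test_Q_zero_for_antisymmetric(self, rng):
        L = rng.normal(0, 1, (6, 6))
        L = np.triu(L, 1)
        L = L - L.T
        for _ in range(5):
            z = rng.dirichlet(np.ones(6))
            assert abs(mean_fitness_Q(z, L)) < 1e-14

    def test_Q_hand_worked(self):
        L = np.array([[0.0, 1.0], [3.0, 0.0]])
        z = np.array([0.5, 0.5])
        assert mean_fitness_Q(z, L) == pytest.approx(1.0)
        lbar = mean_invasion_fitness(z, L)
        assert lbar @ z == pytest.approx(1.0)

    def test_Q_zero_at_vertices(self, rng):
        L = rng.normal(0, 1, (4, 4))
        np.fill_diagonal(L, 0.0)
        e = np.zeros(4)
        e[2] = 1.0
        assert mean_fitness_Q(e, L) == 0.0

    def test_effective_k(self):
        A = np.array([[1.0, -1.0], [-1.0, 1.0]])
        k_eff, q = effective_k(np.array([0.5, 0.5]), 1.0, 0.1, A)
        assert q == pytest.approx(0.0, abs=1e-14)
        assert k_eff == pytest.approx(1.0)
        k_eff0, _ = effective_k(np.array([0.3, 0.7]), 1.4, 0.0, A)
        assert k_eff0 == pytest.approx(1.4)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_Q_equals_q_minus_diagonal_term(self, seed):
        # Q = q(z) - sum_j alpha_jj z_j with the mu-matched Lambda
        A, mu, z = random_A_mu_z(seed)
        L = invasion_fitness_matrix(A, mu)
        _, q = effective_k(z, 1.0, 1.0, A)
        assert mean_fitness_Q(z, L) == pytest.approx(q - np.diag(A) @ z, abs=1e-12)

    def test_time_conversions(self):
        assert slow_to_real_time(0.5, 0.1) == pytest.approx(5.0)
        assert real_to_slow_time(5.0, 0.1) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            slow_to_real_time(1.0, 0.0)
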