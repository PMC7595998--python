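"""Full 1+N+N^2 compartmental system: RHS, aggregation, integration."""

import numpy as np
import pytest

from costrain import (
    EpidemicParameters,
    FullState,
    aggregate,
    fast_coordinates,
    force_of_infection,
    full_rhs,
    integrate_full,
    neutral_equilibrium,
    on_manifold_state,
    uniform_seed_state,
)


def random_simplex_state(rng, N):
    parts = rng.dirichlet(np.ones(1 + N + N * N))
    return FullState(S=parts[0], Ivec=parts[1 : 1 + N], Icc=parts[1 + N :].reshape(N, N))


class TestAggregation:
    def test_zero_infection_state(self):
        s = FullState(S=1.0, Ivec=np.zeros(2), Icc=np.zeros((2, 2)))
        agg = aggregate(s)
        assert agg.Isingle == agg.D == agg.T == 0.0
        np.testing.assert_array_equal(agg.Jvec, 0.0)
        np.testing.assert_array_equal(force_of_infection(s, EpidemicParameters(2, 0.5, 0.5, 2)), 0.0)

    def test_hand_worked_aggregates(self):
        # J_1 = 0.1 + (1/2)(0.02+0.02+0.03+0.01) = 0.14; T = 0.3
        s = FullState(
            S=0.7, Ivec=np.array([0.1, 0.1]), Icc=np.array([[0.02, 0.03], [0.01, 0.04]])
        )
        agg = aggregate(s)
        assert agg.Jvec[0] == pytest.approx(0.14)
        assert agg.Isingle == pytest.approx(0.2)
        assert agg.D == pytest.approx(0.1)
        assert agg.T == pytest.approx(0.3)
        assert agg.T == pytest.approx(agg.Jvec.sum())

    def test_single_strain_force_of_infection(self):
        # F_1 = beta (I_1 + I_11) = 2 (0.2 + 0.1) = 0.6
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=1)
        s = FullState(S=0.7, Ivec=np.array([0.2]), Icc=np.array([[0.1]]))
        assert force_of_infection(s, p)[0] == pytest.approx(0.6)

    def test_force_equals_beta_J(self, rng):
        p = EpidemicParameters(beta=1.7, gamma=0.4, r=0.2, N=4)
        s = random_simplex_state(rng, 4)
        np.testing.assert_allclose(force_of_infection(s, p), p.beta * aggregate(s).Jvec)


class TestRHS:
    def test_disease_free_is_equilibrium(self):
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        s = FullState(S=1.0, Ivec=np.zeros(3), Icc=np.zeros((3, 3)))
        d = full_rhs(s, p, np.ones((3, 3)))
        assert d.S == 0.0
        np.testing.assert_array_equal(d.Ivec, 0.0)
        np.testing.assert_array_equal(d.Icc, 0.0)

    def test_conservation_on_random_simplex_states(self, rng):
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        K = rng.uniform(0.5, 1.5, size=(3, 3))
        for _ in range(20):
            d = full_rhs(random_simplex_state(rng, 3), p, K)
            assert d.total == pytest.approx(0.0, abs=1e-14)

    def test_aggregate_derivative_consistency(self, rng):
        # d/dt of aggregates from chain rule == aggregates of the RHS
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        K = rng.uniform(0.5, 1.5, size=(3, 3))
        s = random_simplex_state(rng, 3)
        d = full_rhs(s, p, K)
        h = 1e-7
        s2 = FullState(S=s.S + h * d.S, Ivec=s.Ivec + h * d.Ivec, Icc=s.Icc + h * d.Icc)
        fd_J = (aggregate(s2).Jvec - aggregate(s).Jvec) / h
        np.testing.assert_allclose(fd_J, aggregate(d).Jvec, atol=1e-6)

    def test_dimension_mismatch(self):
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=2)
        s = FullState(S=1.0, Ivec=np.zeros(2), Icc=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="does not match"):
            full_rhs(s, p, np.ones((3, 3)))


class TestIntegration:
    def test_single_strain_endemic_equilibrium(self):
        # N=1 reduces to SIS-with-self-coinfection; S* = 1/R0
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=1)
        traj = integrate_full(
            uniform_seed_state(1), p, np.array([[1.0]]), np.linspace(0, 100, 21)
        )
        agg = traj.aggregates().iloc[-1]
        assert agg["S"] == pytest.approx(0.5, abs=1e-6)
        assert agg["T"] == pytest.approx(0.5, abs=1e-6)
        assert agg["I"] == pytest.approx(0.25, abs=1e-6)
        assert agg["D"] == pytest.approx(0.25, abs=1e-6)

    def test_conservation_along_trajectory(self, rng):
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        K = rng.uniform(0.8, 1.2, size=(3, 3))
        traj = integrate_full(uniform_seed_state(3), p, K, np.linspace(0, 50, 26))
        for s in traj.states:
            assert abs(s.total - 1.0) <= 1e-8

    def test_ST_block_independent_of_K(self, rng):
        # the (S, T) sub-dynamics close on themselves
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        times = np.linspace(0, 40, 41)
        init = uniform_seed_state(3)
        a = integrate_full(init, p, rng.uniform(0.5, 1.5, (3, 3)), times).aggregates()
        b = integrate_full(init, p, rng.uniform(0.5, 1.5, (3, 3)), times).aggregates()
        np.testing.assert_allclose(a["S"], b["S"], atol=1e-6)
        np.testing.assert_allclose(a["T"], b["T"], atol=1e-6)

    def test_neutral_frequencies_frozen_and_H_decay(self):
        # eps=0 with aggregates at equilibrium but strain shares unequal
        # between single and co-colonization: z_i stays constant and the
        # fast coordinate H_i decays at exactly rate xi.
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=3)
        k = 1.0
        eq = neutral_equilibrium(p, k)
        w = np.array([0.5, 0.3, 0.2])  # single-colonization shares
        v = np.array([0.2, 0.3, 0.5])  # co-colonization shares (off-manifold)
        init = FullState(S=eq.S_star, Ivec=eq.I_star * w, Icc=eq.D_star * np.outer(v, v))
        times = np.linspace(0.0, 5.0, 51)
        traj = integrate_full(
            init, p, np.full((3, 3), k), times, rtol=1e-10, atol=1e-12
        )
        zs, Hs = [], []
        for s in traj.states:
            agg = aggregate(s)
            fc = fast_coordinates(s.Ivec, agg.Jvec, eq)
            zs.append(fc.z)
            Hs.append(np.max(np.abs(fc.H)))
        zs = np.asarray(zs)
        assert np.max(np.abs(zs - zs[0])) < 1e-7
        Hs = np.asarray(Hs)
        win = Hs > 1e-10
        slope = np.polyfit(times[win], np.log(Hs[win]), 1)[0]
        assert slope == pytest.approx(-eq.xi, rel=0.02)

    def test_off_simplex_initial_state_rejected(self):
        p = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=2)
        bad = FullState(S=0.9, Ivec=np.array([0.2, 0.2]), Icc=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="simplex"):
            integrate_full(bad, p, np.ones((2, 2)), np.linspace(0, 1, 5))

    def test_on_manifold_builder(self, eq_r0_2):
        z0 = np.array([0.3, 0.7])
        s = on_manifold_state(z0, eq_r0_2)
        assert s.total == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(s.Ivec, 0.25 * z0)
        np.testing.assert_allclose(s.Icc.sum(), 0.25)
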