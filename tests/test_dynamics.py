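"""Vector field, Jacobian structure, conservation, steady states, entrainment."""

import numpy as np
import pytest

from poolflow import (
    NetworkState,
    TimeVaryingRates,
    Trajectory,
    benchmarks,
    estimate_period,
    find_steady_state,
    integrate,
    jacobian,
    simulate_periodic,
    total_occupancy,
    vector_field,
)
from conftest import TWO_POOL_E


def random_interior_state(network, rng, z_scale=1.0):
    v = np.empty(network.state_size)
    ns = network.n_sites_total
    v[:ns] = rng.uniform(0.05, 0.95, size=ns)
    v[ns:] = rng.uniform(0.05, z_scale, size=network.n_pools)
    return v


class TestVectorField:
    def test_origin_is_equilibrium(self, two_pool_net):
        np.testing.assert_array_equal(
            vector_field(two_pool_net, np.zeros(6)), np.zeros(6)
        )

    def test_hand_evaluated_entry_site_derivative(self, two_pool_net):
        # dx1 of the forward lane at the all-0.5 state:
        # 0.8 * tanh(0.5) * 0.5 - 1 * 0.5 * 0.5
        f = vector_field(two_pool_net, np.full(6, 0.5))
        assert f[0] == pytest.approx(0.8 * np.tanh(0.5) * 0.5 - 0.25, abs=1e-14)
        assert f[0] == pytest.approx(-0.0651531371, abs=1e-9)

    def test_reference_steady_state_annihilates_field(self, two_pool_net):
        f = vector_field(two_pool_net, TWO_POOL_E)
        assert np.max(np.abs(f)) <= 5e-4  # 4-decimal rounding of e

    def test_components_sum_to_zero_everywhere(self, rng):
        for _ in range(5):
            net = benchmarks.random_two_pool_network(rng)
            v = random_interior_state(net, rng, z_scale=3.0)
            assert abs(vector_field(net, v).sum()) < 1e-14


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        net = benchmarks.random_two_pool_network(rng)
        h = 1e-7
        for _ in range(20):
            v = random_interior_state(net, rng)
            J = jacobian(net, v)
            Jfd = np.empty_like(J)
            for k in range(net.state_size):
                dv = np.zeros(net.state_size)
                dv[k] = h
                Jfd[:, k] = (
                    vector_field(net, v + dv) - vector_field(net, v - dv)
                ) / (2 * h)
            assert np.max(np.abs(J - Jfd)) <= 1e-6 * max(1.0, np.max(np.abs(J)))

    def test_metzler_on_state_space(self, rng):
        # cooperative system: off-diagonal entries >= 0 at interior states
        for _ in range(20):
            net = benchmarks.random_two_pool_network(rng)
            for _ in range(5):
                J = jacobian(net, random_interior_state(net, rng, z_scale=2.0))
                off = J - np.diag(np.diag(J))
                assert np.min(off) >= 0.0

    def test_column_sums_vanish(self, two_pool_net, rng):
        # differential of the conserved Q: 1^T J = 0
        J = jacobian(two_pool_net, random_interior_state(two_pool_net, rng))
        np.testing.assert_allclose(J.sum(axis=0), 0.0, atol=1e-14)


class TestIntegrate:
    def test_conserves_first_integral(self, two_pool_net):
        v0 = np.array([0.5, 0.5, 0.5, 0.5, 0.0, 0.0])
        traj = integrate(two_pool_net, v0, 100.0)
        assert traj.conservation_drift <= 1e-8 * 2.0

    def test_converges_from_both_reference_initials(self, two_pool_net):
        for v0 in ([0.5, 0.5, 0.5, 0.5, 0, 0], [0, 0, 0, 0, 1, 1]):
            traj = integrate(two_pool_net, np.array(v0, dtype=float), 200.0)
            np.testing.assert_allclose(traj.final_state(), TWO_POOL_E, atol=5e-5)

    def test_steady_state_is_fixed_point(self, two_pool_net):
        ss = find_steady_state(two_pool_net, r=2.0)
        traj = integrate(two_pool_net, ss.e, 50.0)
        assert np.max(np.abs(traj.final_state() - ss.e)) < 1e-8

    def test_invariance_of_state_space(self, two_pool_net):
        v0 = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        traj = integrate(
            two_pool_net, v0, 50.0, t_eval=np.linspace(0, 50.0, 200)
        )
        x = traj.states[:, :4]
        z = traj.states[:, 4:]
        assert np.all(x >= -1e-9) and np.all(x <= 1 + 1e-9) and np.all(z >= -1e-9)

    def test_persistence_separates_from_boundary(self, two_pool_net):
        # from a boundary initial state, all densities are strictly interior
        # and pools strictly positive for t >= 1
        v0 = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        traj = integrate(two_pool_net, v0, 10.0, t_eval=np.linspace(1.0, 10.0, 50))
        x = traj.states[:, :4]
        z = traj.states[:, 4:]
        assert np.all(x > 0) and np.all(x < 1) and np.all(z > 0)


class TestFindSteadyState:
    def test_zero_level_set(self, two_pool_net):
        ss = find_steady_state(two_pool_net, r=0.0)
        np.testing.assert_array_equal(ss.e, np.zeros(6))

    def test_reference_steady_state(self, two_pool_net):
        ss = find_steady_state(two_pool_net, r=2.0)
        np.testing.assert_allclose(ss.e, TWO_POOL_E, atol=5e-5)
        assert ss.residual < 1e-10
        assert total_occupancy(ss.e) == pytest.approx(2.0, abs=1e-9)

    def test_independent_of_initial_state_in_level_set(self, two_pool_net, rng):
        a = find_steady_state(
            two_pool_net, initial=np.array([0.5, 0.5, 0.5, 0.5, 0.0, 0.0])
        )
        b = find_steady_state(
            two_pool_net, initial=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        )
        assert np.max(np.abs(a.e - b.e)) <= 1e-8

    def test_monotone_continuum_of_steady_states(self, two_pool_net):
        # steady states are strictly ordered componentwise in r
        levels = [0.5, 1.0, 2.0, 4.0]
        states = [find_steady_state(two_pool_net, r=r).e for r in levels]
        for lo, hi in zip(states, states[1:]):
            assert np.all(lo < hi)

    def test_steady_state_flux_identities(self, two_pool_net):
        # within each chain the flux is constant along the lane, and each
        # pool's inbound flux equals its outbound flux
        ss = find_steady_state(two_pool_net, r=2.0)
        for c in two_pool_net.chains:
            e = ss.chain_densities(c.chain_id)
            z = ss.pool_level(c.source_pool)
            lam = c.rates
            fluxes = [lam[0] * c.input_function(z) * (1 - e[0])]
            fluxes += [
                lam[j] * e[j - 1] * (1 - e[j]) for j in range(1, c.n_sites)
            ]
            fluxes.append(lam[-1] * e[-1])
            np.testing.assert_allclose(fluxes, fluxes[0], atol=1e-11)
        out_x = ss.output_rate("X1")
        out_y = ss.output_rate("Y1")
        assert out_x == pytest.approx(out_y, abs=1e-11)

    def test_mismatched_initial_and_r_rejected(self, two_pool_net):
        with pytest.raises(ValueError, match="level set"):
            find_steady_state(
                two_pool_net, r=3.0, initial=np.array([0.5, 0.5, 0.5, 0.5, 0, 0])
            )


class TestPeriodicForcing:
    def test_entrains_to_forcing_period(self):
        net, rates, v0 = benchmarks.two_pool_periodic()
        traj = simulate_periodic(net, rates, v0, 40)
        est = estimate_period(traj)
        assert est.flag == "periodic"
        assert est.period == pytest.approx(1.0, abs=0.01)
        # every state component oscillates with the common period
        comp = est.component_periods
        assert np.all(np.abs(comp[~np.isnan(comp)] - 1.0) <= 0.01)

    def test_time_rescaled_forcing_doubles_period(self):
        net, _, v0 = benchmarks.two_pool_periodic()
        rates2 = TimeVaryingRates(
            functions={
                ("X1", 2): lambda t: 3.0 + 2.0 * np.sin(np.pi * t),
                ("X1", 3): lambda t: 3.0 - 2.0 * np.sin(np.pi * t),
                ("Y1", 1): lambda t: 4.0 - 2.0 * np.sin(np.pi * t),
            },
            period=2.0,
        )
        traj = simulate_periodic(net, rates2, v0, 30)
        est = estimate_period(traj)
        assert est.flag == "periodic"
        assert est.period == pytest.approx(2.0, abs=0.02)

    def test_constant_rates_flagged_constant(self, two_pool_net):
        rates = TimeVaryingRates(
            functions={("X1", 1): lambda t: 1.0}, period=1.0
        )
        v0 = NetworkState.pools_only(two_pool_net, 2.0).to_vector(two_pool_net)
        traj = simulate_periodic(
            two_pool_net, rates, v0, 150, samples_per_period=20
        )
        est = estimate_period(traj)
        assert est.flag == "constant"

    def test_synthetic_sine_period_recovered(self, two_pool_net):
        t = np.linspace(0.0, 20.0, 4001)
        states = 0.5 + 0.1 * np.sin(2 * np.pi * t / 0.5)[:, None] * np.ones((1, 6))
        traj = Trajectory(times=t, states=states, network=two_pool_net)
        est = estimate_period(traj)
        assert est.period == pytest.approx(0.5, abs=0.005)

    def test_nonperiodic_override_rejected(self, two_pool_net):
        rates = TimeVaryingRates(functions={("X1", 1): lambda t: 1.0 + t}, period=1.0)
        with pytest.raises(ValueError, match="periodic"):
            rates.validate(two_pool_net)

    def test_nonpositive_override_rejected(self, two_pool_net):
        rates = TimeVaryingRates(
            functions={("X1", 1): lambda t: np.sin(2 * np.pi * t)}, period=1.0
        )
        with pytest.raises(ValueError, match="positive"):
            rates.validate(two_pool_net)
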