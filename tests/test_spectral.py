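"""Jacobi-matrix spectral machinery and the pool-balance steady-state solve."""

import numpy as np
import pytest

from poolflow import (
    ChainSpec,
    InputFunction,
    benchmarks,
    build_network,
    chain_steady_state,
    find_steady_state,
    jacobi_matrix,
    perron_eigenpair,
    solve_pool_balance,
    steady_state_output_rate,
)
from conftest import TWO_POOL_E


class TestJacobiMatrix:
    def test_unit_rates_single_site(self):
        np.testing.assert_array_equal(
            jacobi_matrix([1.0, 1.0]),
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]],
        )

    def test_off_diagonals_are_inverse_square_roots(self):
        A = jacobi_matrix([4.0, 1.0])
        np.testing.assert_allclose(np.diag(A, 1), [0.5, 1.0])
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 0.0)

    def test_effective_entry_rate_enters_first_entry(self):
        # forward lane of the two-pool benchmark at its steady-state pool level
        eff = 0.8 * np.tanh(0.6023)
        A = jacobi_matrix([eff, 1.0, 1.2])
        np.testing.assert_allclose(
            np.diag(A, 1), [eff ** -0.5, 1.0, 1.2 ** -0.5]
        )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            jacobi_matrix([1.0, 0.0])


class TestPerronEigenpair:
    def test_single_site_unit_rates(self):
        spec = perron_eigenpair([1.0, 1.0])
        assert spec.sigma == pytest.approx(np.sqrt(2.0), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    def test_homogeneous_chain_closed_form(self, n):
        # uniform tridiagonal matrix: sigma = 2 cos(pi / (n + 3))
        spec = perron_eigenpair([1.0] * (n + 1))
        assert spec.sigma == pytest.approx(2 * np.cos(np.pi / (n + 3)), abs=1e-12)

    def test_eigenvector_strictly_positive(self, rng):
        for _ in range(10):
            rates = rng.uniform(0.1, 5.0, size=rng.integers(2, 10))
            spec = perron_eigenpair(rates)
            assert np.all(spec.zeta > 0)
            assert np.linalg.norm(spec.zeta) == pytest.approx(1.0)


class TestChainSteadyState:
    def test_single_site_balance(self):
        # entry = exit = 1: l0 (1 - e) = l1 e gives e = 1/2
        np.testing.assert_allclose(chain_steady_state([1.0, 1.0]), [0.5])

    def test_reference_forward_lane(self):
        e = chain_steady_state([0.8, 1.0, 1.2], 0.8 * np.tanh(0.6023))
        np.testing.assert_allclose(e, [0.3589, 0.2302], atol=5e-5)

    def test_flux_constant_and_equal_to_inverse_sigma_squared(self, rng):
        for _ in range(10):
            rates = rng.uniform(0.2, 4.0, size=rng.integers(2, 12))
            spec = perron_eigenpair(rates)
            e = chain_steady_state(rates)
            R = 1.0 / spec.sigma ** 2
            n = len(rates) - 1
            fluxes = [rates[0] * (1 - e[0])]
            fluxes += [rates[j] * e[j - 1] * (1 - e[j]) for j in range(1, n)]
            fluxes.append(rates[n] * e[n - 1])
            np.testing.assert_allclose(fluxes, R, atol=1e-10)

    def test_densities_interior(self, rng):
        for _ in range(10):
            rates = rng.uniform(0.1, 5.0, size=rng.integers(2, 12))
            e = chain_steady_state(rates)
            assert np.all(e > 0) and np.all(e < 1)

    def test_flux_recursion_agrees_with_eigenvector_route(self):
        from poolflow.spectral_solver import (
            _densities_from_flux,
            _perron_eigenvalue,
        )

        lam = np.array([0.7, 1.3, 0.9, 2.0, 1.1])
        direct = chain_steady_state(lam)
        via_flux = _densities_from_flux(lam, _perron_eigenvalue(lam))
        np.testing.assert_allclose(via_flux, direct, atol=1e-11)


class TestOutputRate:
    def test_known_values(self):
        assert steady_state_output_rate(np.sqrt(2.0)) == pytest.approx(0.5)
        # two-site homogeneous chain: R = 1 / (4 cos^2(pi/5))
        sigma = 2 * np.cos(np.pi / 5)
        assert steady_state_output_rate(sigma) == pytest.approx(
            1 / (4 * np.cos(np.pi / 5) ** 2)
        )
        assert steady_state_output_rate(sigma) == pytest.approx(0.38197, abs=1e-5)

    def test_monotone_in_every_rate(self):
        # lowering any single rate lowers the output flux
        base = [1.0, 2.0, 0.7, 1.5]
        R0 = steady_state_output_rate(perron_eigenpair(base))
        for k in range(len(base)):
            rates = list(base)
            rates[k] *= 0.5
            assert steady_state_output_rate(perron_eigenpair(rates)) < R0


class TestSolvePoolBalance:
    def test_reference_two_pool_network(self, two_pool_net):
        sol = solve_pool_balance(two_pool_net, 2.0)
        assert sol.pool_levels["I"] == pytest.approx(0.6023, abs=5e-5)
        assert sol.pool_levels["II"] == pytest.approx(0.3414, abs=5e-5)
        ss = sol.to_result(two_pool_net)
        np.testing.assert_allclose(ss.e, TWO_POOL_E, atol=5e-5)
        assert ss.residual < 1e-9

    def test_zero_occupancy(self, two_pool_net):
        sol = solve_pool_balance(two_pool_net, 0.0)
        assert all(v == 0.0 for v in sol.pool_levels.values())
        assert all(np.all(d == 0) for d in sol.chain_densities.values())

    def test_symmetric_network_balances_pools(self, rng):
        # a network whose return lanes copy the forward lanes has equal
        # steady-state pool levels (the single-pool network embeds this way)
        x = ChainSpec("X1", 4, (0.9, 1.4, 0.6, 1.1, 1.3), "I", "II",
                      InputFunction.tanh())
        y = ChainSpec("Y1", 4, x.rates, "II", "I", x.input_function)
        net = build_network(["I", "II"], [x, y])
        for r in (0.5, 2.0, 5.0):
            sol = solve_pool_balance(net, r)
            assert sol.pool_levels["I"] == pytest.approx(
                sol.pool_levels["II"], abs=1e-10
            )
            np.testing.assert_allclose(
                sol.chain_densities["X1"], sol.chain_densities["Y1"], atol=1e-10
            )

    def test_agrees_with_ode_route_on_random_networks(self, rng):
        for _ in range(6):
            net = benchmarks.random_two_pool_network(rng)
            for r in (0.5, 2.0):
                a = solve_pool_balance(net, r).to_result(net)
                b = find_steady_state(net, r=r)
                assert np.max(np.abs(a.e - b.e)) <= 1e-6

    def test_three_pool_ring_agrees_with_ode(self, three_pool_net):
        a = solve_pool_balance(three_pool_net, 4.0).to_result(three_pool_net)
        b = find_steady_state(three_pool_net, r=4.0)
        assert np.max(np.abs(a.e - b.e)) <= 1e-6

    @pytest.mark.parametrize("m", [2, 3])
    def test_identical_lane_scaling_reduction(self, m):
        # m identical forward + m identical return lanes at occupancy r
        # reduce to one lane each with entry rates scaled by m at r/m,
        # with pool levels scaled by m (degree-1 homogeneous input functions)
        lamx = (0.7, 1.1, 0.9, 1.3)
        lamy = (1.2, 0.8, 1.5)
        ident = InputFunction.identity()
        chains = [ChainSpec(f"X{i}", 3, lamx, "I", "II", ident) for i in range(m)]
        chains += [ChainSpec(f"Y{i}", 2, lamy, "II", "I", ident) for i in range(m)]
        big = build_network(["I", "II"], chains)
        small = build_network(
            ["I", "II"],
            [
                ChainSpec("X0", 3, (m * lamx[0],) + lamx[1:], "I", "II", ident),
                ChainSpec("Y0", 2, (m * lamy[0],) + lamy[1:], "II", "I", ident),
            ],
        )
        r = 3.0
        eb = solve_pool_balance(big, r)
        es = solve_pool_balance(small, r / m)
        np.testing.assert_allclose(
            eb.chain_densities["X0"], es.chain_densities["X0"], atol=1e-9
        )
        np.testing.assert_allclose(
            eb.chain_densities["Y0"], es.chain_densities["Y0"], atol=1e-9
        )
        assert eb.pool_levels["I"] == pytest.approx(m * es.pool_levels["I"], abs=1e-9)
        assert eb.pool_levels["II"] == pytest.approx(m * es.pool_levels["II"], abs=1e-9)
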