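import numpy as np
import pytest

import habgame as hg
from habgame.nash import SUPPORT_TOL, _slacks
from conftest import random_density


def consumer_only_closed_form(params, env, grid, N_c):
    """Exact single-species equilibrium: density proportional to capacity.

    From the stationarity condition beta_c*(1 - N_c sigma/capacity) =
    lambda plus normalization; the capacity profile is strictly positive so
    the solution is interior.  Verified by substitution below.
    """
    cap_mass = hg.inner_product(env.capacity, np.ones(grid.n_nodes), grid)
    sigma = env.capacity / cap_mass
    lam = params.beta_c * (1.0 - N_c / cap_mass)
    return sigma, lam


def wrap_candidate(sigma_c, sigma_p, lam_c, lam_p, state, params, env, grid):
    g_c = hg.consumer_pointwise_fitness(state,
                                        hg.StrategyPair(sigma_c, sigma_p),
                                        params, env, grid)
    g_p = hg.predator_pointwise_fitness_gradient(
        state, hg.StrategyPair(sigma_c, sigma_p), params, env, grid)
    nu_c = _slacks(sigma_c, g_c, lam_c)
    nu_p = _slacks(sigma_p, g_p, lam_p)
    report = hg.ResidualReport(0, 0, 0, 0, iterations=0, converged=False)
    return hg.NashSolution(strategies=hg.StrategyPair(sigma_c, sigma_p),
                           lambda_c=lam_c, lambda_p=lam_p, nu_c=nu_c,
                           nu_p=nu_p, residuals=report)


class TestKktResidual:
    def test_closed_form_passes(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.0)
        sigma, lam = consumer_only_closed_form(table_params, env, grid21,
                                               0.5)
        cand = wrap_candidate(sigma, np.ones(grid21.n_nodes), lam, 0.0,
                              state, table_params, env, grid21)
        report = hg.kkt_residual(cand, state, table_params, env, grid21)
        assert report.max_residual <= 1e-10

    def test_uniform_in_homogeneous_environment(self, grid21):
        p = hg.derive_parameters({"k_light": 1e-14, "hunt_decay": 1e-18,
                                  "c": 0.3})
        env = hg.environment_profiles(p, grid21)
        state = hg.PopulationState(0.4, 0.2)
        ones = np.ones(grid21.n_nodes)
        pair = hg.StrategyPair(ones, ones)
        g_c = hg.consumer_pointwise_fitness(state, pair, p, env, grid21)
        g_p = hg.predator_pointwise_fitness_gradient(state, pair, p, env,
                                                     grid21)
        lam_c = hg.inner_product(ones, g_c, grid21)
        lam_p = hg.inner_product(ones, g_p, grid21)
        cand = hg.NashSolution(strategies=pair, lambda_c=lam_c,
                               lambda_p=lam_p, nu_c=np.zeros_like(ones),
                               nu_p=np.zeros_like(ones),
                               residuals=hg.ResidualReport(
                                   0, 0, 0, 0, iterations=0,
                                   converged=False))
        report = hg.kkt_residual(cand, state, p, env, grid21)
        assert report.max_residual <= 1e-12

    def test_perturbation_detected(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.0)
        sigma, lam = consumer_only_closed_form(table_params, env, grid21,
                                               0.5)
        sigma = sigma.copy()
        sigma[3] += 0.1
        sigma /= hg.inner_product(sigma, np.ones(grid21.n_nodes), grid21)
        cand = wrap_candidate(sigma, np.ones(grid21.n_nodes), lam, 0.0,
                              state, table_params, env, grid21)
        report = hg.kkt_residual(cand, state, table_params, env, grid21)
        assert report.stationarity_inf_norm > 1e-4

    def test_size_mismatch_raises(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.0)
        bad = np.ones(grid21.n_nodes - 1)
        report = hg.ResidualReport(0, 0, 0, 0, 0, False)
        cand = hg.NashSolution(
            strategies=hg.StrategyPair(bad, np.ones(grid21.n_nodes)),
            lambda_c=0.0, lambda_p=0.0, nu_c=np.zeros(grid21.n_nodes),
            nu_p=np.zeros(grid21.n_nodes), residuals=report)
        with pytest.raises(ValueError):
            hg.kkt_residual(cand, state, table_params, env, grid21)


class TestSolveNash:
    @pytest.mark.parametrize("K", [0.5, 3.0, 40.0])
    @pytest.mark.parametrize("N_c", [0.2, 1.0])
    def test_consumer_only_closed_form(self, K, N_c, grid300):
        p = hg.derive_parameters({"K": K, "c": 0.0})
        env = hg.environment_profiles(p, grid300)
        state = hg.PopulationState(N_c, 0.0)
        sol = hg.solve_nash(state, p, env, grid300, tol=1e-10)
        sigma, lam = consumer_only_closed_form(p, env, grid300, N_c)
        np.testing.assert_allclose(sol.strategies.sigma_c, sigma,
                                   atol=1e-8)
        assert sol.lambda_c == pytest.approx(lam, abs=1e-10)

    def test_homogeneous_habitat_uniform(self, grid21):
        p = hg.derive_parameters({"k_light": 1e-14, "hunt_decay": 1e-18,
                                  "c": 0.3})
        env = hg.environment_profiles(p, grid21)
        state = hg.PopulationState(0.4, 0.2)
        sol = hg.solve_nash(state, p, env, grid21, tol=1e-9)
        np.testing.assert_allclose(sol.strategies.sigma_c,
                                   np.ones(grid21.n_nodes), atol=1e-7)
        np.testing.assert_allclose(sol.strategies.sigma_p,
                                   np.ones(grid21.n_nodes), atol=1e-7)

    def test_five_node_matches_replicator(self):
        p = hg.derive_parameters({"K": 3.0, "c": 0.5})
        grid = hg.build_grid(100.0, 5)
        env = hg.environment_profiles(p, grid)
        state = hg.PopulationState(1.0, 1.0)
        sol = hg.solve_nash(state, p, env, grid, tol=1e-10)
        rep = hg.replicator_solve(state, p, env, grid, seed=0, tol=1e-10)
        np.testing.assert_allclose(rep.sigma_c, sol.strategies.sigma_c,
                                   atol=1e-6)
        np.testing.assert_allclose(rep.sigma_p, sol.strategies.sigma_p,
                                   atol=1e-6)

    def test_support_structure(self, equilibrium_K3, table_params, grid300,
                               env300):
        sol = equilibrium_K3.nash
        state = equilibrium_K3.state
        g_p = hg.predator_pointwise_fitness_gradient(
            state, sol.strategies, table_params, env300, grid300)
        on = sol.strategies.sigma_p > SUPPORT_TOL
        assert on.any() and (~on).any()  # predators occupy a band
        assert np.max(np.abs(g_p[on] - sol.lambda_p)) <= 1e-8
        assert np.max(g_p[~on] - sol.lambda_p) <= 1e-8

    def test_extinct_species_uniform_convention(self, table_params,
                                                grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.7, 0.0)
        sol = hg.solve_nash(state, table_params, env, grid21, tol=1e-10)
        np.testing.assert_array_equal(sol.strategies.sigma_p,
                                      np.ones(grid21.n_nodes))

    def test_warm_start_converges_fast(self, table_params, grid300,
                                       env300):
        state = hg.PopulationState(1.0, 1.0)
        cold = hg.solve_nash(state, table_params, env300, grid300,
                             tol=1e-10)
        nearby = hg.PopulationState(1.01, 1.0)
        warm = hg.solve_nash(nearby, table_params, env300, grid300,
                             init=cold, tol=1e-10)
        assert warm.residuals.iterations < cold.residuals.iterations

    def test_failure_carries_best_iterate(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(1.0, 1.0)
        with pytest.raises(hg.SolverFailureError) as err:
            hg.solve_nash(state, table_params, env, grid21, tol=1e-10,
                          max_iters=1)
        assert err.value.best is not None


class TestBestResponse:
    def test_strict_maximizer_indicator(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        # lots of predators at uniform: best spot is where fitness peaks
        state = hg.PopulationState(0.01, 0.5)
        mean = hg.uniform_pair(grid21)
        g_c = hg.consumer_pointwise_fitness(state, mean, table_params, env,
                                            grid21)
        j = int(np.argmax(g_c))
        br = hg.best_response_consumer(mean, state, table_params, env,
                                       grid21)
        expected = np.zeros(grid21.n_nodes)
        expected[j] = 1.0 / grid21.weights[j]
        np.testing.assert_allclose(br, expected)

    def test_total_tie_uniform(self, grid21):
        p = hg.derive_parameters({"k_light": 1e-14, "hunt_decay": 1e-18})
        env = hg.environment_profiles(p, grid21)
        state = hg.PopulationState(0.4, 0.2)
        br = hg.best_response_consumer(hg.uniform_pair(grid21), state, p,
                                       env, grid21, tie_tol=1e-9)
        np.testing.assert_allclose(br, np.ones(grid21.n_nodes), atol=1e-12)

    def test_no_profitable_deviation_at_nash(self, equilibrium_K3,
                                             table_params, grid300,
                                             env300):
        sol = equilibrium_K3.nash
        state = equilibrium_K3.state
        br = hg.best_response_consumer(sol.strategies, state, table_params,
                                       env300, grid300)
        g_c = hg.consumer_pointwise_fitness(state, sol.strategies,
                                            table_params, env300, grid300)
        br_payoff = hg.inner_product(br, g_c, grid300)
        assert br_payoff - sol.lambda_c <= 1e-8


class TestReplicatorOracle:
    def test_consumer_only_closed_form(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.0)
        rep = hg.replicator_solve(state, table_params, env, grid21,
                                  seed=3, tol=1e-10)
        sigma, _ = consumer_only_closed_form(table_params, env, grid21, 0.5)
        np.testing.assert_allclose(rep.sigma_c, sigma, atol=1e-6)

    def test_nash_is_fixed_point(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(1.0, 0.5)
        sol = hg.solve_nash(state, table_params, env, grid21, tol=1e-12)
        rep = hg.replicator_solve(state, table_params, env, grid21,
                                  init=sol.strategies, tol=1e-9,
                                  max_iters=1, refine=False)
        np.testing.assert_allclose(rep.sigma_c, sol.strategies.sigma_c,
                                   atol=1e-12)
        np.testing.assert_allclose(rep.sigma_p, sol.strategies.sigma_p,
                                   atol=1e-12)

    def test_two_seeds_same_limit(self):
        p = hg.derive_parameters({"K": 3.0, "c": 0.2})
        grid = hg.build_grid(100.0, 11)
        env = hg.environment_profiles(p, grid)
        state = hg.PopulationState(0.5, 0.02)
        rep1 = hg.replicator_solve(state, p, env, grid, seed=1, tol=1e-9)
        rep2 = hg.replicator_solve(state, p, env, grid, seed=2, tol=1e-9)
        np.testing.assert_allclose(rep1.sigma_c, rep2.sigma_c, atol=1e-6)
        np.testing.assert_allclose(rep1.sigma_p, rep2.sigma_p, atol=1e-6)

    def test_nonconvergence_raises(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(1.0, 1.0)
        with pytest.raises(hg.OracleFailureError):
            hg.replicator_solve(state, table_params, env, grid21,
                                max_iters=2, tol=1e-12, refine=False,
                                seed=0)

    def test_invalid_step(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        with pytest.raises(ValueError):
            hg.replicator_solve(hg.PopulationState(1.0, 1.0), table_params,
                                env, grid21, step=0.0)


class TestSolverProperties:
    def test_oracle_equivalence_random_configs(self):
        rng = np.random.default_rng(2024)
        failures = []
        for _ in range(10):
            config = {
                "K": float(rng.uniform(0.5, 40.0)),
                "c": float(rng.uniform(0.0, 1.0)),
            }
            N_c = float(rng.uniform(0.05, 1.0))
            N_p = float(rng.uniform(0.001, 0.1))
            p = hg.derive_parameters(config)
            for n in (3, 5, 11):
                grid = hg.build_grid(100.0, n)
                env = hg.environment_profiles(p, grid)
                state = hg.PopulationState(N_c, N_p)
                sol = hg.solve_nash(state, p, env, grid, tol=1e-11)
                rep = hg.replicator_solve(state, p, env, grid, seed=1,
                                          tol=1e-9, max_iters=2000)
                err = max(
                    np.max(np.abs(rep.sigma_c - sol.strategies.sigma_c)),
                    np.max(np.abs(rep.sigma_p - sol.strategies.sigma_p)))
                if err > 1e-6:
                    failures.append((config, N_c, N_p, n, err))
        assert not failures, failures

    def test_uniqueness_multistart(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.05)
        rng = np.random.default_rng(1234)
        sols = []
        for _ in range(5):
            sc = random_density(rng, grid21)
            sp = random_density(rng, grid21)
            init = wrap_candidate(sc, sp, 0.0, 0.0, state, table_params,
                                  env, grid21)
            sol = hg.solve_nash(state, table_params, env, grid21,
                                init=init, tol=1e-10)
            sols.append(sol.strategies)
        ref = sols[0]
        for other in sols[1:]:
            np.testing.assert_allclose(other.sigma_c, ref.sigma_c,
                                       atol=1e-6)
            np.testing.assert_allclose(other.sigma_p, ref.sigma_p,
                                       atol=1e-6)

    def test_solution_map_continuity(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.05)
        base = hg.solve_nash(state, table_params, env, grid21, tol=1e-10)
        pert = hg.PopulationState(0.505, 0.05)
        moved = hg.solve_nash(pert, table_params, env, grid21, tol=1e-10)
        delta = np.max(np.abs(moved.strategies.sigma_c
                              - base.strategies.sigma_c))
        assert delta < 0.5  # bounded response to a 1% perturbation

    def test_converged_solutions_are_densities(self, table_params, grid21):
        env = hg.environment_profiles(table_params, grid21)
        rng = np.random.default_rng(99)
        for _ in range(5):
            state = hg.PopulationState(rng.uniform(0.05, 1.0),
                                       rng.uniform(0.001, 0.2))
            sol = hg.solve_nash(state, table_params, env, grid21,
                                tol=1e-10)
            ok_c, _ = hg.is_probability_density(sol.strategies.sigma_c,
                                                grid21, tol=1e-8)
            ok_p, _ = hg.is_probability_density(sol.strategies.sigma_p,
                                                grid21, tol=1e-8)
            assert ok_c and ok_p

    def test_solution_serializes(self, table_params, grid21):
        import json

        env = hg.environment_profiles(table_params, grid21)
        state = hg.PopulationState(0.5, 0.05)
        sol = hg.solve_nash(state, table_params, env, grid21, tol=1e-10)
        payload = json.loads(sol.to_json())
        assert payload["residuals"]["converged"] is True
        frame = sol.to_frame(state, table_params, env, grid21)
        assert list(frame.columns) == ["depth", "sigma_c", "sigma_p",
                                       "g_c", "g_p"]
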