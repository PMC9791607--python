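"""Monte Carlo engine: update-rule tables, conservation, determinism, observables."""

import numpy as np
import pytest

from taseptools import (
    LatticeState,
    init_state,
    measure_nn_correlation,
    run_simulation,
    step_parallel,
    step_random_sequential,
    validate_params,
)


def params_open(L=5, alpha=0.5, beta=0.5, update="rs"):
    return validate_params({"L": L, "alpha": alpha, "beta": beta, "update": update})


def params_ring(L=6, N=3, update="rs"):
    return validate_params({"L": L, "boundary": "periodic", "N": N, "update": update})


class TestInitState:
    def test_open_starts_empty(self):
        state = init_state(params_open(L=5))
        assert state.tau.tolist() == [0, 0, 0, 0, 0]

    def test_ring_places_exactly_n_particles(self, rng):
        state = init_state(params_ring(L=6, N=3), rng)
        assert int(state.tau.sum()) == 3

    def test_same_seed_same_placement(self):
        p = params_ring(L=20, N=7)
        a = init_state(p, np.random.default_rng(9))
        b = init_state(p, np.random.default_rng(9))
        assert np.array_equal(a.tau, b.tau)


class TestRandomSequentialStep:
    def test_bulk_hop_moves_particle_forward(self, scripted_rng):
        p = params_open(L=2, alpha=0.0, beta=0.0)
        state = LatticeState(np.array([1, 0]))
        new = step_random_sequential(state, p, scripted_rng(integers=[0]))
        assert new.tau.tolist() == [0, 1]
        assert new.time == pytest.approx(0.5)

    def test_entry_requires_probability_draw(self, scripted_rng):
        p = params_open(L=3, alpha=0.4, beta=0.0)
        state = LatticeState(np.zeros(3))
        hit = step_random_sequential(state, p, scripted_rng(integers=[0], randoms=[0.39]))
        miss = step_random_sequential(state, p, scripted_rng(integers=[0], randoms=[0.41]))
        assert hit.tau.tolist() == [1, 0, 0]
        assert miss.tau.tolist() == [0, 0, 0]

    def test_exit_from_last_site(self, scripted_rng):
        p = params_open(L=3, alpha=0.0, beta=0.8)
        state = LatticeState(np.array([0, 0, 1]))
        new = step_random_sequential(state, p, scripted_rng(integers=[2], randoms=[0.5]))
        assert new.tau.tolist() == [0, 0, 0]

    def test_ring_wraps_last_site_to_first(self, scripted_rng):
        p = params_ring(L=3, N=1)
        state = LatticeState(np.array([0, 0, 1]))
        new = step_random_sequential(state, p, scripted_rng(integers=[2]))
        assert new.tau.tolist() == [1, 0, 0]

    def test_full_ring_is_frozen(self, scripted_rng):
        p = params_ring(L=4, N=4)
        state = LatticeState(np.ones(4))
        for i in range(4):
            new = step_random_sequential(state, p, scripted_rng(integers=[i]))
            assert new.tau.tolist() == [1, 1, 1, 1]

    def test_exclusion_blocks_hop(self, scripted_rng):
        p = params_open(L=3, alpha=0.0, beta=0.0)
        state = LatticeState(np.array([1, 1, 0]))
        new = step_random_sequential(state, p, scripted_rng(integers=[0]))
        assert new.tau.tolist() == [1, 1, 0]


class TestParallelStep:
    def test_blocked_and_free_particles_resolved_from_time_t(self, scripted_rng):
        # site-2 particle moves; site-1 particle is blocked because site 2 was
        # occupied at time t, even though it empties during the step
        p = params_open(L=3, alpha=0.0, beta=0.0, update="parallel")
        state = LatticeState(np.array([1, 1, 0]))
        new = step_parallel(state, p, scripted_rng(randoms=[0.99, 0.99]))
        assert new.tau.tolist() == [1, 0, 1]
        assert new.time == pytest.approx(1.0)

    def test_deterministic_injection_from_empty(self, scripted_rng):
        p = params_open(L=2, alpha=1.0, beta=1.0, update="parallel")
        state = LatticeState(np.array([0, 0]))
        new = step_parallel(state, p, scripted_rng(randoms=[0.5, 0.5]))
        assert new.tau.tolist() == [1, 0]

    def test_two_site_cycle_at_unit_rates(self, scripted_rng):
        p = params_open(L=2, alpha=1.0, beta=1.0, update="parallel")
        state = LatticeState(np.array([1, 0]))
        for expected in ([0, 1], [1, 0], [0, 1], [1, 0]):
            state = step_parallel(state, p, scripted_rng(randoms=[0.5, 0.5]))
            assert state.tau.tolist() == expected

    def test_ring_wrap(self, scripted_rng):
        p = params_ring(L=3, N=1, update="parallel")
        state = LatticeState(np.array([0, 0, 1]))
        new = step_parallel(state, p, scripted_rng())
        assert new.tau.tolist() == [1, 0, 0]

    def test_vacated_site_not_entered_same_step(self, scripted_rng):
        # site 1 occupied at t: its particle leaves, but injection is forbidden
        p = params_open(L=2, alpha=1.0, beta=0.0, update="parallel")
        state = LatticeState(np.array([1, 0]))
        new = step_parallel(state, p, scripted_rng(randoms=[0.5, 0.5]))
        assert new.tau.tolist() == [0, 1]


class TestRunSimulation:
    def test_replay_is_bit_identical(self):
        p = params_open(L=12, alpha=0.3, beta=0.7)
        a = run_simulation(p, 2000, seed=42)
        b = run_simulation(p, 2000, seed=42)
        assert np.array_equal(a.rho, b.rho)
        assert np.array_equal(a.J_bond, b.J_bond)
        assert np.array_equal(a.final_state.tau, b.final_state.tau)

    def test_ring_conserves_particles(self):
        p = params_ring(L=10, N=4)
        r = run_simulation(p, 3000, seed=5)
        assert int(r.final_state.tau.sum()) == 4
        # spatial mean of time-averaged density is exactly N/L on a ring
        assert r.rho.mean() == pytest.approx(0.4, abs=1e-12)

    def test_no_measured_sweeps_is_an_error(self):
        with pytest.raises(ValueError, match="burn-in"):
            run_simulation(params_open(), 10, burn_in=10)

    def test_ld_phase_bulk_density(self):
        p = params_open(L=200, alpha=0.2, beta=0.6)
        r = run_simulation(p, 20_000, seed=11)
        bulk = r.rho[60:140].mean()
        assert bulk == pytest.approx(0.2, abs=0.02)

    def test_current_continuity_open_chain(self):
        p = params_open(L=30, alpha=0.4, beta=0.9)
        r = run_simulation(p, 60_000, seed=17, n_batches=40)
        currents = np.concatenate([[r.J_enter], r.J_bond, [r.J_exit]])
        ses = np.concatenate([[r.J_enter_se], r.J_bond_se, [r.J_exit_se]])
        grand = currents.mean()
        z = (currents - grand) / ses
        assert np.abs(z).max() < 4.0

    def test_rs_ring_current_matches_exact_combinatorics(self):
        # uniform stationary measure gives J = N(L-N)/(L(L-1))
        L, N = 20, 8
        p = params_ring(L=L, N=N)
        r = run_simulation(p, 50_000, seed=23, n_batches=40)
        expected = N * (L - N) / (L * (L - 1))
        se = r.batch_J_bond.mean(axis=1).std(ddof=1) / np.sqrt(r.n_batches)
        assert abs(r.J_mean - expected) < 3 * se + 1e-4


class TestNearestNeighbourCorrelation:
    def test_frozen_full_ring_has_zero_correlation(self):
        p = params_ring(L=6, N=6)
        r = run_simulation(p, 500, seed=0)
        assert np.allclose(measure_nn_correlation(r), 0.0)

    def test_rs_ring_matches_uniform_measure(self):
        # <t_i t_{i+1}> = N(N-1)/(L(L-1)) = 0.2 under the uniform measure,
        # so C = 0.2 - 0.25 = -0.05
        p = params_ring(L=6, N=3)
        r = run_simulation(p, 200_000, seed=3)
        assert np.allclose(measure_nn_correlation(r), -0.05, atol=0.01)

    def test_parallel_half_filled_ring_is_maximally_anticorrelated(self):
        # the parallel rule orders the half-filled ring into the alternating
        # pattern: <t_i t_{i+1}> = 0 while <t_i> = 1/2, so C = -1/4
        p = params_ring(L=10, N=5, update="parallel")
        r = run_simulation(p, 5000, burn_in=1000, seed=8)
        assert np.allclose(measure_nn_correlation(r), -0.25, atol=1e-3)
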