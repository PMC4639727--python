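import numpy as np
import pytest

from crowdsolve import (
    IterationOutcome,
    ModelParams,
    apply_iteration_scores,
    apply_selection,
    init_population,
    run_game,
    run_iteration,
    run_round,
    sample_roles,
    solve_probability,
    spawn_rng,
)

from conftest import make_population


class TestSampleRoles:
    def test_certain_collaboration(self):
        assert sample_roles(np.ones(8), spawn_rng(1)).all()

    def test_certain_individualism(self):
        assert not sample_roles(np.zeros(8), spawn_rng(1)).any()

    def test_binomial_mean_at_half(self):
        rng = spawn_rng(3)
        counts = [sample_roles(np.full(10, 0.5), rng).sum() for _ in range(10_000)]
        se = np.sqrt(10 * 0.25 / len(counts))
        assert abs(np.mean(counts) - 5.0) < 3 * se


class TestSolveProbability:
    def test_collectivist_solves_at_simplicity(self):
        assert solve_probability("collectivist", 0.7) == 0.7

    def test_individualist_boundary_and_power(self):
        assert solve_probability("individualist", 1.0, G=7) == 1.0
        assert solve_probability("individualist", 0.5, G=3) == pytest.approx(0.125)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            solve_probability("individualist", 0.5, G=0)
        with pytest.raises(ValueError):
            solve_probability("individualist", 0.5)


class TestApplyIterationScores:
    def test_lone_individualist_success_without_collectivists(self):
        # no collectivist solves: capacity stays, only the solver's private G
        pop = make_population([0.5, 0.5, 0.5, 0.5])
        outcome = IterationOutcome(
            collectivist=np.array([[True, True, False, False]]),
            gain=np.array([[0, 0, 6, 3]]),
            solved=np.array([[False, False, True, False]]),
        )
        apply_iteration_scores(pop, outcome)
        assert pop.capacity[0] == 0
        np.testing.assert_allclose(pop.fitness[0], [0, 0, 6, 0])

    def test_single_solver_pays_updated_capacity_to_both(self):
        pop = make_population([0.5, 0.5])
        outcome = IterationOutcome(
            collectivist=np.array([[True, True]]),
            gain=np.array([[0, 0]]),
            solved=np.array([[True, False]]),
        )
        apply_iteration_scores(pop, outcome)
        assert pop.capacity[0] == 1
        np.testing.assert_allclose(pop.fitness[0], [1.0, 1.0])

    def test_two_solvers_share_and_private_gain_stack(self):
        # capacity 4 -> 5; two solvers pay 5 each to every member; the
        # solving individualist additionally keeps its G = 9
        pop = make_population([0.5] * 4, capacity=[4])
        outcome = IterationOutcome(
            collectivist=np.array([[True, True, True, False]]),
            gain=np.array([[0, 0, 0, 9]]),
            solved=np.array([[True, True, False, True]]),
        )
        apply_iteration_scores(pop, outcome)
        assert pop.capacity[0] == 5
        np.testing.assert_allclose(pop.fitness[0], [10.0, 10.0, 10.0, 19.0])

    def test_inconsistent_outcome_rejected(self):
        pop = make_population([0.5, 0.5])
        outcome = IterationOutcome(
            collectivist=np.array([[True, True]]),
            gain=np.array([[0, 0]]),
            solved=np.array([[True, False]]),
        )
        outcome.solver_count = np.array([2])
        with pytest.raises(RuntimeError):
            apply_iteration_scores(pop, outcome)


class TestRunIteration:
    def test_vanishing_simplicity_freezes_all_scores(self):
        params = ModelParams(N=20, S=5, R=1e-300, seed=1)
        pop = init_population(params, spawn_rng(1))
        for _ in range(50):
            run_iteration(pop, params, spawn_rng(2))
        assert not pop.fitness.any()
        assert not pop.capacity.any()

    def test_certain_solving_full_collaboration(self):
        # all p=1, R=1, S=5: capacity ticks every iteration and every
        # player gains s * Sigma_new = 5 * Sigma_new
        params = ModelParams(N=5, S=5, R=1.0, seed=1)
        pop = make_population([1.0] * 5)
        total = 0.0
        for t in range(1, 11):
            run_iteration(pop, params, spawn_rng(0, t))
            total += 5 * t
            assert pop.capacity[0] == t
            np.testing.assert_allclose(pop.fitness[0], total)

    def test_same_seed_gives_identical_outcome(self):
        params = ModelParams(N=20, S=5, R=0.5, seed=1)
        pops, outs = [], []
        for _ in range(2):
            pop = init_population(params, spawn_rng(4))
            _, out = run_iteration(pop, params, spawn_rng(5))
            pops.append(pop)
            outs.append(out)
        np.testing.assert_array_equal(pops[0].fitness, pops[1].fitness)
        np.testing.assert_array_equal(outs[0].solved, outs[1].solved)

    def test_solver_count_consistency(self):
        params = ModelParams(N=30, S=10, R=0.7, seed=1)
        pop = init_population(params, spawn_rng(6))
        _, out = run_iteration(pop, params, spawn_rng(7))
        np.testing.assert_array_equal(
            out.solver_count, (out.collectivist & out.solved).sum(axis=1)
        )
        np.testing.assert_array_equal(out.capacity_incremented, out.solver_count >= 1)


class TestRunRound:
    def test_empty_round_scores_nothing(self):
        params = ModelParams(N=10, S=5, R=0.5, iterations_per_round=0, seed=1)
        pop = init_population(params, spawn_rng(1))
        res = run_round(pop, params, spawn_rng(2))
        assert res.mean_fitness == 0.0
        assert not res.per_group_capacity.any()

    def test_certain_solving_saturates_capacity(self):
        params = ModelParams(N=10, S=5, R=1.0, iterations_per_round=40, seed=1)
        pop = make_population([[1.0] * 5, [1.0] * 5])
        res = run_round(pop, params, spawn_rng(3))
        np.testing.assert_array_equal(res.per_group_capacity, [40, 40])

    def test_mean_fitness_is_recomputable(self):
        params = ModelParams(N=20, S=5, R=0.6, iterations_per_round=50, seed=1)
        pop = init_population(params, spawn_rng(4))
        res = run_round(pop, params, spawn_rng(5))
        assert res.mean_fitness == pytest.approx(pop.fitness.mean())

    def test_single_iteration_round_matches_run_iteration_bitwise(self):
        params = ModelParams(N=20, S=5, R=0.6, iterations_per_round=1, seed=1)
        pop_a = init_population(params, spawn_rng(6))
        pop_b = pop_a.copy()
        run_round(pop_a, params, spawn_rng(8))
        run_iteration(pop_b, params, spawn_rng(8))
        np.testing.assert_array_equal(pop_a.fitness, pop_b.fitness)
        np.testing.assert_array_equal(pop_a.capacity, pop_b.capacity)

    def test_capacity_recount_matches_instrumented_iterations(self):
        # capacity equals the number of iterations with >= 1 solving
        # collectivist, recounted through the per-iteration path
        params = ModelParams(N=12, S=4, R=0.4, iterations_per_round=80, seed=1)
        pop = init_population(params, spawn_rng(9))
        recount = np.zeros(pop.n_groups, dtype=int)
        rng = spawn_rng(10)
        for _ in range(params.iterations_per_round):
            _, out = run_iteration(pop, params, rng)
            recount += out.capacity_incremented
        np.testing.assert_array_equal(pop.capacity, recount)

    def test_fitness_never_decreases_within_round(self):
        params = ModelParams(N=12, S=4, R=0.5, seed=1)
        pop = init_population(params, spawn_rng(11))
        rng = spawn_rng(12)
        prev = pop.fitness.copy()
        for _ in range(60):
            run_iteration(pop, params, rng)
            assert (pop.fitness >= prev).all()
            prev = pop.fitness.copy()


class TestApplySelection:
    def test_equal_fitness_replaces_nobody(self):
        params = ModelParams(N=10, S=5, R=0.5, seed=1)
        pop = make_population([[0.1] * 5, [0.9] * 5])
        p_before = pop.p.copy()
        apply_selection(pop, params, spawn_rng(1))
        np.testing.assert_array_equal(pop.p, p_before)

    def test_replacement_count_is_fraction_of_population(self):
        params = ModelParams(N=10, S=5, R=0.5, replacement_fraction=0.2, seed=1)
        pop = make_population([[0.5] * 5, [0.5] * 5])
        pop.fitness[0, :] = 0.0  # five players strictly below the mean
        pop.fitness[1, :] = 10.0
        p_before = pop.p.copy()
        apply_selection(pop, params, spawn_rng(2))
        assert (pop.p != p_before).sum() == 2  # floor(0.2 * 10) = 2
        assert (pop.p[1] == p_before[1]).all()  # above-mean players survive

    def test_pool_smaller_than_quota(self):
        params = ModelParams(N=10, S=5, R=0.5, replacement_fraction=0.5, seed=1)
        pop = make_population([[0.5] * 5, [0.5] * 5])
        pop.fitness[0, 0] = -0.0  # single below-mean player
        pop.fitness.flat[1:] = 5.0
        p_before = pop.p.copy()
        apply_selection(pop, params, spawn_rng(3))
        assert (pop.p != p_before).sum() == 1

    def test_resets_scores_and_preserves_shape(self):
        params = ModelParams(N=10, S=5, R=0.5, seed=1)
        pop = make_population([[0.5] * 5, [0.5] * 5], capacity=[3, 7])
        pop.fitness[:] = np.arange(10).reshape(2, 5)
        apply_selection(pop, params, spawn_rng(4))
        assert pop.p.shape == (2, 5)
        assert not pop.fitness.any()
        assert not pop.capacity.any()

    def test_survivors_keep_exact_p(self):
        params = ModelParams(N=20, S=5, R=0.5, replacement_fraction=0.2, seed=1)
        pop = make_population(np.full((4, 5), 0.5))
        rng = spawn_rng(5)
        pop.fitness[:] = rng.random((4, 5))
        keep = pop.fitness >= pop.fitness.mean()
        p_before = pop.p.copy()
        apply_selection(pop, params, spawn_rng(6))
        assert (pop.p[keep] == p_before[keep]).all()


class TestRunGame:
    def test_seeded_game_is_reproducible(self, tiny_params):
        a = run_game(tiny_params)
        b = run_game(tiny_params)
        assert a.final_mean_p == b.final_mean_p
        assert a.final_mean_fitness == b.final_mean_fitness
        np.testing.assert_array_equal(a.p_distribution, b.p_distribution)

    def test_capacity_bounded_by_iterations(self, tiny_params):
        res = run_game(tiny_params)
        assert (res.final_capacity <= tiny_params.iterations_per_round).all()
        assert 0.0 <= res.final_mean_p <= 1.0

    def test_single_round_game_applies_no_selection(self):
        # without selection the p distribution stays uniform: mean ~ 0.5
        means = []
        for seed in range(20):
            params = ModelParams(N=100, S=10, R=0.9, iterations_per_round=20,
                                 rounds_per_game=1, seed=seed)
            means.append(run_game(params).final_mean_p)
        se = np.sqrt(1 / 12 / (20 * 100))
        assert abs(np.mean(means) - 0.5) < 3 * se

    def test_group_symmetry_across_games(self):
        # equally-sized groups are statistically equivalent: across games,
        # per-group capacities agree within sampling error
        caps = []
        for seed in range(12):
            params = ModelParams(N=20, S=10, R=0.5, iterations_per_round=50,
                                 rounds_per_game=10, seed=seed)
            caps.append(run_game(params).final_capacity)
        caps = np.array(caps, dtype=float)
        diff = caps[:, 0] - caps[:, 1]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * max(se, 1e-9)
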