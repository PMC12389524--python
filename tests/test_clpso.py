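import numpy as np
import pytest

from mixqsar.clpso import (
    SearchSpace,
    assign_exemplars,
    build_estimator,
    clpso_step,
    cv_fitness,
    default_search_space,
    init_swarm,
    learning_probabilities,
    optimize,
    pso_step,
)
from mixqsar.errors import ConfigurationError
from mixqsar.synthetic import SyntheticConfig, make_synthetic_dataset


def sphere(p):
    return float(np.sum(p**2))


def space_1d(lo=-100.0, hi=100.0):
    return SearchSpace([lo], [hi], ("real",), ("x",))


class TestPSOStep:
    def test_zero_randoms_give_pure_inertia(self):
        state = init_swarm(sphere, space_1d(), n_particles=4, seed=0)
        v_before = state.velocities.copy()
        pso_step(state, sphere, rand1=0.0, rand2=0.0)
        np.testing.assert_allclose(
            state.velocities[np.abs(state.velocities) > 0],
            (state.inertia * v_before)[np.abs(state.velocities) > 0],
        )

    def test_forced_arithmetic_example(self):
        """omega=0.5, V=1, c1=c2=1, rand=1, pbest=2, gbest=3, X=0 -> V'=5.5."""
        state = init_swarm(sphere, space_1d(), n_particles=1, seed=0)
        state.inertia, state.c1, state.c2 = 0.5, 1.0, 1.0
        state.velocities[:] = 1.0
        state.positions[:] = 0.0
        state.pbest[:] = 2.0
        state.pbest_fitness[:] = sphere(np.array([2.0]))
        state.gbest[:] = 3.0
        state.gbest_fitness = sphere(np.array([3.0]))
        pso_step(state, sphere, rand1=1.0, rand2=1.0)
        assert state.velocities[0, 0] == pytest.approx(0.5 + 2.0 + 3.0)
        assert state.positions[0, 0] == pytest.approx(5.5)

    def test_converges_on_1d_sphere(self):
        best, best_f, _ = optimize(
            sphere, space_1d(-10, 10), n_particles=20, max_evaluations=4000,
            seed=3, algorithm="pso",
        )
        assert abs(best[0]) <= 1e-3


class TestAssignExemplars:
    def test_pc_zero_forces_exactly_one_foreign_dimension(self):
        space = SearchSpace([-1.0] * 4, [1.0] * 4, ("real",) * 4, tuple("abcd"))
        state = init_swarm(sphere, space, n_particles=5, seed=1)
        assign_exemplars(state, learning_probs=np.zeros(5), particles=np.arange(5))
        for i in range(5):
            foreign = state.exemplars[i] != i
            assert foreign.sum() == 1

    def test_pc_one_with_two_particles_follows_the_other(self):
        space = space_1d()
        state = init_swarm(sphere, space, n_particles=2, seed=2)
        assign_exemplars(state, learning_probs=np.ones(2), particles=np.arange(2))
        assert state.exemplars[0, 0] == 1
        assert state.exemplars[1, 0] == 0

    def test_non_self_rate_matches_learning_probability(self):
        """Monte-Carlo: with Pc=0.5 about half of all dimension assignments
        should be foreign (binomial check over 10^4 draws)."""
        space = SearchSpace([-1.0] * 10, [1.0] * 10, ("real",) * 10, tuple("abcdefghij"))
        state = init_swarm(sphere, space, n_particles=50, seed=3)
        foreign = 0
        total = 0
        for _ in range(20):
            assign_exemplars(state, learning_probs=np.full(50, 0.5),
                             particles=np.arange(50))
            foreign += int((state.exemplars != np.arange(50)[:, None]).sum())
            total += state.exemplars.size
        assert foreign / total == pytest.approx(0.5, abs=0.02)

    def test_learning_probability_schedule_spans_005_to_05(self):
        pc = learning_probabilities(20)
        assert pc[0] == pytest.approx(0.05)
        assert pc[-1] == pytest.approx(0.5)
        assert np.all(np.diff(pc) > 0)


class TestCLPSOStep:
    def test_zero_rand_is_pure_inertia(self):
        state = init_swarm(sphere, space_1d(), n_particles=4, seed=0)
        v_before = state.velocities.copy()
        x_before = state.positions.copy()
        clpso_step(state, sphere, rand=0.0)
        np.testing.assert_allclose(state.velocities, state.inertia * v_before)
        np.testing.assert_allclose(state.positions, x_before + state.inertia * v_before)

    def test_single_particle_at_pbest_with_zero_velocity_is_fixed_point(self):
        state = init_swarm(sphere, space_1d(), n_particles=1, seed=0)
        state.positions[:] = state.pbest.copy()
        state.velocities[:] = 0.0
        x_before = state.positions.copy()
        clpso_step(state, sphere)
        np.testing.assert_array_equal(state.positions, x_before)

    def test_median_fitness_on_5d_bowl(self):
        """Seeded 5-D quadratic bowl: median final gbest over 10 seeds
        reaches 1e-2 once the swarm has a converged budget."""
        space = SearchSpace([-5.0] * 5, [5.0] * 5, ("real",) * 5, tuple("abcde"))
        f = lambda p: float(np.sum((p - 1.0) ** 2))  # noqa: E731
        finals = [
            optimize(f, space, n_particles=10, max_evaluations=1500, seed=s)[1]
            for s in range(10)
        ]
        assert np.median(finals) <= 1e-2


class TestOptimize:
    def test_recovers_known_point_within_budget(self):
        """2-D distance-to-target fitness: median recovery below 1e-3 in
        500 evaluations over 10 seeds."""
        target = np.array([1.3, -2.1])
        space = SearchSpace([-5.0] * 2, [5.0] * 2, ("real",) * 2, ("x", "y"))
        f = lambda p: float(np.sum((p - target) ** 2))  # noqa: E731
        errors = [
            np.linalg.norm(
                optimize(f, space, n_particles=4, max_evaluations=500, seed=s)[0] - target
            )
            for s in range(10)
        ]
        assert np.median(errors) <= 1e-3

    def test_budget_equal_to_swarm_returns_best_initial_sample(self):
        space = space_1d(-10, 10)
        best, best_f, trace = optimize(sphere, space, n_particles=8, max_evaluations=8, seed=4)
        assert len(trace) == 8
        assert best_f == pytest.approx(trace.min())

    def test_gbest_trace_is_monotone_and_positions_in_bounds(self):
        space = SearchSpace([-3.0] * 3, [3.0] * 3, ("real",) * 3, ("a", "b", "c"))
        best, best_f, trace = optimize(sphere, space, n_particles=10,
                                       max_evaluations=400, seed=9)
        running = np.minimum.accumulate(trace)
        assert np.all(np.diff(running) <= 0)
        assert np.all(best >= space.lower) and np.all(best <= space.upper)

    def test_integer_dimension_recovers_exhaustively_checkable_optimum(self):
        space = SearchSpace([1.0, -5.0], [10.0, 5.0], ("integer", "real"), ("k", "x"))
        f = lambda p: float((p[0] - 7.0) ** 2 + p[1] ** 2)  # noqa: E731
        best, _, _ = optimize(f, space, n_particles=8, max_evaluations=400, seed=0)
        assert best[0] == 7.0  # integer dims are integral in the reported best

    def test_non_finite_fitness_is_penalized_not_fatal(self):
        calls = {"n": 0}

        def nasty(p):
            calls["n"] += 1
            return np.nan if calls["n"] % 3 == 0 else sphere(p)

        best, best_f, _ = optimize(nasty, space_1d(-5, 5), n_particles=6,
                                   max_evaluations=120, seed=2)
        assert np.isfinite(best_f)

    def test_clpso_beats_plain_pso_on_multimodal_wells(self):
        """Sum of cosine wells (Rastrigin), 5-D, 20 seeds: comprehensive
        learning should preserve enough diversity to beat plain PSO in the
        median."""
        space = SearchSpace([-5.0] * 5, [5.0] * 5, ("real",) * 5, tuple("abcde"))

        def rastrigin(p):
            return float(np.sum(p**2 - 10 * np.cos(2 * np.pi * p) + 10))

        cl = np.median([
            optimize(rastrigin, space, 15, 8000, seed=s, algorithm="clpso")[1]
            for s in range(20)
        ])
        ps = np.median([
            optimize(rastrigin, space, 15, 8000, seed=s, algorithm="pso")[1]
            for s in range(20)
        ])
        assert cl <= ps


class TestCVFitness:
    @pytest.fixture
    def linear_split_table(self):
        config = SyntheticConfig(
            n_compounds=60, n_informative=2, n_redundant=0, n_noise=1,
            noise_sd=0.0, coefficients=[1.5, -1.0], seed=8,
        )
        table, _ = make_synthetic_dataset(config)
        return table

    def test_published_mixed_svr_position_evaluates(self, linear_split_table):
        space = default_search_space("svr_mixed")
        fitness = cv_fitness("svr_mixed", linear_split_table, space, folds=3, seed=0)
        position = np.array([1.06, 0.01, 800.13, 98.69, 0.01, 3, 0.83, 0.12])
        value = fitness(position)
        assert np.isfinite(value) or value == np.inf  # evaluated, never raises

    def test_deterministic_for_same_position(self, linear_split_table):
        space = default_search_space("svr_mixed")
        fitness = cv_fitness("svr_mixed", linear_split_table, space, folds=3, seed=0)
        position = np.array([1.0, 0.05, 0.5, 0.5, 1.0, 2, 0.3, 0.3])
        assert fitness(position) == fitness(position.copy())

    def test_tuning_beats_untuned_default(self, linear_split_table):
        space = default_search_space("svr_mixed")
        fitness = cv_fitness("svr_mixed", linear_split_table, space, folds=3, seed=0)
        default_position = (space.lower + space.upper) / 2.0
        baseline = fitness(default_position)
        _, tuned, _ = optimize(fitness, space, n_particles=8, max_evaluations=80, seed=1)
        assert tuned < baseline

    def test_infeasible_weights_are_repaired_not_fatal(self, linear_split_table):
        space = default_search_space("svr_mixed")
        fitness = cv_fitness("svr_mixed", linear_split_table, space, folds=3, seed=0)
        position = np.array([1.0, 0.05, 0.5, 0.5, 1.0, 2, 0.9, 0.9])  # alpha+beta=1.8
        assert np.isfinite(fitness(position))

    def test_unknown_family_rejected(self, linear_split_table):
        with pytest.raises(ConfigurationError):
            cv_fitness("svr_rbf", linear_split_table, default_search_space("rf"))

    @pytest.mark.parametrize("family", ["rf", "gbdt", "svr_poly"])
    def test_all_tree_and_poly_families_evaluate(self, linear_split_table, family):
        space = default_search_space(family)
        fitness = cv_fitness(family, linear_split_table, space, folds=3, seed=0)
        mid = (space.lower + space.upper) / 2.0
        assert np.isfinite(fitness(mid))

    def test_estimator_seed_roundtrip_for_rf(self, linear_split_table):
        est = build_estimator("rf", dict(n_trees=5, max_depth=3, min_samples_split=2,
                                         min_samples_leaf=1, seed=3))
        est.fit(linear_split_table.X, linear_split_table.response)
        assert np.isfinite(est.predict(linear_split_table.X[:3])).all()
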