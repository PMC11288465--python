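"""Swarm update rules (hand-arithmetic oracles), elitism, determinism."""

import numpy as np
import pytest
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from swarmfs.data import FeatureMask
from swarmfs.fitness import FitnessEvaluator, FitnessSpec
from swarmfs.optimizers import (
    OptimizerConfig,
    PheromoneState,
    SwarmFeatureSelector,
    aco_construct,
    aco_feature_prob,
    aco_update_pheromone,
    binarize,
    gwo_step,
    optimize,
    pso_step,
    sigmoid,
    wo_step,
)


class TestBinarize:
    def test_sigmoid_midpoint_and_saturation(self):
        assert sigmoid(np.array([0.0]))[0] == 0.5
        assert sigmoid(np.array([10.0]))[0] > 0.99995 - 1e-9

    def test_large_positive_positions_always_selected(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = binarize(np.full(6, 10.0), rng)
            assert mask.n_selected == 6

    def test_all_negative_repaired_to_single_bit(self):
        rng = np.random.default_rng(0)
        pos = np.array([-50.0, -60.0, -40.0, -55.0])
        for _ in range(20):
            mask = binarize(pos, rng)
            assert mask.n_selected == 1
            assert mask.indices()[0] == 2  # the largest transfer value forced on


class TestWhaleStep:
    def test_spiral_at_zero_distance_returns_best(self, scripted_rng):
        best = np.array([1.0, -2.0, 3.0])
        rng = scripted_rng([0.3, 0.9])  # p < 0.5 -> spiral; l = 0.8
        out = wo_step(best.copy(), best, a=1.0, rng=rng)
        np.testing.assert_allclose(out, best)

    def test_spiral_at_l_zero_adds_distance(self, scripted_rng):
        # l = 0: e^0 * cos 0 = 1, so x' = x* + |x* - x|
        x = np.array([0.0, 4.0])
        best = np.array([2.0, 1.0])
        rng = scripted_rng([0.3, 0.5])  # p -> spiral; uniform(−1,1) draw 0.5 -> l = 0
        out = wo_step(x, best, a=1.0, rng=rng, spiral_b=1.0)
        np.testing.assert_allclose(out, best + np.abs(best - x))

    def test_encircle_with_scripted_coefficients(self, scripted_rng):
        # p >= 0.5 -> encircling; r1 = r2 = 0.5, a = 1 gives A = 0, C = 1,
        # so x' = x* exactly (zero attack step about the best)
        x = np.array([3.0, -1.0])
        best = np.array([1.0, 2.0])
        rng = scripted_rng([0.9, 0.5, 0.5, 0])
        out = wo_step(x, best, a=1.0, rng=rng, others=[x])
        np.testing.assert_allclose(out, best)


class TestGreyWolfStep:
    def test_a_zero_returns_mean_of_leaders(self):
        rng = np.random.default_rng(0)
        leaders = [np.array([2.0, 0.0]), np.array([0.0, 2.0]), np.array([1.0, 1.0])]
        out = gwo_step(np.array([5.0, 5.0]), leaders, a=0.0, rng=rng)
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_scripted_single_leader_arithmetic(self, scripted_rng):
        # r1 = r2 = 0.5, a = 1: A = 0, C = 1, D = |2 - 0| = 2, candidate = 2
        rng = scripted_rng([0.5, 0.5])
        out = gwo_step(np.array([0.0]), [np.array([2.0])], a=1.0, rng=rng)
        np.testing.assert_allclose(out, [2.0])

    def test_no_leaders_rejected(self):
        with pytest.raises(ValueError):
            gwo_step(np.zeros(2), [], a=1.0, rng=np.random.default_rng(0))


class TestParticleStep:
    def test_degenerate_coefficients_freeze_particle(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, 2.0])
        v, x2 = pso_step(x, np.array([0.3, -0.3]), x + 1, x - 1, 0.0, 0.0, 0.0, 6.0, rng)
        np.testing.assert_allclose(v, 0.0)
        np.testing.assert_allclose(x2, x)

    def test_at_both_attractors_velocity_is_inertia_only(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0])
        v, _ = pso_step(x, np.array([0.4]), x, x, 0.5, 2.0, 2.0, 6.0, rng)
        np.testing.assert_allclose(v, [0.2])

    def test_scripted_hand_arithmetic(self, scripted_rng):
        # v' = 0.5*0.1 + 1*0.5*0.2 + 1*0.5*0.4 = 0.35; x' = x + 0.35
        rng = scripted_rng([0.5, 0.5])
        x = np.array([1.0])
        v, x2 = pso_step(x, np.array([0.1]), x + 0.2, x + 0.4, 0.5, 1.0, 1.0, 6.0, rng)
        np.testing.assert_allclose(v, [0.35])
        np.testing.assert_allclose(x2, [1.35])

    def test_velocity_clamp(self):
        rng = np.random.default_rng(0)
        x = np.zeros(1)
        v, _ = pso_step(x, np.zeros(1), x + 100, x + 100, 0.9, 2.0, 2.0, 6.0, rng)
        assert abs(v[0]) <= 6.0


class TestAntColony:
    def test_probability_normalization_and_symmetry(self):
        tau = np.ones(4)
        eta = np.ones(4)
        p = aco_feature_prob(tau, eta, np.array([True] * 4))
        np.testing.assert_allclose(p, 0.25)
        p1 = aco_feature_prob(tau, eta, np.array([False, True, False, False]))
        np.testing.assert_allclose(p1, [0.0, 1.0, 0.0, 0.0])

    def test_route_probability_substitution(self):
        # tau = (2, 1), eta = (1, 1), alpha = beta = 1 -> (2/3, 1/3)
        p = aco_feature_prob(np.array([2.0, 1.0]), np.ones(2), np.array([True, True]))
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aco_feature_prob(np.ones(2), np.ones(2), np.array([False, False]))

    def test_degenerate_stopping_rules(self):
        state = PheromoneState(tau=np.ones(5), eta=np.ones(5))
        rng = np.random.default_rng(0)
        assert aco_construct(state, p_stop=1.0, rng=rng).n_selected == 1
        assert aco_construct(state, p_stop=0.0, rng=rng).n_selected == 5

    def test_construction_frequency_tracks_probability(self):
        tau = np.array([4.0, 2.0, 1.0, 1.0])
        state = PheromoneState(tau=tau, eta=np.ones(4))
        expected = aco_feature_prob(tau, np.ones(4), np.ones(4, dtype=bool))
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            mask = aco_construct(state, p_stop=1.0, rng=rng)
            counts[mask.indices()[0]] += 1
        np.testing.assert_allclose(counts / n, expected, atol=0.02)

    def test_full_evaporation_clamps_to_floor(self):
        state = PheromoneState(tau=np.full(3, 5.0), eta=np.ones(3))
        out = aco_update_pheromone(
            state, [(FeatureMask(bits=np.array([1, 0, 0])), 0.5)], rho=1.0, q=0.0,
            tau_min=0.01, tau_max=10.0,
        )
        np.testing.assert_allclose(out.tau, 0.01)

    def test_best_mask_features_gain_pheromone(self):
        state = PheromoneState(tau=np.ones(3), eta=np.ones(3))
        best = FeatureMask(bits=np.array([1, 1, 0]))
        worse = FeatureMask(bits=np.array([0, 0, 1]))
        out = aco_update_pheromone(state, [(best, 0.1), (worse, 0.9)])
        assert out.tau[0] == out.tau[1] > out.tau[2]

    def test_two_iteration_recursion_matches_hand_computation(self):
        state = PheromoneState(tau=np.ones(2), eta=np.ones(2))
        m1 = FeatureMask(bits=np.array([1, 0]))
        s1 = aco_update_pheromone(state, [(m1, 0.5)], rho=0.2, q=1.0, tau_max=10.0)
        # tau0: 0.8 + 1/(0.5 + 1e-6); tau1: 0.8
        np.testing.assert_allclose(s1.tau, [0.8 + 1.0 / 0.500001, 0.8])
        m2 = FeatureMask(bits=np.array([0, 1]))
        s2 = aco_update_pheromone(s1, [(m2, 0.25)], rho=0.2, q=1.0, tau_max=10.0)
        np.testing.assert_allclose(
            s2.tau, [0.8 * (0.8 + 1.0 / 0.500001), 0.8 * 0.8 + 1.0 / 0.250001]
        )


@pytest.fixture(scope="module")
def quick(small_synthetic):
    table, _ = small_synthetic
    return table


class TestOptimize:
    def test_zero_iterations_returns_valid_initial_best(self, quick):
        cfg = OptimizerConfig(algorithm="WO", population=5, iterations=0, seed=2)
        mask, trace = optimize(quick, FitnessSpec(seed=2), cfg)
        assert 1 <= mask.n_selected <= quick.n_features
        assert len(trace.best_fitness) == 1

    @pytest.mark.parametrize("alg", ["WO", "GWO", "ACO", "PSO"])
    def test_seeded_determinism(self, quick, alg):
        cfg = OptimizerConfig(algorithm=alg, population=4, iterations=5, seed=13)
        m1, t1 = optimize(quick, FitnessSpec(seed=13), cfg)
        m2, t2 = optimize(quick, FitnessSpec(seed=13), cfg)
        np.testing.assert_array_equal(m1.bits, m2.bits)
        assert t1.best_fitness == t2.best_fitness

    @pytest.mark.parametrize("alg", ["WO", "GWO", "ACO", "PSO"])
    def test_returned_fitness_is_trace_minimum(self, quick, alg):
        cfg = OptimizerConfig(algorithm=alg, population=4, iterations=8, seed=5)
        spec = FitnessSpec(seed=5)
        mask, trace = optimize(quick, spec, cfg)
        best = trace.best_fitness
        assert all(a >= b - 1e-15 for a, b in zip(best, best[1:]))
        assert best[-1] == min(best)
        assert FitnessEvaluator(quick, spec)(mask) == pytest.approx(best[-1])

    def test_single_class_rejected(self, quick):
        one = quick.take(np.flatnonzero(quick.labels == quick.labels[0]))
        with pytest.raises(ValueError, match="2 classes"):
            optimize(one, FitnessSpec(), OptimizerConfig(iterations=1))

    def test_whale_spiral_limit(self):
        """As the whale reaches the prey the spiral contracts onto it."""
        best = np.array([0.5, -0.5])
        rng = np.random.default_rng(3)
        for eps in (1e-3, 1e-6, 1e-9):
            out = wo_step(best + eps, best, a=0.0, rng=np.random.default_rng(1))
            assert np.linalg.norm(out - best) <= eps * np.e

    def test_gwo_small_population_uses_available_leaders(self, quick):
        cfg = OptimizerConfig(algorithm="GWO", population=2, iterations=2, seed=0)
        mask, _ = optimize(quick, FitnessSpec(seed=0), cfg)
        assert mask.n_selected >= 1

    def test_trace_evaluation_count(self, quick):
        cfg = OptimizerConfig(algorithm="PSO", population=3, iterations=4, seed=1)
        _, trace = optimize(quick, FitnessSpec(seed=1), cfg)
        assert trace.n_evaluations[-1] == 3 * 5  # population x (init + iterations)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            OptimizerConfig(algorithm="simulated-annealing")
        with pytest.raises(ValueError):
            OptimizerConfig(population=0)


class TestSelectorEstimator:
    def test_fit_transform_and_support(self, small_synthetic):
        table, _ = small_synthetic
        sel = SwarmFeatureSelector(
            algorithm="PSO", n_agents=4, n_iterations=3, random_state=0
        )
        xt = sel.fit_transform(table.values, table.labels.astype(str))
        assert xt.shape == (table.n_samples, sel.mask_.n_selected)
        assert sel.get_support().sum() == sel.mask_.n_selected

    def test_composes_in_sklearn_pipeline(self, small_synthetic):
        table, _ = small_synthetic
        pipe = Pipeline(
            [
                ("fs", SwarmFeatureSelector(n_agents=3, n_iterations=2, random_state=1)),
                ("svm", SVC(kernel="linear")),
            ]
        )
        pipe.fit(table.values, table.labels.astype(str))
        assert pipe.score(table.values, table.labels.astype(str)) > 0.5

    def test_get_params_round_trip(self):
        sel = SwarmFeatureSelector(algorithm="GWO", n_iterations=7)
        clone_params = SwarmFeatureSelector(**sel.get_params()).get_params()
        assert clone_params == sel.get_params()
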