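"""Optimizer unit and property tests: chaotic map, spiral operator, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cafrisk.optimizer import (
    OptimizerConfig,
    SearchSpace,
    bernoulli_map_step,
    bernoulli_orbit,
    init_population,
    optimize,
    spiral_flight_mutate,
)


def reference_pso(objective, space, seed, population=30, iterations=200):
    """Independent minimal PSO used as a convergence-order oracle."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(space.lower, space.upper, (population, space.dim))
    v = np.zeros_like(x)
    pbest = x.copy()
    pf = np.array([objective(xi) for xi in x])
    g = int(np.argmin(pf))
    gbest, gf = pbest[g].copy(), pf[g]
    for _ in range(iterations):
        r1, r2 = rng.random(x.shape), rng.random(x.shape)
        v = 0.7 * v + 1.5 * r1 * (pbest - x) + 1.5 * r2 * (gbest - x)
        x = np.clip(x + v, space.lower, space.upper)
        f = np.array([objective(xi) for xi in x])
        better = f < pf
        pbest[better], pf[better] = x[better], f[better]
        g = int(np.argmin(pf))
        if pf[g] < gf:
            gbest, gf = pbest[g].copy(), pf[g]
    return gf


class TestBernoulliMap:
    def test_piecewise_branches(self):
        assert bernoulli_map_step(0.3, 0.4) == pytest.approx(0.5)
        assert bernoulli_map_step(0.7, 0.4) == pytest.approx(0.25)

    @given(st.floats(0.001, 0.999), st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_range_preserved(self, x, lam):
        assert 0.0 < bernoulli_map_step(x, lam) < 1.0

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            bernoulli_map_step(0.0, 0.4)
        with pytest.raises(ValueError):
            bernoulli_map_step(0.5, 1.0)

    def test_orbit_is_mixing_no_empty_decile(self):
        orbit = bernoulli_orbit(0.123456, 0.4, length=1000)
        counts, _ = np.histogram(orbit, bins=10, range=(0, 1))
        assert np.all(counts > 0)


class TestInitPopulation:
    def test_unit_cube_positions_are_orbit_values_in_bounds(self):
        space = SearchSpace.cube(4, 0.0, 1.0)
        pos = init_population(space, 10, 0.4, seed=0)
        assert pos.shape == (10, 4)
        assert np.all((pos > 0) & (pos < 1))

    def test_affine_scaling_into_box(self):
        space = SearchSpace(np.array([-5.0, 0.0]), np.array([5.0, 10.0]))
        pos = init_population(space, 8, 0.4, seed=1)
        assert np.all(pos >= space.lower) and np.all(pos <= space.upper)

    def test_seed_determinism(self):
        space = SearchSpace.cube(3, -2.0, 2.0)
        assert np.array_equal(
            init_population(space, 6, 0.4, seed=9), init_population(space, 6, 0.4, seed=9)
        )

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([1.0]), np.array([1.0]))


class TestSpiralMutation:
    def test_fixed_point_at_best(self):
        space = SearchSpace.cube(3, -2.0, 2.0)
        best = np.array([0.5, -0.5, 1.0])
        assert spiral_flight_mutate(best, best, 1.0, 0.37, space) == pytest.approx(best)

    def test_cosine_zero_collapses_to_best(self):
        space = SearchSpace.cube(2, -5.0, 5.0)
        x = np.array([3.0, -3.0])
        best = np.array([1.0, 1.0])
        assert spiral_flight_mutate(x, best, 1.0, 0.25, space) == pytest.approx(best)

    def test_hand_computed_1d_case(self):
        space = SearchSpace.cube(1, -2.0, 2.0)
        out = spiral_flight_mutate(np.array([-1.0]), np.array([0.0]), 1.0, 0.0, space)
        assert out == pytest.approx([1.0])

    def test_clamped_to_bounds(self):
        space = SearchSpace.cube(1, -1.0, 1.0)
        out = spiral_flight_mutate(np.array([-1.0]), np.array([1.0]), 1.0, 1.0, space)
        assert -1.0 <= out[0] <= 1.0


class TestOptimize:
    @pytest.mark.parametrize("variant", ["igkso", "gkso"])
    def test_2d_sphere_convergence_matches_pso_order(self, variant):
        space = SearchSpace.cube(2, -100.0, 100.0)
        sphere = lambda x: float(np.sum(x * x))
        res = optimize(sphere, space, OptimizerConfig(seed=3, variant=variant))
        assert res.best_fitness < 1e-3
        assert reference_pso(sphere, space, seed=3) < 1e-3

    def test_constant_objective_flat_curve(self):
        space = SearchSpace.cube(3, 0.0, 1.0)
        res = optimize(lambda x: 4.2, space, OptimizerConfig(population=5, iterations=10, seed=0))
        assert res.best_fitness == 4.2
        assert np.all(res.convergence_curve == 4.2)

    def test_curve_monotone_and_consistent_with_best(self):
        space = SearchSpace.cube(4, -5.0, 5.0)
        obj = lambda x: float(np.sum(np.abs(x)) + np.sum(x**2))
        res = optimize(obj, space, OptimizerConfig(population=8, iterations=30, seed=2))
        assert np.all(np.diff(res.convergence_curve) <= 0)
        assert res.convergence_curve[-1] == res.best_fitness
        assert res.best_fitness == pytest.approx(obj(res.best_position))

    def test_every_evaluated_position_inside_box(self):
        space = SearchSpace(np.array([-1.0, 2.0]), np.array([1.0, 3.0]))
        seen = []

        def recording(x):
            seen.append(x.copy())
            return float(np.sum(x * x))

        optimize(recording, space, OptimizerConfig(population=6, iterations=15, seed=4))
        seen = np.array(seen)
        assert np.all(seen >= space.lower - 1e-12) and np.all(seen <= space.upper + 1e-12)

    def test_non_finite_objective_triggers_reset(self):
        space = SearchSpace.cube(2, -1.0, 1.0)

        def spiky(x):
            if abs(x[0]) < 0.2:
                return float("nan")
            return float(np.sum(x * x))

        res = optimize(spiky, space, OptimizerConfig(population=5, iterations=10, seed=1))
        assert np.isfinite(res.best_fitness)

    def test_seed_reproducibility(self):
        space = SearchSpace.cube(3, -2.0, 2.0)
        obj = lambda x: float(np.sum(x**4 - x))
        cfg = OptimizerConfig(population=7, iterations=20, seed=11)
        a = optimize(obj, space, cfg)
        b = optimize(obj, space, cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert np.array_equal(a.convergence_curve, b.convergence_curve)
        assert a.evaluations == b.evaluations

    def test_invalid_configs_rejected_before_evaluation(self):
        calls = []
        with pytest.raises(ValueError):
            OptimizerConfig(population=1)
        with pytest.raises(ValueError):
            OptimizerConfig(iterations=0)
        with pytest.raises(ValueError):
            OptimizerConfig(bernoulli_lambda=1.2)
        with pytest.raises(ValueError):
            OptimizerConfig(variant="pso")
        assert calls == []
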