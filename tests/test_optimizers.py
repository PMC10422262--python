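import numpy as np
import pytest

from mmgsel.optimizers import (
    OptimizerConfig,
    SwarmState,
    csa_acceleration,
    csa_eye_update,
    csa_hunt_update,
    csa_mu,
    csa_search_update,
    goa_decay_coefficient,
    goa_position_update,
    goa_social_force,
    initialize_positions,
    optimize,
    rotate_about,
)

sphere = lambda x: -float(np.sum(np.asarray(x) ** 2))


def _state(positions, cfg, fitnesses=None):
    positions = np.asarray(positions, dtype=float)
    fits = (
        np.asarray(fitnesses, dtype=float)
        if fitnesses is not None
        else np.array([sphere(p) for p in positions])
    )
    best = int(np.argmax(fits))
    return SwarmState(
        positions=positions.copy(),
        velocities=np.zeros_like(positions),
        velocities_prev=np.zeros_like(positions),
        personal_best=positions.copy(),
        personal_best_fitness=fits.copy(),
        global_best=positions[best].copy(),
        global_best_fitness=float(fits[best]),
        iteration=1,
    )


class TestInitialization:
    def test_degenerate_box_collapses(self):
        cfg = OptimizerConfig(dim=3, pop_size=5, lb=0.5, ub=0.5)
        pos = initialize_positions(cfg, np.random.default_rng(0))
        assert np.all(pos == 0.5)

    def test_uniform_law(self):
        cfg = OptimizerConfig(dim=1, pop_size=10_000, lb=0.0, ub=1.0)
        pos = initialize_positions(cfg, np.random.default_rng(0))
        assert 0.45 <= pos.mean() <= 0.55
        assert pos.min() >= 0.0 and pos.max() <= 1.0

    def test_seed_determinism(self):
        cfg = OptimizerConfig(dim=4, pop_size=6, seed=7)
        a = initialize_positions(cfg, np.random.default_rng(7))
        b = initialize_positions(cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestCSAPhases:
    def test_search_no_op_when_coefficients_vanish(self):
        cfg = OptimizerConfig(dim=3, pop_size=4, lb=-5, ub=5, p1=0.0, p2=0.0, pp=0.0)
        state = _state(np.random.default_rng(1).uniform(-5, 5, (4, 3)), cfg)
        before = state.positions.copy()
        csa_search_update(state, cfg, np.random.default_rng(0))
        assert np.allclose(state.positions, before)

    def test_exploration_weight_boundaries(self):
        assert csa_mu(0, 100, alpha=4.0) == pytest.approx(1.0)
        assert csa_mu(100, 100, alpha=1.0) == pytest.approx(np.exp(-1.0))

    def test_exploration_weight_decays(self):
        mus = [csa_mu(t, 50, 4.0) for t in range(0, 51, 10)]
        assert all(a >= b for a, b in zip(mus, mus[1:]))

    def test_rotation_of_unit_vector(self):
        out = rotate_about(np.array([1.0, 0.0]), np.zeros(2), 0, 1, np.pi / 2)
        assert out == pytest.approx([0.0, 1.0], abs=1e-10)

    def test_eye_update_preserves_centroid_distance(self):
        cfg = OptimizerConfig(dim=5, pop_size=8, lb=-100, ub=100, seed=3)
        pos = np.random.default_rng(3).uniform(-1, 1, (8, 5))
        state = _state(pos, cfg)
        center = pos.mean(axis=1, keepdims=True)  # rotation center per individual
        before = np.linalg.norm(pos - center, axis=1)
        csa_eye_update(state, cfg, np.random.default_rng(4))
        after = np.linalg.norm(state.positions - center, axis=1)
        assert np.allclose(before, after, atol=1e-10)

    def test_hunt_inertia_vanishes_at_final_iteration(self):
        cfg = OptimizerConfig(dim=2, pop_size=3, lb=-5, ub=5, max_iter=10, c1=0.0, c2=0.0)
        state = _state(np.ones((3, 2)), cfg)
        state.velocities = np.full((3, 2), 2.0)
        state.iteration = 10
        csa_hunt_update(state, cfg, np.random.default_rng(0))
        assert np.allclose(state.velocities, 0.0)  # omega = 0 at t = T

    def test_hunt_equal_velocities_no_displacement(self):
        # with c1 = c2 = 0 and p_w = 0 the inertia is 1, so v' = v and the
        # kinematic term (v'^2 - v^2)/2a vanishes
        cfg = OptimizerConfig(
            dim=2, pop_size=3, lb=-5, ub=5, max_iter=10, c1=0.0, c2=0.0, p_w=0.0
        )
        state = _state(np.random.default_rng(5).uniform(-1, 1, (3, 2)), cfg)
        state.velocities = np.full((3, 2), 0.7)
        before = state.positions.copy()
        state.iteration = 5
        csa_hunt_update(state, cfg, np.random.default_rng(0))
        assert np.allclose(state.positions, before)

    def test_acceleration_value_at_t10(self):
        assert csa_acceleration(10) == pytest.approx(2590.0 * (1 - np.exp(-1)), rel=1e-6)

    def test_acceleration_floored_at_t1(self):
        assert csa_acceleration(1) == pytest.approx(1e-6)


class TestGOAPieces:
    def test_social_force_at_zero_repels(self):
        assert goa_social_force(0.0, f_attract=0.5) == pytest.approx(-0.5)

    def test_social_force_single_sign_change(self):
        r = np.linspace(1e-6, 4.0, 4000)
        s = goa_social_force(r, 0.5, 1.5)
        assert np.count_nonzero(np.diff(np.sign(s)) != 0) == 1

    def test_social_force_vanishes_at_infinity(self):
        assert goa_social_force(50.0) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "t,expected", [(0, 1.0), (100, 1e-5), (50, 0.500005)]
    )
    def test_decay_coefficient(self, t, expected):
        cfg = OptimizerConfig(dim=1, max_iter=100, c_max=1.0, c_min=1e-5)
        assert goa_decay_coefficient(t, cfg) == pytest.approx(expected)

    def test_identical_positions_move_to_target(self):
        cfg = OptimizerConfig(dim=2, pop_size=2, lb=-5, ub=5)
        pos = np.array([[1.0, 1.0], [1.0, 1.0]])
        state = _state(pos, cfg, fitnesses=[0.0, 0.0])
        state.global_best = np.array([3.0, -2.0])
        goa_position_update(state, cfg, c=0.7)
        assert np.allclose(state.positions, [3.0, -2.0])

    def test_zero_coefficient_jumps_to_target(self):
        cfg = OptimizerConfig(dim=2, pop_size=3, lb=-5, ub=5)
        state = _state(np.random.default_rng(0).uniform(-1, 1, (3, 2)), cfg)
        state.global_best = np.array([0.5, 0.5])
        goa_position_update(state, cfg, c=0.0)
        assert np.allclose(state.positions, [0.5, 0.5])

    def test_mirror_symmetry_preserved(self):
        cfg = OptimizerConfig(dim=1, pop_size=2, lb=-5, ub=5)
        state = _state(np.array([[1.0], [3.0]]), cfg, fitnesses=[0.0, 0.0])
        state.global_best = np.array([2.0])
        goa_position_update(state, cfg, c=0.4)
        a, b = state.positions[:, 0]
        assert a - 2.0 == pytest.approx(-(b - 2.0), abs=1e-12)


class TestOptimize:
    @pytest.mark.parametrize("algorithm", ["csa", "goa"])
    def test_sphere_maximum_found(self, algorithm):
        cfg = OptimizerConfig(dim=10, pop_size=20, max_iter=200, lb=-1, ub=1, seed=0)
        res = optimize(sphere, algorithm, cfg)
        assert res.best_fitness > -0.01

    def test_evaluation_bookkeeping(self):
        cfg = OptimizerConfig(dim=2, pop_size=2, max_iter=1, lb=-1, ub=1)
        res = optimize(sphere, "csa", cfg)
        assert res.evaluations == 2 * (1 + 1)  # init + one iteration

    @pytest.mark.parametrize("algorithm", ["csa", "goa"])
    def test_seed_reproducibility(self, algorithm):
        cfg = OptimizerConfig(dim=5, pop_size=8, max_iter=20, lb=-2, ub=2, seed=11)
        a = optimize(sphere, algorithm, cfg)
        b = optimize(sphere, algorithm, cfg)
        assert np.array_equal(a.fitness_history, b.fitness_history)
        assert np.array_equal(a.best_position, b.best_position)

    @pytest.mark.parametrize("algorithm", ["csa", "goa"])
    def test_history_monotone_and_bounded(self, algorithm):
        cfg = OptimizerConfig(dim=6, pop_size=10, max_iter=50, lb=-3, ub=3, seed=2)
        seen = []
        res = optimize(lambda x: (seen.append(np.asarray(x).copy()), sphere(x))[1],
                       algorithm, cfg)
        assert np.all(np.diff(res.fitness_history) >= 0)
        for pos in seen:
            assert np.all(pos >= -3) and np.all(pos <= 3)

    def test_non_finite_objective_rejected(self):
        cfg = OptimizerConfig(dim=2, pop_size=3, max_iter=1, lb=-1, ub=1)
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: np.nan, "csa", cfg)

    def test_unknown_algorithm_rejected(self):
        cfg = OptimizerConfig(dim=2)
        with pytest.raises(ValueError, match="unknown algorithm"):
            optimize(sphere, "pso", cfg)
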