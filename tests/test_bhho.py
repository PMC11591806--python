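import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcdpipe import BHHOConfig, binarize, escape_energy, levy, optimize, sigmoid_transfer
from bcdpipe.bhho import (dive_target_hard, dive_target_soft, exploration_step,
                          hard_siege_step, init_population, levy_sigma,
                          mean_position, select_phase, soft_siege_step)

LB, UB = -4.0, 4.0


class TestTransferAndBinarization:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.5), (4.0, 0.9820), (-4.0, 0.0180)])
    def test_sigmoid_values(self, x, expected):
        assert sigmoid_transfer(x) == pytest.approx(expected, abs=1e-4)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(-30, 30))
    def test_sigmoid_symmetry(self, x):
        assert sigmoid_transfer(x) + sigmoid_transfer(-x) == pytest.approx(1.0)

    @pytest.mark.parametrize("draw,expected_bit", [(0.3, 1), (0.9, 0)])
    def test_binarize_threshold_at_zero_position(self, draw, expected_bit):
        assert binarize(np.array([0.0]), np.array([draw]))[0] == expected_bit

    def test_binarize_monte_carlo_matches_sigmoid(self):
        rng = np.random.default_rng(11)
        bits = binarize(np.ones(10_000), rng.random(10_000))
        assert bits.mean() == pytest.approx(0.731, abs=0.02)


class TestEnergyAndLevy:
    @pytest.mark.parametrize("g0,j,it_max,expected", [
        (1.0, 0, 100, 2.0),
        (0.7, 100, 100, 0.0),
        (-0.8, 75, 100, -0.4),
    ])
    def test_escape_energy(self, g0, j, it_max, expected):
        assert escape_energy(g0, j, it_max) == pytest.approx(expected)

    def test_energy_envelope_decays_linearly(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g0 = rng.uniform(-1, 1)
            j = int(rng.integers(0, 101))
            assert abs(escape_energy(g0, j, 100)) <= 2 * abs(g0) * (1 - j / 100) + 1e-12

    def test_levy_sigma_at_canonical_exponent(self):
        assert levy_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)

    def test_levy_output_length(self):
        assert len(levy(7, 1.5, np.random.default_rng(0))) == 7


class TestPhaseDispatch:
    @settings(deadline=None, max_examples=200)
    @given(st.floats(-2.5, 2.5), st.floats(0, 1))
    def test_exactly_one_phase_per_draw_pair(self, g, e):
        phase = select_phase(g, e)
        conditions = {
            "exploration": abs(g) >= 1,
            "soft_siege": 1 > abs(g) >= 0.5 and e >= 0.5,
            "hard_siege": abs(g) < 0.5 and e >= 0.5,
            "soft_siege_dive": 1 > abs(g) >= 0.5 and e < 0.5,
            "hard_siege_dive": abs(g) < 0.5 and e < 0.5,
        }
        assert conditions[phase]
        assert sum(conditions.values()) == 1


class TestStepRules:
    def test_exploration_with_zero_r1_returns_random_hawk(self):
        x = np.array([2.0])
        x_rand = np.array([1.0])
        new = exploration_step(x, x_rand, x, x, LB, UB, 0.0, 0.7, 0.0, 0.0, 0.9)
        assert new == pytest.approx([1.0])

    def test_exploration_hand_trace(self):
        new = exploration_step(np.array([2.0]), np.array([1.0]), np.array([0.0]),
                               np.array([0.0]), LB, UB, 0.5, 0.25, 0.0, 0.0, 0.9)
        assert new == pytest.approx([1.0])  # 1 - 0.5*|1 - 2*0.25*2|

    def test_exploration_mean_branch_with_zero_r3(self):
        new = exploration_step(np.array([0.0]), np.array([0.0]), np.array([3.0]),
                               np.array([1.0]), LB, UB, 0.1, 0.1, 0.0, 0.5, 0.2)
        assert new == pytest.approx([2.0])  # prey - mean

    def test_soft_siege_zero_energy_gives_delta(self):
        new = soft_siege_step(np.array([0.5]), np.array([2.0]), 0.0, 1.3, LB, UB)
        assert new == pytest.approx([1.5])

    def test_soft_siege_hand_trace(self):
        new = soft_siege_step(np.array([0.0]), np.array([1.0]), 0.5, 1.0, LB, UB)
        assert new == pytest.approx([0.5])  # 1 - 0.5*|1 - 0|

    def test_hard_siege_zero_energy_keeps_position(self):
        new = hard_siege_step(np.array([1.7]), np.array([0.0]), 0.0, LB, UB)
        assert new == pytest.approx([1.7])

    def test_hard_siege_at_prey_is_fixed_point(self):
        new = hard_siege_step(np.array([2.0]), np.array([2.0]), 0.9, LB, UB)
        assert new == pytest.approx([2.0])

    def test_hard_siege_hand_trace(self):
        new = hard_siege_step(np.array([2.0]), np.array([0.0]), 0.4, LB, UB)
        assert new == pytest.approx([1.2])  # 2 - 0.4*2

    def test_dive_targets_at_zero_energy_equal_prey(self):
        prey = np.array([1.5])
        assert dive_target_soft(np.array([0.0]), prey, 0.0, 1.0, LB, UB) == pytest.approx(prey)
        assert dive_target_hard(np.array([0.3]), prey, 0.0, 1.0, LB, UB) == pytest.approx(prey)

    def test_mean_position_matches_column_mean(self):
        rng = np.random.default_rng(5)
        pos = rng.normal(0, 1, (4, 3))
        assert mean_position(pos) == pytest.approx(pos.mean(axis=0))


def count_zeros(mask: np.ndarray) -> float:
    return float((1 - mask).sum())


class TestOptimize:
    def test_init_population_shapes_and_prey(self):
        pop = init_population(3, BHHOConfig(pop_size=5), seed=0, fitness_fn=count_zeros)
        assert pop.positions.shape == (5, 3)
        assert set(np.unique(pop.positions)) <= {0.0, 1.0}
        assert pop.prey_fitness == pop.fitness.min()

    def test_init_is_deterministic(self):
        a = init_population(4, BHHOConfig(), seed=3, fitness_fn=count_zeros)
        b = init_population(4, BHHOConfig(), seed=3, fitness_fn=count_zeros)
        assert np.array_equal(a.positions, b.positions)

    def test_injected_mask_bounds_initial_prey(self):
        ones = np.ones(6, dtype=np.int8)
        pop = init_population(6, BHHOConfig(pop_size=3), seed=1,
                              fitness_fn=count_zeros, init_masks=[ones])
        assert pop.prey_fitness == 0.0

    def test_reaches_known_optimum_on_bit_counting(self):
        result = optimize(count_zeros, dim=6, config=BHHOConfig(pop_size=10, it_max=50),
                          seed=3)
        assert result.best_fitness == 0.0
        assert result.best_mask.sum() == 6

    def test_trace_is_non_increasing_for_any_seed(self):
        rng = np.random.default_rng(0)
        table = rng.random(2 ** 6)
        def fit(mask):
            return float(table[int("".join(map(str, mask.astype(int))), 2)])
        for seed in range(5):
            result = optimize(fit, dim=6, config=BHHOConfig(it_max=30), seed=seed)
            assert all(b <= a for a, b in zip(result.trace, result.trace[1:]))
            assert len(result.trace) == 30

    def test_bit_identical_determinism(self):
        a = optimize(count_zeros, dim=8, config=BHHOConfig(), seed=5)
        b = optimize(count_zeros, dim=8, config=BHHOConfig(), seed=5)
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.trace == b.trace
        assert a.n_evaluations == b.n_evaluations

    def test_positions_stay_binary_hence_bounded(self):
        config = BHHOConfig(pop_size=6, it_max=20)
        pop = init_population(5, config, seed=2, fitness_fn=count_zeros)
        assert np.all(pop.positions >= config.lb) and np.all(pop.positions <= config.ub)
        result = optimize(count_zeros, dim=5, config=config, seed=2)
        assert set(np.unique(result.best_mask)) <= {0, 1}

    def test_handles_infinite_fitness_regions(self):
        def fit(mask):
            if mask.sum() < 2:
                return np.inf
            return float(mask.sum())
        result = optimize(fit, dim=6, config=BHHOConfig(it_max=40), seed=1)
        assert result.best_fitness == 2.0
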