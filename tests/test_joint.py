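import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rbfqsar import JointRBFSelector, decode, encode_mask, fitness
from rbfqsar.joint import METRIC_FLOOR, block_selection
from rbfqsar.qpso import QPSO
from rbfqsar.validation import make_folds


class TestDecode:
    @pytest.mark.parametrize(
        "value,expected",
        [(563, [1, 2, 5, 6, 10]), (0, []), (1023, list(range(1, 11)))],
    )
    def test_block_selection_worked_examples(self, value, expected):
        assert block_selection(value) == expected

    def test_full_position_vector_worked_example(self):
        pos = [0.01, 0.25, 515.6, 511.9, 91.0, 0.15, 400.3, 43.7]
        eps, delta, mask = decode(pos, 56)
        assert eps == pytest.approx(0.01)
        assert delta == pytest.approx(0.25)
        selected = sorted((np.flatnonzero(mask) + 1).tolist())
        assert selected == [3, 10, 20, 21, 22, 24, 25, 27, 45, 48, 49, 53, 54, 56]

    def test_rounding_is_half_away_from_zero(self):
        # 511.5 rounds up to 512, selecting only within-block position 10
        _, _, mask = decode([1, 1, 511.5], 10)
        assert np.flatnonzero(mask).tolist() == [9]

    def test_out_of_range_values_clipped(self):
        eps, delta, mask = decode([99.0, -3.0, 2000.0], 10)
        assert eps == 5.0 and delta == 1e-4
        assert mask.all()  # 2000 clips to 1023 -> all ten selected

    def test_bits_beyond_descriptor_count_ignored(self):
        _, _, mask = decode([1, 1, 1023.0], 7)
        assert mask.sum() == 7

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode([1, 1, 1], 56)

    @given(st.integers(min_value=0, max_value=1023))
    @settings(deadline=None, max_examples=64, derandomize=True)
    def test_encode_decode_round_trip(self, value):
        _, _, mask = decode([1, 1, float(value)], 10)
        assert encode_mask(mask)[0] == value


@pytest.fixture(scope="module")
def learnable():
    rng = np.random.default_rng(0)
    X = rng.uniform(-2, 2, (80, 6))
    y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] ** 2
    return X, y


class TestFitness:
    def test_learnable_noiseless_target_near_one(self, learnable):
        X, y = learnable
        mask = np.array([True, True, False, False, False, False])
        rec = fitness(X, y, eps=1e-3, delta=1.5, mask=mask, max_neurons=60, seed=0)
        assert rec.r2 > 0.99 and rec.r2_cv10 > 0.95
        assert rec.feasible
        assert rec.fitness == pytest.approx(1.0, abs=0.1)

    def test_overfit_gap_penalized(self, learnable):
        """A candidate violating the gap constraint scores worse than any
        feasible one."""
        X, y = learnable
        rng = np.random.default_rng(1)
        y_noisy = y + rng.normal(0, 1.0, len(y))
        mask = np.ones(6, dtype=bool)
        # tiny mse goal with noise: interpolates training, poor CV
        rec = fitness(X, y_noisy, eps=1e-4, delta=0.3, mask=mask, max_neurons=80, seed=0)
        good = fitness(X, y, eps=1e-3, delta=1.5,
                       mask=np.array([True, True, False, False, False, False]),
                       max_neurons=60, seed=0)
        assert not rec.feasible
        assert rec.fitness > good.fitness + 1e5

    def test_nonpositive_metrics_floored(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        # spread so large every basis column is ~constant: predictor ~ mean
        rec = fitness(X, y, eps=1e-4, delta=5.0, mask=np.ones(3, bool),
                      max_neurons=2, seed=0)
        if rec.r2_cv10 <= 0:
            assert rec.fitness >= 1.0 / (max(rec.r2, METRIC_FLOOR) * METRIC_FLOOR)

    def test_empty_mask_returns_worst_without_raising(self):
        rec = fitness(np.ones((10, 3)), np.arange(10.0), 0.01, 1.0,
                      np.zeros(3, bool))
        assert rec.fitness > 1e6
        assert not rec.feasible


class TestQPSO:
    def test_minimizes_sphere(self):
        res = QPSO(lambda x: float((x**2).sum()), (np.full(3, -5.0), np.full(3, 5.0)),
                   n_particles=15, n_iterations=150, seed=0).run()
        assert res.best_fitness < 1e-3

    def test_history_non_increasing(self):
        res = QPSO(lambda x: float((x**2).sum()), (np.full(2, -5.0), np.full(2, 5.0)),
                   n_particles=8, n_iterations=60, seed=1).run()
        assert np.all(np.diff(res.history) <= 0)

    def test_positions_respect_bounds(self):
        seen = []
        QPSO(lambda x: seen.append(x.copy()) or float(x.sum()),
             (np.zeros(2), np.ones(2)), n_particles=5, n_iterations=30, seed=2).run()
        arr = np.array(seen)
        assert arr.min() >= 0 and arr.max() <= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            QPSO(lambda x: 0.0, (np.zeros(2), np.ones(2)), n_particles=1)


class TestJointOptimizer:
    def test_single_descriptor_degenerate(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (50, 1))
        y = np.tanh(X[:, 0])
        sel = JointRBFSelector(population=6, iterations=20, max_neurons=30,
                               seed=0).fit(X, y)
        assert sel.mask_.tolist() == [True]
        assert sel.record_.feasible

    def test_deterministic_given_seed(self, learnable):
        X, y = learnable
        rng = np.random.default_rng(4)
        yn = y + rng.normal(0, 0.2, len(y))
        a = JointRBFSelector(population=5, iterations=10, max_neurons=25, seed=9).fit(X, yn)
        b = JointRBFSelector(population=5, iterations=10, max_neurons=25, seed=9).fit(X, yn)
        np.testing.assert_array_equal(a.mask_, b.mask_)
        assert a.eps_ == b.eps_ and a.delta_ == b.delta_
        np.testing.assert_allclose(a.fitness_history_, b.fitness_history_)

    def test_best_fitness_history_non_increasing(self, learnable):
        X, y = learnable
        rng = np.random.default_rng(5)
        yn = y + rng.normal(0, 0.2, len(y))
        sel = JointRBFSelector(population=5, iterations=15, max_neurons=25, seed=1).fit(X, yn)
        assert np.all(np.diff(sel.fitness_history_) <= 0)

    def test_near_exhaustive_optimum_on_toy(self):
        """On 6 descriptors the swarm at generous budget reaches a fitness
        within 1% of exhaustive search over all 64 masks x an (eps, delta)
        grid restricted to the same grid points."""
        rng = np.random.default_rng(6)
        X = rng.uniform(-2, 2, (50, 6))
        y = np.tanh(X[:, 0]) + 0.4 * X[:, 1] ** 2 + rng.normal(0, 0.15, 50)
        folds = make_folds(50, 10, 0)
        best_ex = np.inf
        for m in range(1, 64):
            mask = np.array([(m >> b) & 1 for b in range(6)], dtype=bool)
            for eps in (1e-3, 1e-2):
                for delta in (1.0, 2.0):
                    rec = fitness(X, y, eps, delta, mask, folds=folds, max_neurons=30)
                    best_ex = min(best_ex, rec.fitness)
        sel = JointRBFSelector(population=20, iterations=250, max_neurons=30,
                               cv_folds=10, seed=0).fit(X, y)
        # swarm searches a continuous superset of the grid, so it may do
        # strictly better; it must not trail by more than 1%
        assert sel.record_.fitness <= best_ex * 1.01
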