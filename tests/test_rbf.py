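import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rbfqsar import RBFNetRegressor
from rbfqsar.rbf import gaussian_basis, TrainingStallWarning


def brute_force_predict(model, X):
    """Literal double-loop transcription of the network output formula."""
    out = np.zeros(len(X))
    for i, x in enumerate(X):
        s = model.bias_
        for c, w in zip(model.centers_, model.weights_):
            d = np.sqrt(((x - c) ** 2).sum())
            if model.basis == "halfwidth":
                s += w * np.exp(-((0.8326 * d / model.spread) ** 2))
            else:
                s += w * np.exp(-((d / model.spread) ** 2))
        out[i] = s
    return out


class TestBasis:
    def test_halfwidth_convention_gives_half_at_spread(self):
        assert gaussian_basis(np.array([2.0]), 2.0, "halfwidth")[0] == pytest.approx(0.5, abs=1e-4)

    def test_plain_convention(self):
        assert gaussian_basis(np.array([1.0]), 1.0, "plain")[0] == pytest.approx(np.exp(-1))

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError):
            gaussian_basis(np.ones(2), 0.0)


class TestFit:
    def test_single_point_reproduced(self):
        # with a bias unit the lone target is absorbed by the bias; without
        # one, a single centre at x0 carries it
        m = RBFNetRegressor(mse_goal=1e-9, spread=1.0).fit([[2.0, 3.0]], [5.0])
        assert m.predict([[2.0, 3.0]])[0] == pytest.approx(5.0)
        m2 = RBFNetRegressor(mse_goal=1e-9, spread=1.0, fit_bias=False).fit([[2.0, 3.0]], [5.0])
        np.testing.assert_allclose(m2.centers_, [[2.0, 3.0]])
        assert m2.predict([[2.0, 3.0]])[0] == pytest.approx(5.0)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-3, 3, (15, 2))
        y = rng.standard_normal(15)
        m = RBFNetRegressor(mse_goal=1e-12, spread=1.0, max_neurons=15).fit(X, y)
        assert m.train_mse_ < 1e-8

    def test_stops_at_mse_goal(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-3, 3, (40, 1))
        y = np.sin(X[:, 0])
        m = RBFNetRegressor(mse_goal=1e-3, spread=1.0, max_neurons=40).fit(X, y)
        assert m.train_mse_ <= 1e-3
        assert m.n_neurons_ < 40

    def test_neuron_cap_respected(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        m = RBFNetRegressor(mse_goal=1e-12, spread=1.0, max_neurons=5).fit(X, y)
        assert m.n_neurons_ == 5

    def test_centers_are_training_rows(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        m = RBFNetRegressor(mse_goal=1e-6, spread=1.0, max_neurons=10).fit(X, y)
        for c in m.centers_:
            assert (np.abs(X - c).sum(axis=1) < 1e-12).any()

    def test_conflicting_targets_warn_and_return_ls_fit(self):
        X = np.zeros((4, 2))
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.warns(TrainingStallWarning):
            m = RBFNetRegressor(mse_goal=1e-9, spread=1.0).fit(X, y)
        # best least-squares answer for identical inputs is the mean
        assert m.predict(np.zeros((1, 2)))[0] == pytest.approx(0.5)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RBFNetRegressor(mse_goal=0).fit([[1.0]], [1.0])
        with pytest.raises(ValueError):
            RBFNetRegressor(spread=-1).fit([[1.0]], [1.0])


class TestPredict:
    def test_query_at_lone_center_unit_weight(self):
        m = RBFNetRegressor(fit_bias=False)
        m.centers_ = np.array([[1.0, 2.0]])
        m.weights_ = np.array([1.0])
        m.bias_ = 0.0
        m.n_neurons_ = 1
        m.n_features_in_ = 2
        assert m.predict([[1.0, 2.0]])[0] == pytest.approx(1.0)

    def test_far_query_decays_to_bias(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        m = RBFNetRegressor(mse_goal=1e-6, spread=1.0, max_neurons=10).fit(X, y)
        far = np.full((1, 2), 1e3)
        assert m.predict(far)[0] == pytest.approx(m.bias_, abs=1e-10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        for basis in ("halfwidth", "plain"):
            m = RBFNetRegressor(mse_goal=1e-4, spread=1.3, max_neurons=12, basis=basis).fit(X, y)
            Xq = rng.standard_normal((8, 3))
            np.testing.assert_allclose(m.predict(Xq), brute_force_predict(m, Xq), atol=1e-10)

    def test_dimension_mismatch_raises(self):
        m = RBFNetRegressor(mse_goal=1e-4, spread=1.0).fit(np.ones((3, 2)), np.arange(3.0))
        with pytest.raises(ValueError):
            m.predict(np.ones((2, 5)))


class TestProperties:
    def test_lowering_goal_never_raises_final_mse(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-2, 2, (30, 2))
        y = np.sin(X[:, 0]) * X[:, 1]
        goals = [1e-1, 1e-2, 1e-3, 1e-4]
        mses = [
            RBFNetRegressor(mse_goal=g, spread=1.0, max_neurons=30).fit(X, y).train_mse_
            for g in goals
        ]
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))

    def test_row_permutation_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 3))
        y = X[:, 0] ** 2 + rng.standard_normal(25) * 0.1
        perm = rng.permutation(25)
        Xq = rng.standard_normal((6, 3))
        m1 = RBFNetRegressor(mse_goal=1e-3, spread=1.2, max_neurons=20).fit(X, y)
        m2 = RBFNetRegressor(mse_goal=1e-3, spread=1.2, max_neurons=20).fit(X[perm], y[perm])
        np.testing.assert_allclose(m1.predict(Xq), m2.predict(Xq), atol=1e-8)

    def test_small_spread_full_budget_approaches_nearest_neighbor(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 10, (15, 1))
        y = rng.standard_normal(15)
        m = RBFNetRegressor(mse_goal=1e-14, spread=1e-3, max_neurons=15, fit_bias=False).fit(X, y)
        Xq = X + 1e-5
        nn = y[np.argmin(cdist(Xq, X), axis=1)]
        # residual deviation is the basis decay over the 1e-5 query offset
        np.testing.assert_allclose(m.predict(Xq), nn, atol=1e-3)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        m = RBFNetRegressor(mse_goal=1e-3, spread=0.9, max_neurons=8).fit(X, y)
        path = tmp_path / "model.json"
        m.save(path, descriptor_names=["a", "b"])
        m2 = RBFNetRegressor.load(path)
        np.testing.assert_allclose(m.predict(X), m2.predict(X), atol=1e-12)
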