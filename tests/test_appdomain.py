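import numpy as np
import pytest

from rbfqsar import (
    ConsensusModel,
    coverage,
    flag_outliers,
    fwd_ad,
    leverage_ad,
)
from rbfqsar.appdomain import ADReport, FrequencyWeightedDistanceAD, LeverageAD, ad_report


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _mask(p, idx):
    m = np.zeros(p, dtype=bool)
    m[idx] = True
    return m


class TestLeverage:
    def test_reference_warning_leverage(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((759, 55))
        _, h_star = leverage_ad(X, X[:1], p=55)
        assert h_star == pytest.approx(0.22134, abs=5e-6)

    def test_single_training_point_has_leverage_one(self):
        X = np.array([[2.0, 1.0]])
        h, _ = leverage_ad(X, X)
        assert h[0] == pytest.approx(1.0)

    def test_matches_hat_matrix_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 2))
        h, _ = leverage_ad(X, X)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(h, np.diag(H), atol=1e-10)

    def test_training_leverage_sums_to_p(self):
        """Trace of the hat matrix equals the column count (no intercept
        augmentation here: X enters as given)."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        h, _ = leverage_ad(X, X)
        assert h.sum() == pytest.approx(5.0, abs=1e-8)

    def test_singular_design_uses_pseudo_inverse(self):
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.warns(UserWarning, match="singular"):
            ad = LeverageAD().fit(X)
        assert np.all(np.isfinite(ad.leverage(X)))


class TestFWD:
    def _consensus_two_descriptors(self):
        """f = (1, 0.5): both sub-models use descriptor 0, one uses 1."""
        return ConsensusModel(
            [(_ConstantModel(0), _mask(2, [0, 1])), (_ConstantModel(0), _mask(2, [0]))]
        )

    def test_training_centroid_has_zero_distance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 2))
        cm = self._consensus_two_descriptors()
        ad = FrequencyWeightedDistanceAD(standardize=True).fit(X, cm)
        mu = X.mean(axis=0, keepdims=True)
        assert ad.distance(mu)[0] == pytest.approx(0.0, abs=1e-10)
        assert ad.predict(mu)[0] == 1

    def test_equal_weights_preserve_unweighted_ordering(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 3))
        cm = ConsensusModel([(_ConstantModel(0), _mask(3, [0, 1, 2]))] * 2)
        d, _, f = fwd_ad(cm, X, X, standardize=False)
        np.testing.assert_allclose(f, 1.0)
        centroid = X.mean(axis=0)
        unweighted = np.linalg.norm(X - centroid, axis=1)
        np.testing.assert_allclose(np.argsort(d), np.argsort(unweighted))

    def test_hand_arithmetic_on_five_compound_toy(self):
        """f = (1, 0.5), no standardization: v, C and d computed by hand."""
        X = np.array([[1.0, 2.0], [3.0, 0.0], [5.0, 4.0], [7.0, 2.0], [4.0, 2.0]])
        cm = self._consensus_two_descriptors()
        d, thr, f = fwd_ad(cm, X, X, standardize=False)
        np.testing.assert_allclose(f, [1.0, 0.5])
        V = X * np.array([1.0, 0.5])
        C = V.mean(axis=0)  # (4.0, 1.0)
        np.testing.assert_allclose(C, [4.0, 1.0])
        expected = np.sqrt(((V - C) ** 2).sum(axis=1))
        np.testing.assert_allclose(d, expected, atol=1e-12)
        assert thr == pytest.approx(expected.mean() + 3 * expected.std(ddof=1), abs=1e-12)

    def test_proportional_usage_counts_leave_distances_unchanged(self):
        """Duplicating every sub-model doubles n_j and N, leaving f_j and
        hence all distances unchanged."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 2))
        cm1 = self._consensus_two_descriptors()
        cm2 = ConsensusModel(cm1.submodels * 2)
        d1, t1, _ = fwd_ad(cm1, X, X)
        d2, t2, _ = fwd_ad(cm2, X, X)
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        assert t1 == pytest.approx(t2)

    def test_no_descriptors_rejected(self):
        cm = ConsensusModel([(_ConstantModel(0), np.zeros(2, bool))])
        with pytest.raises(ValueError):
            FrequencyWeightedDistanceAD().fit(np.ones((3, 2)), cm)


class TestOutliers:
    def test_perfect_predictions_after_noise_no_outliers(self):
        rng = np.random.default_rng(6)
        y = rng.uniform(0, 9, 50)
        yh = y + rng.normal(0, 0.3, 50)
        assert len(flag_outliers(y, yh)) == 0

    def test_injected_gross_error_flagged(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 9, 60)
        yh = y + rng.normal(0, 0.3, 60)
        y = y.copy()
        y[17] += 5 * 0.3 * 10  # gross error far beyond 3 sigma
        flagged = flag_outliers(y, yh)
        assert flagged.tolist() == [17]

    def test_zero_residual_sd_rejected(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            flag_outliers(y, y)


class TestADReport:
    def _report(self):
        rng = np.random.default_rng(8)
        Xt = rng.standard_normal((40, 3))
        Xv = rng.standard_normal((15, 3))
        f = lambda X: np.tanh(X[:, 0]) + 0.2 * X[:, 1]

        class _F:
            def predict(self, X):
                return np.tanh(X[:, 0]) + 0.2 * X[:, 1]

        cm = ConsensusModel([(_F(), _mask(3, [0, 1]))])
        yt = f(Xt) + rng.normal(0, 0.1, 40)
        yv = f(Xv) + rng.normal(0, 0.1, 15)
        return ad_report(cm, Xt, yt, Xv, yv)

    def test_one_row_per_compound_with_all_fields(self):
        rep = self._report()
        df = rep.to_dataframe()
        assert len(df) == 55
        assert set(df.columns) >= {
            "compound_id", "set", "leverage", "fwd_distance",
            "std_residual", "inside_leverage", "inside_fwd", "outlier",
        }
        assert (df["set"] == "train").sum() == 40

    def test_coverage_bounds_and_extremes(self):
        rep = self._report()
        cov = coverage(rep, "fwd")
        assert 0.0 <= cov["train"] <= 1.0 and 0.0 <= cov["valid"] <= 1.0
        # FWD threshold construction keeps most training compounds inside
        assert cov["train"] > 0.85
        # degenerate thresholds
        rep_all = ADReport(
            compound_ids=["a", "b"], set_labels=np.array(["train", "valid"]),
            leverage=np.zeros(2), warning_leverage=1.0,
            fwd_distance=np.array([5.0, 6.0]), fwd_threshold=1.0,
            std_residuals=np.zeros(2),
            inside_leverage=np.array([True, True]),
            inside_fwd=np.array([False, False]),
            outliers=np.array([], dtype=int),
        )
        assert coverage(rep_all, "fwd") == {"train": 0.0, "valid": 0.0}
        assert coverage(rep_all, "leverage") == {"train": 1.0, "valid": 1.0}
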