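"""Gradient boosting correctness, pooling, evaluation harness, and
importance accounting."""

import json

import numpy as np
import pytest

from phenoherit import gbm


def brute_force_depth1(X, y):
    """Enumerate every (feature, threshold) split; return best train MSE."""
    n, d = X.shape
    best = np.var(y)
    for j in range(d):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (lo + hi)
            mask = X[:, j] <= thr
            if mask.all() or not mask.any():
                continue
            mse = (
                np.sum((y[mask] - y[mask].mean()) ** 2)
                + np.sum((y[~mask] - y[~mask].mean()) ** 2)
            ) / n
            best = min(best, mse)
    return best


class TestFit:
    def test_m_zero_predicts_mean(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((20, 3)), rng.random(20)
        m = gbm.fit(X, y, M=0)
        np.testing.assert_allclose(m.predict(X), y.mean())

    def test_two_point_exact_split(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 1.0])
        m = gbm.fit(X, y, M=1, rate=1.0, max_depth=1)
        np.testing.assert_allclose(m.predict(X), y)
        tree = m.trees[0]
        assert 0.0 < tree["threshold"] < 1.0

    def test_defaults_match_documented_hyperparameters(self):
        rng = np.random.default_rng(1)
        m = gbm.fit(rng.random((12, 2)), rng.random(12))
        assert m.M == 200 and m.rate == 0.1
        assert len(m.trees) == 200

    @pytest.mark.parametrize("seed", range(5))
    def test_single_tree_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        X = rng.random((n, 3))
        if seed % 2:
            X[:, 1] = np.round(X[:, 1], 1)  # induce duplicate values
        y = rng.random(n)
        m = gbm.fit(X, y, M=1, rate=1.0, max_depth=1)
        assert m.loss_trace[0] == pytest.approx(brute_force_depth1(X, y), abs=1e-12)

    def test_loss_trace_non_increasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.random((40, 4))
            y = rng.random(40)
            m = gbm.fit(X, y, M=30)
            assert np.all(np.diff(m.loss_trace) <= 1e-12)

    def test_constant_features_degenerate_to_mean(self):
        X = np.ones((10, 2))
        y = np.arange(10.0)
        m = gbm.fit(X, y, M=5)
        np.testing.assert_allclose(m.predict(X), y.mean())

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        X, y = rng.random((30, 4)), rng.random(30)
        perm = rng.permutation(30)
        m1 = gbm.fit(X, y, M=20)
        m2 = gbm.fit(X[perm], y[perm], M=20)
        Xnew = rng.random((10, 4))
        np.testing.assert_allclose(m1.predict(Xnew), m2.predict(Xnew), atol=1e-12)

    def test_training_mse_beats_constant_model(self):
        rng = np.random.default_rng(4)
        X = rng.random((50, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 50)
        m = gbm.fit(X, y, M=50)
        assert m.loss_trace[-1] <= np.var(y)


class TestPredict:
    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        m = gbm.fit(rng.random((10, 3)), rng.random(10), M=2)
        with pytest.raises(ValueError):
            m.predict(rng.random((4, 2)))

    def test_agrees_with_reference_library(self):
        from sklearn.ensemble import GradientBoostingRegressor

        rng = np.random.default_rng(6)
        X = rng.random((150, 8))
        y = 2 * X[:, 0] - X[:, 1] ** 2 + 0.5 * np.sin(6 * X[:, 2]) + 0.05 * rng.standard_normal(150)
        ours = gbm.fit(X, y, M=100, rate=0.1, max_depth=3)
        ref = GradientBoostingRegressor(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=0
        ).fit(X, y)
        mse_ours = float(np.mean((y - ours.predict(X)) ** 2))
        mse_ref = float(np.mean((y - ref.predict(X)) ** 2))
        assert mse_ours <= 1.1 * mse_ref

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(7)
        X, y = rng.random((20, 3)), rng.random(20)
        m = gbm.fit(X, y, M=5)
        back = gbm.GBMModel.from_json(m.to_json())
        np.testing.assert_allclose(back.predict(X), m.predict(X))

    def test_unknown_version_rejected(self):
        rng = np.random.default_rng(8)
        m = gbm.fit(rng.random((10, 2)), rng.random(10), M=1)
        obj = json.loads(m.to_json())
        obj["version"] = 99
        with pytest.raises(ValueError):
            gbm.GBMModel.from_json(json.dumps(obj))


class TestPooling:
    def test_equal_se_midpoint(self):
        p = gbm.pool_estimates([0.4, 0.6], [0.1, 0.1])
        assert p.value == pytest.approx(0.5)
        assert p.se == pytest.approx(0.1 / np.sqrt(2))

    def test_single_record_identity(self):
        p = gbm.pool_estimates([0.42], [0.07])
        assert p.value == pytest.approx(0.42)
        assert p.se == pytest.approx(0.07)

    def test_unequal_se_hand_case(self):
        p = gbm.pool_estimates([0.4, 0.6], [0.1, 0.2])
        assert p.value == pytest.approx(0.44)

    def test_missing_se_falls_back_to_mean(self):
        p = gbm.pool_estimates([0.2, 0.6], [0.1, np.nan])
        assert p.value == pytest.approx(0.4)
        assert p.se is None and not p.weighted

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gbm.pool_estimates([])


class TestEvaluate:
    def test_oracle_predictor_is_perfect(self):
        rng = np.random.default_rng(9)
        X = rng.random((60, 2))
        y = X[:, 0] + X[:, 1]

        def oracle(Xtr, ytr, Xte):
            return Xte[:, 0] + Xte[:, 1]

        rep = gbm.evaluate(X, y, n_splits=10, seed=1, fit_predict=oracle)
        np.testing.assert_allclose(rep.pearson_r, 1.0, atol=1e-12)
        np.testing.assert_allclose(rep.slope, 1.0, atol=1e-9)
        np.testing.assert_allclose(rep.intercept, 0.0, atol=1e-9)

    def test_degenerate_splits_skipped(self):
        X = np.random.default_rng(10).random((12, 1))
        y = np.ones(12)

        def oracle(Xtr, ytr, Xte):
            return np.zeros(len(Xte))

        rep = gbm.evaluate(X, y, n_splits=4, seed=2, fit_predict=oracle)
        assert rep.n_skipped == 4

    def test_smooth_function_recovery_slope(self):
        # targets = smooth feature function + noise: held-out regression of
        # actual on predicted should be close to the identity
        rng = np.random.default_rng(11)
        X = rng.random((400, 5))
        y = 0.4 + 0.3 * X[:, 0] - 0.2 * X[:, 1] * X[:, 2] + rng.normal(0, 0.05, 400)
        rep = gbm.evaluate(X, y, n_splits=5, seed=3, M=200)
        assert 0.85 <= rep.mean_slope <= 1.15
        assert rep.mean_r > 0.6


class TestImportance:
    def test_no_split_model_flagged(self):
        m = gbm.fit(np.ones((10, 2)), np.arange(10.0), M=3)
        rep = gbm.feature_importance(m)
        assert rep.no_splits
        np.testing.assert_array_equal(rep.per_feature, 0.0)

    def test_single_split_concentrates_importance(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 1.0])
        m = gbm.fit(X, y, M=1, rate=1.0, max_depth=1)
        rep = gbm.feature_importance(m)
        assert rep.per_feature[0] == pytest.approx(1.0)

    def test_block_share_tracks_generating_features(self):
        from phenoherit.features import FeatureSchema

        rng = np.random.default_rng(12)
        X = rng.random((300, 10))
        y = 2.0 * X[:, 0] + X[:, 1]  # depends only on the "curve" block
        schema = FeatureSchema(
            blocks=[("curve", 2, "curve"), ("rest", 8, "other")], vocabularies={}
        )
        m = gbm.fit(X, y, M=50)
        rep = gbm.feature_importance(m, schema)
        assert rep.block_shares["curve"] > 0.8
        assert sum(rep.block_shares.values()) == pytest.approx(1.0)
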