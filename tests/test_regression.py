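import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from nirsolids.regression import (
    GRNNRegressor,
    LSSVMRegressor,
    PLSRegressorNIPALS,
    grnn_predict,
    select_n_lv,
)
from nirsolids.simulate import NoiseModel, generate_dataset


class TestPLSR:
    def test_rank_one_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=25)
        p = rng.normal(size=6)
        X, y = np.outer(t, p), t.copy()
        model = PLSRegressorNIPALS(n_lv=1).fit(X, y)
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 1e-8

    def test_univariate_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 1))
        y = -2.5 * X[:, 0] + 0.3 + rng.normal(size=30) * 0.2
        model = PLSRegressorNIPALS(n_lv=1).fit(X, y)
        slope = np.polyfit(X[:, 0], y, 1)[0]
        assert model.coef_[0] == pytest.approx(slope, abs=1e-9)

    def test_score_columns_orthogonal(self, noisy_coarse):
        model = PLSRegressorNIPALS(n_lv=5).fit(
            noisy_coarse.absorbance, noisy_coarse.reference
        )
        T = model.T_
        for a in range(5):
            for b in range(a + 1, 5):
                bound = 1e-8 * np.linalg.norm(T[:, a]) * np.linalg.norm(T[:, b])
                assert abs(T[:, a] @ T[:, b]) < bound

    def test_matches_established_pls_implementation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        y = X @ np.arange(8.0) + rng.normal(size=30)
        ours = PLSRegressorNIPALS(n_lv=4).fit(X, y).predict(X)
        theirs = PLSRegression(n_components=4, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_prediction_identities(self, noisy_coarse):
        X, y = noisy_coarse.absorbance, noisy_coarse.reference
        model = PLSRegressorNIPALS(n_lv=4).fit(X, y)
        assert model.predict(model.x_mean_[None])[0] == pytest.approx(model.y_mean_)
        np.testing.assert_allclose(
            model.predict(X), model.predict_via_scores(X), atol=1e-9
        )

    def test_n_lv_bounds_enforced(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            PLSRegressorNIPALS(n_lv=5).fit(X, np.arange(5.0))


class TestSelectNLv:
    def test_noiseless_rank_one_needs_one_component(self):
        t = np.random.default_rng(3).normal(size=20)
        X = np.outer(t, [1.0, -1.0, 2.0])
        best, curve = select_n_lv(X, t, max_lv=3, folds=5, seed=0)
        assert best == 1
        assert np.all(curve >= 0)

    def test_matches_brute_force_cv_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(size=20) * 0.5
        best, curve = select_n_lv(X, y, max_lv=5, folds=4, seed=7)
        # oracle: independent CV loop refitting sklearn's PLS per component count
        kf = KFold(n_splits=4, shuffle=True, random_state=7)
        oracle = []
        for a in range(1, 6):
            press = 0.0
            for tr, te in kf.split(X):
                m = PLSRegression(n_components=a, scale=False).fit(X[tr], y[tr])
                press += np.sum((m.predict(X[te]).ravel() - y[te]) ** 2)
            oracle.append(np.sqrt(press / 20))
        np.testing.assert_allclose(curve, oracle, atol=1e-8)
        assert best == int(np.argmin(oracle)) + 1


class TestGRNN:
    def test_small_sigma_is_nearest_neighbor(self):
        Xc = np.array([[0.0], [1.0], [2.0]])
        yc = np.array([5.0, -1.0, 7.0])
        pred = grnn_predict(Xc, yc, [[1.2]], sigma=1e-6)
        assert pred[0] == pytest.approx(-1.0)

    def test_large_sigma_is_global_mean(self):
        Xc = np.array([[0.0], [1.0], [2.0]])
        yc = np.array([5.0, -1.0, 7.0])
        pred = grnn_predict(Xc, yc, [[0.3], [1.9]], sigma=1e6)
        np.testing.assert_allclose(pred, yc.mean(), atol=1e-6)

    def test_matches_nadaraya_watson_oracle(self):
        rng = np.random.default_rng(5)
        Xc, yc = rng.normal(size=(5, 3)), rng.normal(size=5)
        Xq = rng.normal(size=(2, 3))
        sigma = 0.8
        pred = grnn_predict(Xc, yc, Xq, sigma)
        for i in range(2):
            w = np.exp(-np.sum((Xq[i] - Xc) ** 2, axis=1) / (2 * sigma**2))
            assert pred[i] == pytest.approx(w @ yc / w.sum(), abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            GRNNRegressor(sigma=0.0).fit([[1.0]], [1.0])
        with pytest.raises(ValueError):
            GRNNRegressor(sigma=1.0).fit(np.zeros((0, 2)), [])


class TestLSSVM:
    def test_vanishing_regularization_interpolates(self):
        model = LSSVMRegressor(gamma=1e9, width=1.0).fit(
            np.array([[0.0], [1.0]]), np.array([1.0, 3.0])
        )
        np.testing.assert_allclose(
            model.predict([[0.0], [1.0]]), [1.0, 3.0], atol=1e-6
        )

    def test_residual_decreases_with_gamma(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        errs = []
        for gamma in (1.0, 10.0, 100.0):
            model = LSSVMRegressor(gamma=gamma, width=1.5).fit(X, y)
            errs.append(np.abs(model.predict(X) - y).max())
        assert errs[0] > errs[1] > errs[2]

    def test_linear_system_residual_small(self, noisy_coarse):
        model = LSSVMRegressor(gamma=10.0, width=5.0).fit(
            noisy_coarse.absorbance[:20], noisy_coarse.reference[:20]
        )
        assert model._residual_ < 1e-8

    def test_validation(self):
        with pytest.raises(ValueError):
            LSSVMRegressor(gamma=-1.0).fit([[0.0]], [1.0])


class TestRegressorInvariants:
    def test_zero_noise_benchmark_plsr_exact(self):
        d = generate_dataset(60, seed=13, noise=NoiseModel.silent())
        from nirsolids.preprocess import spxy_split

        split = spxy_split(d, 0.7)
        Xc = d.absorbance[split.calibration_indices]
        yc = d.reference[split.calibration_indices]
        Xp = d.absorbance[split.prediction_indices]
        yp = d.reference[split.prediction_indices]
        best, _ = select_n_lv(Xc, yc, max_lv=5, folds=5, seed=0)
        model = PLSRegressorNIPALS(n_lv=best).fit(Xc, yc)
        assert np.sqrt(np.mean((model.predict(Xp) - yp) ** 2)) < 1e-6

    def test_training_order_permutation_invariance(self, noisy_coarse):
        X, y = noisy_coarse.absorbance[:25], noisy_coarse.reference[:25]
        perm = np.random.default_rng(8).permutation(25)
        for make in (
            lambda: PLSRegressorNIPALS(n_lv=3),
            lambda: GRNNRegressor(sigma=2.0),
            lambda: LSSVMRegressor(gamma=10.0, width=3.0),
        ):
            a = make().fit(X, y).predict(X[:5])
            b = make().fit(X[perm], y[perm]).predict(X[:5])
            np.testing.assert_allclose(a, b, atol=1e-9)
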