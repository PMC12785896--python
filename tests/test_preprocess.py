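import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsolids.dataset import SpectraSet
from nirsolids.preprocess import (
    SavitzkyGolay,
    isolation_c,
    pca_scores,
    remove_outliers,
    sg_smooth,
    spxy_split,
)
from nirsolids.simulate import NoiseModel, generate_dataset


def as_set(X, y=None):
    X = np.atleast_2d(X)
    return SpectraSet(
        [f"s{i}" for i in range(X.shape[0])],
        900.0 + np.arange(X.shape[1]),
        X,
        reference=y,
    )


class TestSavitzkyGolay:
    def test_low_degree_polynomials_are_fixed_points(self):
        lam = np.linspace(0, 1, 50)
        rows = np.vstack([2 + 3 * lam - lam**2, 1 - lam + 0.5 * lam**2])
        out = SavitzkyGolay(window=7, polyorder=2).transform(rows)
        np.testing.assert_allclose(out, rows, atol=1e-9)

    def test_polyorder_zero_is_moving_average(self):
        row = np.array([[0.0, 0.0, 5.0, 0.0, 0.0]])
        out = SavitzkyGolay(window=5, polyorder=0).transform(row)
        assert out[0, 2] == pytest.approx(1.0)

    def test_matches_sliding_local_regression_oracle(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=41)
        window, polyorder, half = 7, 2, 3
        out = SavitzkyGolay(window, polyorder).transform(row[None])[0]
        for i in range(half, 41 - half):
            xs = np.arange(-half, half + 1)
            coef = np.polynomial.polynomial.polyfit(xs, row[i - half : i + half + 1], polyorder)
            assert out[i] == pytest.approx(coef[0], abs=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(scale=st.floats(-5, 5, allow_nan=False), seed=st.integers(0, 100))
    def test_commutes_with_row_scaling(self, scale, seed):
        row = np.random.default_rng(seed).normal(size=31)[None]
        sg = SavitzkyGolay(11, 2)
        np.testing.assert_allclose(
            sg.transform(scale * row), scale * sg.transform(row), atol=1e-12
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="odd"):
            sg_smooth(as_set(np.zeros((2, 20))), window=4)
        with pytest.raises(ValueError):
            sg_smooth(as_set(np.zeros((2, 20))), window=5, polyorder=5)


class TestPcaScores:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, -1.0, 0.5])
        _, explained, k = pca_scores(as_set(X), 0.95)
        assert k == 1
        assert explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_ratios_identity(self):
        X = np.random.default_rng(0).normal(size=(20, 6))
        _, explained, _ = pca_scores(as_set(X), 0.95)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        X = np.random.default_rng(1).normal(size=(15, 5))
        scores, _, k = pca_scores(as_set(X), 0.9999999)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order]
        for j in range(k):
            assert np.allclose(scores[:, j], oracle[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -oracle[:, j], atol=1e-8
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_scores(as_set(np.ones((5, 4))), 0.95)


class TestRemoveOutliers:
    def test_path_length_normalizer_at_two(self):
        assert isolation_c(2) == pytest.approx(1.0)

    def test_scores_bounded(self, outlier_dataset):
        _, report = remove_outliers(outlier_dataset, contamination=0.05, seed=1)
        assert np.all(report.anomaly_scores > 0)
        assert np.all(report.anomaly_scores <= 1)

    def test_injected_outliers_recovered(self, outlier_dataset):
        injected = set(outlier_dataset.metadata["outlier_indices"])
        _, report = remove_outliers(outlier_dataset, contamination=0.05, seed=1)
        assert injected <= set(report.removed_indices.tolist())

    def test_removal_count_is_ceiling(self, outlier_dataset):
        cleaned, report = remove_outliers(outlier_dataset, contamination=0.03, seed=0)
        expected = int(np.ceil(0.03 * outlier_dataset.n_samples))
        assert report.removed_indices.size == expected
        assert cleaned.n_samples == outlier_dataset.n_samples - expected

    def test_deterministic_per_seed(self, outlier_dataset):
        _, a = remove_outliers(outlier_dataset, contamination=0.05, seed=9)
        _, b = remove_outliers(outlier_dataset, contamination=0.05, seed=9)
        np.testing.assert_array_equal(a.removed_indices, b.removed_indices)

    def test_contamination_validated(self, outlier_dataset):
        with pytest.raises(ValueError):
            remove_outliers(outlier_dataset, contamination=0.7)
        with pytest.raises(ValueError):
            remove_outliers(outlier_dataset, subsample=10_000)


def spxy_oracle(X, y, n_cal):
    """Independent brute-force farthest-point selection on joint distances."""
    n = len(y)
    dx = np.array([[np.sqrt(np.sum((X[i] - X[j]) ** 2)) for j in range(n)] for i in range(n)])
    dy = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])
    d = dx / dx.max() + dy / dy.max()
    pair, best = None, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                pair, best = (i, j), d[i, j]
    selected = list(pair)
    while len(selected) < n_cal:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in selected:
                continue
            m = min(d[i, j] for j in selected)
            if m > cand_best:
                cand_best, cand = m, i
        selected.append(cand)
    return set(selected)


class TestSpxySplit:
    def test_calibration_size_70_percent(self):
        d = generate_dataset(10, seed=0, noise=NoiseModel.silent())
        split = spxy_split(d, 0.7)
        assert split.calibration_indices.size == 7
        assert split.prediction_indices.size == 3

    def test_partition_is_exact(self, noisy_coarse):
        split = spxy_split(noisy_coarse, 0.7)
        union = np.union1d(split.calibration_indices, split.prediction_indices)
        np.testing.assert_array_equal(union, np.arange(noisy_coarse.n_samples))
        assert np.intersect1d(split.calibration_indices, split.prediction_indices).size == 0

    def test_max_distance_pair_in_calibration(self, noisy_coarse):
        X, y = noisy_coarse.absorbance, noisy_coarse.reference
        dx = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dy = np.abs(y[:, None] - y[None])
        d = dx / dx.max() + dy / dy.max()
        i, j = np.unravel_index(np.argmax(d), d.shape)
        cal = set(spxy_split(noisy_coarse, 0.7).calibration_indices.tolist())
        assert {int(i), int(j)} <= cal

    def test_matches_brute_force_oracle_n8(self):
        rng = np.random.default_rng(5)
        d = as_set(rng.normal(size=(8, 10)), y=rng.uniform(2, 16, size=8))
        split = spxy_split(d, 0.7)
        oracle = spxy_oracle(d.absorbance, d.reference, round(0.7 * 8))
        assert set(split.calibration_indices.tolist()) == oracle

    def test_deterministic(self, noisy_coarse):
        a = spxy_split(noisy_coarse, 0.6)
        b = spxy_split(noisy_coarse, 0.6)
        np.testing.assert_array_equal(a.calibration_indices, b.calibration_indices)

    def test_requires_reference(self):
        d = as_set(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="reference"):
            spxy_split(d, 0.7)
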