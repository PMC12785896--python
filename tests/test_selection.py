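import numpy as np
import pytest

from nirsolids.regression import PLSRegressorNIPALS
from nirsolids.selection import (
    CARSSelector,
    FullSpectrumSelector,
    SelectionResult,
    UVESelector,
    VIPSelector,
    compute_vip,
    full_spectrum,
    uve_select,
    vip_scores,
)
from nirsolids.simulate import BandModel, NoiseModel, generate_dataset

from conftest import COARSE_GRID, coarse_band_centers


class TestUVE:
    def test_scores_cover_real_variables_only(self, noisy_coarse):
        r = uve_select(noisy_coarse.absorbance, noisy_coarse.reference, n_lv=5, seed=0)
        assert r.scores.size == noisy_coarse.n_wavelengths
        assert r.selected_indices.size >= 1
        assert r.selected_indices.max() < noisy_coarse.n_wavelengths

    def test_band_centers_retained_on_zero_noise(self, zero_noise_coarse):
        r = uve_select(
            zero_noise_coarse.absorbance, zero_noise_coarse.reference, n_lv=3, seed=0
        )
        for c in coarse_band_centers():
            assert c in r.selected_indices

    def test_pure_noise_response_barely_selects(self, noisy_coarse):
        y = np.random.default_rng(99).normal(size=noisy_coarse.n_samples)
        r = uve_select(noisy_coarse.absorbance, y, n_lv=5, seed=0)
        assert r.selected_indices.size <= 0.05 * noisy_coarse.n_wavelengths

    def test_deterministic_per_seed(self, noisy_coarse):
        a = uve_select(noisy_coarse.absorbance, noisy_coarse.reference, seed=4)
        b = uve_select(noisy_coarse.absorbance, noisy_coarse.reference, seed=4)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)


class TestVIP:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        y = 2 * X[:, 0] + rng.normal(size=20) * 0.1
        r = vip_scores(X, y, n_lv=1)
        assert r.scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_mean_square_identity(self, noisy_coarse):
        model = PLSRegressorNIPALS(n_lv=5).fit(
            noisy_coarse.absorbance, noisy_coarse.reference
        )
        vip = compute_vip(model)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_equally_informative_variables(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]] * 2)
        y = X[:, 0] + X[:, 1]
        r = vip_scores(X, y, n_lv=2)
        np.testing.assert_allclose(r.scores, [1.0, 1.0], atol=1e-6)

    def test_selects_band_regions(self, noisy_coarse):
        r = vip_scores(noisy_coarse.absorbance, noisy_coarse.reference, n_lv=5)
        assert np.all(r.scores[r.selected_indices] > 1.0)

    def test_zero_variance_y_rejected(self, noisy_coarse):
        with pytest.raises(ValueError, match="degenerate"):
            vip_scores(noisy_coarse.absorbance, np.ones(noisy_coarse.n_samples))


@pytest.fixture(scope="module")
def cars_fixture():
    """Narrow informative bands + white noise: sparse subsets win RMSECV."""
    bands = BandModel(widths=np.full(5, 10.0))
    noise = NoiseModel(
        additive_sd=0.03, multiplicative_scatter_sd=0.0,
        baseline_slope_sd=0.0, baseline_offset_sd=0.0,
    )
    data = generate_dataset(40, seed=21, bands=bands, noise=noise, wavelengths=COARSE_GRID)
    result = CARSSelector(n_runs=60, cv_folds=5, seed=1).fit(
        data.absorbance, data.reference
    ).result_
    return data, bands, result


class TestCARS:
    def test_decay_schedule_endpoints(self, cars_fixture):
        _, _, r = cars_fixture
        assert r.runs[0]["n_retained"] == COARSE_GRID.size
        assert r.runs[-1]["n_retained"] == 2

    def test_retained_counts_non_increasing(self, cars_fixture):
        _, _, r = cars_fixture
        counts = [run["n_retained"] for run in r.runs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovers_informative_bands_sparsely(self, cars_fixture):
        _, bands, r = cars_fixture
        centers = coarse_band_centers(bands)
        covered = sum(
            any(abs(i - c) <= 1 for i in r.selected_indices) for c in centers
        )
        assert covered >= 4
        assert r.selected_indices.size < 0.2 * COARSE_GRID.size

    def test_best_rmsecv_no_worse_than_most_runs(self, cars_fixture):
        _, _, r = cars_fixture
        assert r.best_rmsecv == pytest.approx(min(run["rmsecv"] for run in r.runs))

    def test_deterministic_per_seed(self, noisy_coarse):
        args = dict(n_runs=10, cv_folds=3, seed=8)
        a = CARSSelector(**args).fit(noisy_coarse.absorbance, noisy_coarse.reference)
        b = CARSSelector(**args).fit(noisy_coarse.absorbance, noisy_coarse.reference)
        np.testing.assert_array_equal(a.result_.selected_indices, b.result_.selected_indices)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            CARSSelector(n_runs=1).fit(np.zeros((10, 5)), np.arange(10.0))
        with pytest.raises(ValueError):
            CARSSelector().fit(np.zeros((10, 1)), np.arange(10.0))


class TestFullSpectrum:
    def test_full_grid(self):
        r = full_spectrum(901)
        assert r.selected_indices.size == 901

    def test_single_wavelength(self):
        np.testing.assert_array_equal(full_spectrum(1).selected_indices, [0])

    def test_idempotent(self):
        a, b = full_spectrum(33), full_spectrum(33)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)


class TestSelectorContracts:
    def test_transform_subsets_columns_only(self, noisy_coarse):
        X, y = noisy_coarse.absorbance, noisy_coarse.reference
        sel = VIPSelector(n_lv=5).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape[0] == X.shape[0]
        np.testing.assert_array_equal(Xt, X[:, sel.get_support()])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            SelectionResult("x", np.array([], dtype=int), np.zeros(5))
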