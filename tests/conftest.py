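import numpy as np
import pytest

from nirsolids.simulate import BandModel, NoiseModel, generate_dataset

COARSE_GRID = np.arange(900.0, 1801.0, 5.0)  # 181 points, fast fixtures


def coarse_band_centers(bands: BandModel | None = None) -> list[int]:
    bands = bands or BandModel()
    return [int(np.argmin(np.abs(COARSE_GRID - c))) for c in bands.centers]


@pytest.fixture(scope="session")
def zero_noise_coarse():
    """Noise-free spectra on the coarse grid: X is exactly affine in SSC."""
    return generate_dataset(
        60, seed=7, noise=NoiseModel.silent(), wavelengths=COARSE_GRID
    )


@pytest.fixture(scope="session")
def noisy_coarse():
    """Mildly noisy coarse-grid dataset for selection/regression tests."""
    noise = NoiseModel(
        additive_sd=0.003,
        multiplicative_scatter_sd=0.005,
        baseline_slope_sd=0.01,
        baseline_offset_sd=0.005,
    )
    return generate_dataset(60, seed=3, noise=noise, wavelengths=COARSE_GRID)


@pytest.fixture(scope="session")
def outlier_dataset():
    """Full-grid dataset with 5% injected gross outliers (seeded)."""
    noise = NoiseModel(outlier_fraction=0.05)
    return generate_dataset(120, seed=42, noise=noise)
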