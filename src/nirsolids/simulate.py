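"""Seeded generator of juice-like NIR absorbance spectra with known SSC.

Emulates diffuse-reflectance absorbance of a sugar-rich juice measured on a
portable instrument over 900-1800 nm at 1 nm (901 points): five broad,
overlapping absorption bands (water O-H near 980/1450/1530 nm, sugar/organic
C-H near 1220/1660 nm), a per-sample scatter baseline (offset + tilt +
multiplicative gain), additive instrument noise, and optionally a small
fraction of corrupted "abnormal" rows mimicking instrument or handling errors.

The band model couples absorbance linearly to the soluble-solids content
(SSC, %): sugar C-H bands grow with SSC while water bands shrink slightly
(sugar displaces water). With all noise terms at zero the spectrum is an
exact affine function of SSC, which downstream latent-variable regression
must recover to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet

__all__ = [
    "BandModel",
    "NoiseModel",
    "default_grid",
    "sample_ssc",
    "generate_dataset",
]

#: SSC distribution of the emulated sample population (%, truncated normal).
SSC_MEAN = 6.99
SSC_SD = 3.79
SSC_MIN = 2.20
SSC_MAX = 16.5


def default_grid() -> np.ndarray:
    """900..1800 nm at 1 nm -> 901 points."""
    return np.arange(900.0, 1801.0, 1.0)


@dataclass
class BandModel:
    """Gaussian absorption bands and their linear coupling to SSC.

    ``ssc_coupling`` is in AU per % SSC: positive for the sugar C-H bands at
    1220 and 1660 nm, negative for the water-dominated bands at 980 and
    1450 nm, small for the 1530 nm combination band.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.array([980.0, 1220.0, 1450.0, 1530.0, 1660.0])
    )
    widths: np.ndarray = field(
        default_factory=lambda: np.array([30.0, 28.0, 26.0, 24.0, 22.0])
    )
    base_amplitude: np.ndarray = field(
        default_factory=lambda: np.array([0.80, 0.30, 1.20, 0.55, 0.35])
    )
    ssc_coupling: np.ndarray = field(
        default_factory=lambda: np.array([-0.004, 0.012, -0.006, 0.003, 0.009])
    )

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.base_amplitude = np.asarray(self.base_amplitude, dtype=float)
        self.ssc_coupling = np.asarray(self.ssc_coupling, dtype=float)
        if not (self.centers.shape == self.widths.shape == self.base_amplitude.shape == self.ssc_coupling.shape):
            raise ValueError("band parameter arrays must share one length")
        if np.any(self.widths <= 0):
            raise ValueError("band widths must be positive")

    def design(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-amplitude band shapes, (n_bands, p)."""
        lam = np.asarray(wavelengths, dtype=float)[None, :]
        c = self.centers[:, None]
        w = self.widths[:, None]
        return np.exp(-((lam - c) ** 2) / (2.0 * w**2))


@dataclass
class NoiseModel:
    """Instrument/scatter noise terms; all SDs in the units noted.

    ``additive_sd`` (AU) white noise per point; ``multiplicative_scatter_sd``
    (unitless) per-sample gain spread; ``baseline_slope_sd`` (AU per 1000 nm)
    per-sample tilt; ``baseline_offset_sd`` (AU) per-sample offset;
    ``outlier_fraction`` of rows corrupted by a spike plus baseline shift of
    ``outlier_magnitude`` x additive_sd.
    """

    additive_sd: float = 0.005
    multiplicative_scatter_sd: float = 0.02
    baseline_slope_sd: float = 0.05
    baseline_offset_sd: float = 0.02
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 10.0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_scatter_sd",
                     "baseline_slope_sd", "baseline_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """All noise terms zero — the exact-linear regime."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def sample_ssc(
    n: int,
    seed: int,
    mean: float = SSC_MEAN,
    sd: float = SSC_SD,
    min: float = SSC_MIN,
    max: float = SSC_MAX,
) -> np.ndarray:
    """Draw SSC values (%) from a normal(mean, sd) truncated to [min, max].

    Rejection sampling: draws are redrawn until inside the bounds, so the
    result is an exact truncated normal and every value respects the bounds.
    Deterministic per seed.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if not min < max:
        raise ValueError("min must be < max")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= min) & (draw <= max)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_dataset(
    n: int,
    seed: int,
    bands: BandModel | None = None,
    noise: NoiseModel | None = None,
    wavelengths: np.ndarray | None = None,
    ssc: np.ndarray | None = None,
    base_offset: float = 0.15,
) -> SpectraSet:
    """Generate a seeded synthetic dataset with known SSC ground truth.

    Per sample i on grid lambda::

        clean_i(l) = base_offset + off_i + slope_i*(l-l_mid)/1000
                     + sum_b (A_b + c_b*SSC_i) * exp(-(l-mu_b)^2/(2 s_b^2))
        x_i(l)     = clean_i(l) * (1 + g_i) + eps_i(l)

    with off/slope/g/eps drawn from :class:`NoiseModel`. Rows designated as
    outliers additionally receive a broad baseline shift and a narrow spike,
    each scaled to ``outlier_magnitude * additive_sd`` (an absolute floor of
    0.03 AU on the per-unit scale keeps injected faults gross, as real
    instrument errors — bubbles, empty cells, stray light — are).
    Outlier row indices are recorded in ``metadata['outlier_indices']``;
    the true SSC is carried as the reference vector.
    """
    bands = bands or BandModel()
    noise = noise or NoiseModel()
    lam = default_grid() if wavelengths is None else np.asarray(wavelengths, float)
    if np.any(bands.centers < lam[0]) or np.any(bands.centers > lam[-1]):
        raise ValueError("band centers must lie within the wavelength grid")
    rng = np.random.default_rng(seed)
    if ssc is None:
        ssc = sample_ssc(n, seed=int(rng.integers(0, 2**31 - 1)))
    else:
        ssc = np.asarray(ssc, dtype=float)
        if ssc.shape != (n,):
            raise ValueError("ssc must have length n")

    shapes = bands.design(lam)  # (B, p)
    amplitude = bands.base_amplitude[None, :] + ssc[:, None] * bands.ssc_coupling[None, :]
    clean = base_offset + amplitude @ shapes  # (n, p)

    mid = 0.5 * (lam[0] + lam[-1])
    offset = rng.normal(0.0, noise.baseline_offset_sd, size=n)
    slope = rng.normal(0.0, noise.baseline_slope_sd, size=n)
    clean = clean + offset[:, None] + slope[:, None] * (lam[None, :] - mid) / 1000.0

    gain = rng.normal(0.0, noise.multiplicative_scatter_sd, size=n)
    x = clean * (1.0 + gain[:, None])
    x = x + rng.normal(0.0, noise.additive_sd, size=x.shape)

    n_out = int(round(noise.outlier_fraction * n))
    outlier_idx = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.array([], int)
    if n_out:
        mag = noise.outlier_magnitude * max(noise.additive_sd, 0.03)
        for i in outlier_idx:
            shift = rng.choice([-1.0, 1.0]) * mag
            spike_center = rng.uniform(lam[0], lam[-1])
            spike = mag * np.exp(-((lam - spike_center) ** 2) / (2 * 8.0**2))
            x[i] = x[i] + shift + rng.choice([-1.0, 1.0]) * spike

    return SpectraSet(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        wavelengths=lam,
        absorbance=x,
        reference=ssc,
        metadata={
            "seed": int(seed),
            "outlier_indices": [int(i) for i in outlier_idx],
            "generator": "nirsolids.simulate.generate_dataset",
        },
    )
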