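"""Frozen seeded benchmark fixtures.

Everything here regenerates bit-identically from a seed, so tests and the
reproduction script need no stored data: the default benchmark emulates the
study conditions (180 juice samples, truncated-normal SSC, five-band spectra,
portable-instrument noise, 4.5% injected abnormal rows).
"""

from __future__ import annotations

import hashlib

import numpy as np

from .dataset import SpectraSet
from .simulate import BandModel, NoiseModel, generate_dataset

__all__ = [
    "make_default_benchmark",
    "dataset_digest",
    "fixture_manifest",
    "run_moecnn_benchmark",
]

DEFAULT_N = 180
DEFAULT_OUTLIER_FRACTION = 0.045


def make_default_benchmark(seed: int = 42, n: int = DEFAULT_N) -> SpectraSet:
    """The default synthetic benchmark: n=180, default bands/noise, 4.5%
    injected outliers, SSC truncated-normal in [2.20, 16.5]."""
    noise = NoiseModel(outlier_fraction=DEFAULT_OUTLIER_FRACTION)
    return generate_dataset(n=n, seed=seed, bands=BandModel(), noise=noise)


def run_moecnn_benchmark(seed: int = 42, epochs: int = 500, n: int = DEFAULT_N):
    """The reference end-to-end benchmark: generate, screen outliers,
    SG-smooth, SPXY 70/30, train the MoE-CNN (Adam, lr 0.001), evaluate.

    Returns ``(calibration_report, prediction_report, model)``; the headline
    number is ``prediction_report.rpd``.
    """
    from .metrics import evaluate
    from .moecnn import MoECNNRegressor
    from .preprocess import remove_outliers, sg_smooth, spxy_split

    data = make_default_benchmark(seed=seed, n=n)
    clean, _ = remove_outliers(data, contamination=DEFAULT_OUTLIER_FRACTION, seed=seed)
    clean = sg_smooth(clean)
    split = spxy_split(clean, fraction=0.7)
    Xc = clean.absorbance[split.calibration_indices]
    yc = clean.reference[split.calibration_indices]
    Xp = clean.absorbance[split.prediction_indices]
    yp = clean.reference[split.prediction_indices]
    model = MoECNNRegressor(epochs=epochs, seed=seed).fit(Xc, yc)
    cal = evaluate(yc, model.predict(Xc), set_label="calibration")
    pred = evaluate(yp, model.predict(Xp), set_label="prediction")
    return cal, pred, model


def dataset_digest(data: SpectraSet) -> str:
    """SHA-256 over the rounded (1e-12) absorbance + reference bytes."""
    h = hashlib.sha256()
    h.update(np.round(data.absorbance, 12).tobytes())
    if data.reference is not None:
        h.update(np.round(data.reference, 12).tobytes())
    return h.hexdigest()


def fixture_manifest(seeds=(42,)) -> list[dict]:
    """Name/seed/digest rows for the frozen fixtures."""
    return [
        {
            "name": f"default_benchmark_seed{s}",
            "seed": int(s),
            "n": DEFAULT_N,
            "digest": dataset_digest(make_default_benchmark(seed=s)),
        }
        for s in seeds
    ]
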