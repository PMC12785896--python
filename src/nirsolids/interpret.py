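"""Wavelength-importance maps.

Two routes:

* :func:`plsr_importance` — loading-based importance of a fitted PLSR: the
  mean absolute loading of each wavelength across latent variables,
  normalized to a maximum of 1.
* :func:`shapley_attribution` — model-agnostic Shapley values on contiguous
  wavelength bins (the players of the cooperative game). A coalition's value
  is the model prediction with absent bins replaced by the background-mean
  spectrum. Estimation is by seeded permutation sampling (each sampled
  permutation contributes a telescoping sum, so local accuracy
  sum(phi) = f(x) - f(background mean) holds exactly on average); for small
  bin counts an exhaustive enumeration over all coalitions is available and
  serves as the exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .regression import PLSRegressorNIPALS

__all__ = ["ImportanceMap", "plsr_importance", "shapley_attribution", "shapley_exact"]


@dataclass
class ImportanceMap:
    wavelengths: np.ndarray
    importance: np.ndarray
    method: str
    normalization: str = "max-1"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.importance = np.asarray(self.importance, dtype=float)
        if self.wavelengths.shape != self.importance.shape:
            raise ValueError("wavelengths and importance must align")
        if np.any(self.importance < -1e-12):
            raise ValueError("importance scores must be non-negative")


def _normalize(scores: np.ndarray, normalization: str) -> np.ndarray:
    scores = np.maximum(scores, 0.0)
    if normalization == "max-1":
        top = scores.max()
        return scores / top if top > 0 else scores
    if normalization == "sum-1":
        total = scores.sum()
        return scores / total if total > 0 else scores
    raise ValueError(f"unknown normalization {normalization!r}")


def plsr_importance(
    model: PLSRegressorNIPALS, wavelengths=None, normalization: str = "max-1"
) -> ImportanceMap:
    """Mean |loading| per wavelength across all latent variables."""
    if not hasattr(model, "P_"):
        raise ValueError("model must be fitted")
    scores = np.abs(model.P_).mean(axis=1)
    wl = np.arange(scores.size) if wavelengths is None else np.asarray(wavelengths, float)
    return ImportanceMap(wl, _normalize(scores, normalization), "loading", normalization)


def _bin_slices(p: int, bins: int) -> list[np.ndarray]:
    """Partition p wavelengths into `bins` contiguous near-equal groups."""
    edges = np.linspace(0, p, bins + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(bins)]


def _coalition_predict(predict, x, background_mean, members, bin_groups):
    """Model value of one coalition: absent bins imputed by background mean."""
    z = np.tile(background_mean, (x.shape[0], 1))
    for b in members:
        z[:, bin_groups[b]] = x[:, bin_groups[b]]
    return predict(z)


def _as_predict(model):
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


def shapley_exact(model, background, explain, bins: int = 8) -> np.ndarray:
    """Exact per-sample Shapley values by enumeration over all 2^bins coalitions.

    Returns phi of shape (n_explain, bins). Intended for small bin counts
    (cost 2^bins model calls); acts as the oracle for the sampled estimator.
    """
    predict = _as_predict(model)
    background = np.atleast_2d(np.asarray(background, float))
    explain = np.atleast_2d(np.asarray(explain, float))
    if background.shape[0] == 0:
        raise ValueError("empty background set")
    groups = _bin_slices(explain.shape[1], bins)
    bg_mean = background.mean(axis=0)
    values: dict[frozenset, np.ndarray] = {}
    all_bins = list(range(bins))
    for size in range(bins + 1):
        for S in combinations(all_bins, size):
            values[frozenset(S)] = _coalition_predict(
                predict, explain, bg_mean, S, groups
            )
    phi = np.zeros((explain.shape[0], bins))
    for j in range(bins):
        others = [b for b in all_bins if b != j]
        for size in range(bins):
            weight = 1.0 / (bins * comb(bins - 1, size))
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[:, j] += weight * (values[fs | {j}] - values[fs])
    return phi


def shapley_sampled(
    model, background, explain, bins: int = 20, n_coalitions: int = 256, seed: int = 0
) -> np.ndarray:
    """Permutation-sampling Shapley estimate, phi of shape (n_explain, bins).

    ``n_coalitions`` counts sampled permutations; every permutation adds one
    marginal contribution per bin via a telescoping scan, so the efficiency
    identity holds exactly for each sampled permutation.
    """
    predict = _as_predict(model)
    background = np.atleast_2d(np.asarray(background, float))
    explain = np.atleast_2d(np.asarray(explain, float))
    if background.shape[0] == 0:
        raise ValueError("empty background set")
    groups = _bin_slices(explain.shape[1], bins)
    bg_mean = background.mean(axis=0)
    rng = np.random.default_rng(seed)
    phi = np.zeros((explain.shape[0], bins))
    for _ in range(n_coalitions):
        order = rng.permutation(bins)
        z = np.tile(bg_mean, (explain.shape[0], 1))
        prev = predict(z)
        for b in order:
            z[:, groups[b]] = explain[:, groups[b]]
            cur = predict(z)
            phi[:, b] += cur - prev
            prev = cur
    return phi / n_coalitions


def shapley_attribution(
    model,
    background,
    explain,
    n_coalitions: int = 256,
    bins: int = 20,
    seed: int = 0,
    wavelengths=None,
    exact: bool = False,
    normalization: str = "max-1",
) -> ImportanceMap:
    """Wavelength importance from Shapley values of contiguous bins.

    Per-sample bin attributions phi are averaged over the explain set as
    mean |phi| and expanded back to the full wavelength grid (each
    wavelength inherits its bin's score) before normalization.
    """
    if exact:
        phi = shapley_exact(model, background, explain, bins=bins)
    else:
        phi = shapley_sampled(
            model, background, explain, bins=bins,
            n_coalitions=n_coalitions, seed=seed,
        )
    bin_scores = np.abs(phi).mean(axis=0)
    explain = np.atleast_2d(np.asarray(explain, float))
    p = explain.shape[1]
    per_wl = np.empty(p)
    for score, idx in zip(bin_scores, _bin_slices(p, bins)):
        per_wl[idx] = score
    wl = np.arange(p) if wavelengths is None else np.asarray(wavelengths, float)
    return ImportanceMap(wl, _normalize(per_wl, normalization), "shapley", normalization)
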