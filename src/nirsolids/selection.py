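"""Wavelength selection over PLSR: UVE, VIP, CARS, and the full-spectrum
pass-through.

All selectors are sklearn-style transformers: ``fit(X, y)`` learns the
retained wavelength indices, ``transform(X)`` subsets columns, and
``get_support(indices=True)`` / ``result_`` expose the selection. Selection
always acts on columns (wavelengths), never on rows (samples).

* UVE (uninformative variable elimination) appends p tiny uniform-noise
  columns, collects leave-one-out PLSR coefficients, and keeps real
  wavelengths whose stability |mean(b)/sd(b)| exceeds the largest stability
  observed among the noise columns.
* VIP (variable importance in projection) keeps wavelengths with VIP > 1,
  where VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a) over the
  fitted PLSR components; the scores always satisfy mean(VIP^2) = 1.
* CARS (competitive adaptive reweighted sampling) runs Monte-Carlo PLSR fits
  on random 80-90% sample subsets; an exponential decay schedule forces the
  retained-wavelength count from p down to 2, adaptive reweighted sampling
  competes survivors by |coefficient|, and the subset with minimal k-fold
  RMSECV wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .regression import PLSRegressorNIPALS, rmsecv_curve, select_n_lv

__all__ = [
    "SelectionResult",
    "UVESelector",
    "VIPSelector",
    "CARSSelector",
    "FullSpectrumSelector",
    "uve_select",
    "vip_scores",
    "cars_select",
    "full_spectrum",
    "make_selector",
]


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``scores`` is the per-wavelength diagnostic: stability for UVE, VIP score
    for VIP, selection frequency across Monte-Carlo runs for CARS, ones for
    the full spectrum. CARS additionally reports ``best_rmsecv`` and a
    per-run record of (retained count, RMSECV).
    """

    method: str
    selected_indices: np.ndarray
    scores: np.ndarray
    best_rmsecv: float | None = None
    runs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size == 0:
            raise ValueError("selection must retain at least one wavelength")
        self.selected_indices = np.unique(self.selected_indices)


class _BaseSelector(BaseEstimator, TransformerMixin):
    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.result_.selected_indices]

    def get_support(self, indices: bool = True):
        if indices:
            return self.result_.selected_indices
        mask = np.zeros(self.result_.scores.size, dtype=bool)
        mask[self.result_.selected_indices] = True
        return mask


class UVESelector(_BaseSelector):
    """Uninformative variable elimination (stability vs. injected noise)."""

    def __init__(self, n_lv: int = 5, seed: int = 0):
        self.n_lv = n_lv
        self.seed = seed

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 3:
            raise ValueError("UVE needs at least 3 samples")
        n_lv = min(self.n_lv, n - 2, 2 * p)  # LOO fits use n-1 rows
        rng = np.random.default_rng(self.seed)
        scale = 1e-10 * max(np.abs(X).max(), 1.0)
        noise = rng.uniform(0.0, 1.0, size=(n, p)) * scale
        Xa = np.hstack([X, noise])
        coefs = np.empty((n, 2 * p))
        for i in range(n):
            rows = np.delete(np.arange(n), i)
            model = PLSRegressorNIPALS(n_lv=n_lv).fit(Xa[rows], y[rows])
            coefs[i] = model.coef_
        mean = coefs.mean(axis=0)
        sd = coefs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(sd > 0, mean / sd, np.where(mean != 0, np.inf, 0.0))
        stability = np.abs(c)
        cutoff = stability[p:].max()
        keep = np.flatnonzero(stability[:p] > cutoff)
        if keep.size == 0:
            keep = np.array([int(np.argmax(stability[:p]))])
        self.result_ = SelectionResult("uve", keep, stability[:p])
        return self


class VIPSelector(_BaseSelector):
    """Variable importance in projection with the conventional VIP > 1 rule."""

    def __init__(self, n_lv: int = 5, threshold: float = 1.0):
        self.n_lv = n_lv
        self.threshold = threshold

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if np.allclose(y, y[0]):
            raise ValueError("degenerate: y has zero variance")
        n, p = X.shape
        model = PLSRegressorNIPALS(n_lv=min(self.n_lv, n - 1, p)).fit(X, y)
        vip = compute_vip(model)
        keep = np.flatnonzero(vip > self.threshold)
        if keep.size == 0:
            keep = np.array([int(np.argmax(vip))])
        self.result_ = SelectionResult("vip", keep, vip)
        return self


def compute_vip(model: PLSRegressorNIPALS) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)."""
    W, T, q = model.W_, model.T_, model.q_
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # y-variance explained per LV
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


class CARSSelector(_BaseSelector):
    """Competitive adaptive reweighted sampling.

    The PLSR component count used inside cross-validation is chosen once on
    the full data before the Monte-Carlo runs and held fixed, so RMSECV
    values are comparable across candidate subsets. Per run i (1-based) the
    exponential decay schedule keeps round(r_i * p) wavelengths with
    r_i = a e^{-k i}, r_1 = 1, r_N = 2/p; forced removal makes a
    deterministic coarse cut (top |coefficient|, ties to the lower index),
    then adaptive reweighted sampling competes the remainder down to the
    scheduled count by a weighted draw without replacement with probability
    proportional to |coefficient|. The scheduled count never drops below 2,
    so a PLSR fit is always possible.
    """

    def __init__(
        self,
        n_runs: int = 100,
        cv_folds: int = 5,
        max_lv: int = 10,
        seed: int = 0,
    ):
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.max_lv = max_lv
        self.seed = seed

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if p < 2:
            raise ValueError("CARS needs at least 2 wavelengths")
        if self.n_runs < 2 or self.cv_folds < 2:
            raise ValueError("n_runs and cv_folds must be >= 2")
        rng = np.random.default_rng(self.seed)
        n_lv, _ = select_n_lv(
            X, y, max_lv=self.max_lv, folds=self.cv_folds, seed=self.seed
        )

        N = self.n_runs
        k = np.log(p / 2.0) / (N - 1)
        ratios = np.exp(k) * np.exp(-k * np.arange(1, N + 1))
        hits = np.zeros(p)
        survivors = np.arange(p)
        runs: list[dict] = []
        best_idx, best_rmsecv = None, np.inf
        for i in range(N):
            frac = rng.uniform(0.80, 0.90)
            rows = rng.choice(n, size=max(2, int(round(frac * n))), replace=False)
            lv = min(n_lv, rows.size - 1, survivors.size)
            model = PLSRegressorNIPALS(n_lv=lv).fit(X[np.ix_(rows, survivors)], y[rows])
            b = np.abs(model.coef_)
            # forced removal: deterministic coarse cut to twice the scheduled
            # count by |b| (ties -> lower index) ...
            n_keep = min(max(2, int(round(ratios[i] * p))), survivors.size)
            n_force = min(2 * n_keep, survivors.size)
            order = np.lexsort((np.arange(b.size), -b))
            survivors = survivors[order[:n_force]]
            b = b[order[:n_force]]
            # ... then adaptive reweighted sampling competes the survivors
            # down to the scheduled count: a weighted draw without
            # replacement with probability proportional to |b|
            if survivors.size > n_keep:
                if np.count_nonzero(b) >= n_keep:
                    pick = rng.choice(
                        survivors.size, size=n_keep, replace=False, p=b / b.sum()
                    )
                else:
                    pick = np.arange(n_keep)  # b already sorted descending
                b = b[pick]
                survivors = survivors[pick]
            sort_order = np.argsort(survivors)
            survivors, b = survivors[sort_order], b[sort_order]
            hits[survivors] += 1
            lv_eval = min(n_lv, survivors.size, n - 1 - int(np.ceil(n / self.cv_folds)))
            curve = rmsecv_curve(
                X[:, survivors], y, max_lv=max(lv_eval, 1),
                folds=self.cv_folds, seed=self.seed,
            )
            rmsecv = float(curve[-1])
            runs.append({"n_retained": int(n_keep), "rmsecv": rmsecv})
            if rmsecv < best_rmsecv:
                best_rmsecv, best_idx = rmsecv, survivors.copy()
        self.result_ = SelectionResult(
            "cars", best_idx, hits / N, best_rmsecv=best_rmsecv, runs=runs
        )
        return self


class FullSpectrumSelector(_BaseSelector):
    """Pass-through: every wavelength selected."""

    def fit(self, X, y=None):
        p = np.atleast_2d(np.asarray(X)).shape[1]
        if p < 1:
            raise ValueError("need at least one wavelength")
        self.result_ = SelectionResult("fs", np.arange(p), np.ones(p))
        return self


# -- thin functional wrappers ------------------------------------------------

def uve_select(X, y, n_lv: int = 5, seed: int = 0) -> SelectionResult:
    return UVESelector(n_lv=n_lv, seed=seed).fit(X, y).result_


def vip_scores(X, y, n_lv: int = 5) -> SelectionResult:
    return VIPSelector(n_lv=n_lv).fit(X, y).result_


def cars_select(
    X, y, n_runs: int = 100, cv_folds: int = 5, seed: int = 0, max_lv: int = 10
) -> SelectionResult:
    return (
        CARSSelector(n_runs=n_runs, cv_folds=cv_folds, max_lv=max_lv, seed=seed)
        .fit(X, y)
        .result_
    )


def full_spectrum(p: int) -> SelectionResult:
    return FullSpectrumSelector().fit(np.zeros((1, p))).result_


def make_selector(method: str, **kwargs):
    """Selector factory for the CLI: one of uve, vip, cars, fs."""
    table = {
        "uve": UVESelector,
        "vip": VIPSelector,
        "cars": CARSSelector,
        "fs": FullSpectrumSelector,
    }
    if method not in table:
        raise ValueError(f"unknown selection method {method!r}")
    cls = table[method]
    valid = cls().get_params().keys()
    return cls(**{k: v for k, v in kwargs.items() if k in valid})
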