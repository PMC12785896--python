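"""Chemometric regressors: PLSR (NIPALS), GRNN, LSSVM, and an epsilon-SVR
delegate — all sklearn-style estimators.

PLSR is fitted by the classic NIPALS sequence on column-centered data
(variance scaling optional and off by default: absorbance units are
homogeneous across wavelengths). The GRNN is the Gaussian-kernel
Nadaraya-Watson smoother; the LSSVM solves the standard least-squares SVM
linear system with an RBF kernel. Hyperparameters (latent-variable count,
GRNN spread, LSSVM gamma/width) are chosen by k-fold cross-validated RMSE
with a shared convention of 5 folds.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError, solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "PLSRegressorNIPALS",
    "GRNNRegressor",
    "LSSVMRegressor",
    "EpsilonSVR",
    "plsr_fit",
    "plsr_predict",
    "select_n_lv",
    "grnn_predict",
    "lssvm_fit",
    "lssvm_predict",
]


class PLSRegressorNIPALS(BaseEstimator, RegressorMixin):
    """Partial least squares regression (PLS1) fitted by NIPALS.

    Parameters
    ----------
    n_lv : int
        Number of latent variables (score/loading pairs) to extract.
    scale : bool
        If True, X columns are scaled to unit variance as well as centered.

    Attributes
    ----------
    W_ : ndarray (p, A)   weight vectors (unit norm)
    P_ : ndarray (p, A)   X loadings
    q_ : ndarray (A,)     y loadings
    T_ : ndarray (n, A)   scores (mutually orthogonal)
    coef_ : ndarray (p,)  regression vector on (centered/scaled) X
    x_mean_, y_mean_, x_scale_ : centering/scaling state
    """

    def __init__(self, n_lv: int = 2, scale: bool = False):
        self.n_lv = n_lv
        self.scale = scale

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if y.shape != (n,):
            raise ValueError("y length must equal n_samples")
        if not 1 <= self.n_lv <= min(n - 1, p):
            raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        self.x_scale_ = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self.x_scale_ = np.where(self.x_scale_ == 0, 1.0, self.x_scale_)
        Xc = (X - self.x_mean_) / self.x_scale_
        yc = y - self.y_mean_

        A = self.n_lv
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        q = np.zeros(A)
        Xr, yr = Xc.copy(), yc.copy()
        norm0 = np.linalg.norm(Xc.T @ yc)
        tt0 = None
        for a in range(A):
            w = Xr.T @ yr
            norm = np.linalg.norm(w)
            if norm <= max(1e-12 * norm0, 1e-300):
                # residual information exhausted; truncate quietly
                A = a
                W, P, T, q = W[:, :A], P[:, :A], T[:, :A], q[:A]
                break
            w /= norm
            t = Xr @ w
            tt = t @ t
            tt0 = tt if tt0 is None else tt0
            if tt <= 1e-24 * tt0:
                A = a
                W, P, T, q = W[:, :A], P[:, :A], T[:, :A], q[:A]
                break
            pvec = Xr.T @ t / tt
            qa = yr @ t / tt
            Xr = Xr - np.outer(t, pvec)
            yr = yr - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        if A == 0:
            raise ValueError("degenerate problem: X'y is zero")
        self.n_lv_ = A
        self.W_, self.P_, self.T_, self.q_ = W, P, T, q
        # b = W (P'W)^-1 q  maps centered/scaled X directly to centered y
        self.coef_ = W @ solve(P.T @ W, q)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was fit with {self.x_mean_.size}"
            )
        return (X - self.x_mean_) / self.x_scale_ @ self.coef_ + self.y_mean_

    def predict_via_scores(self, X):
        """Component-space prediction path (algebraically equals predict)."""
        Xc = (np.atleast_2d(np.asarray(X, float)) - self.x_mean_) / self.x_scale_
        T = Xc @ self.W_ @ np.linalg.inv(self.P_.T @ self.W_)
        return T @ self.q_ + self.y_mean_


def plsr_fit(X, y, n_lv: int, scale: bool = False) -> PLSRegressorNIPALS:
    return PLSRegressorNIPALS(n_lv=n_lv, scale=scale).fit(X, y)


def plsr_predict(model: PLSRegressorNIPALS, X) -> np.ndarray:
    return model.predict(X)


def rmsecv_curve(
    X, y, max_lv: int, folds: int = 5, seed: int = 0, scale: bool = False
) -> np.ndarray:
    """Fold-wise RMSECV for PLSR with 1..max_lv latent variables."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    max_lv = min(max_lv, X.shape[1], n - 1 - int(np.ceil(n / folds)))
    max_lv = max(max_lv, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    press = np.zeros(max_lv)
    for train, test in kf.split(X):
        cap = min(max_lv, len(train) - 1, X.shape[1])
        model = PLSRegressorNIPALS(n_lv=cap, scale=scale).fit(X[train], y[train])
        Xc = (X[test] - model.x_mean_) / model.x_scale_
        # accumulate predictions per component count without refitting
        R = np.linalg.inv(model.P_.T @ model.W_)
        T = Xc @ model.W_ @ R
        for a in range(max_lv):
            aa = min(a + 1, model.n_lv_)
            pred = T[:, :aa] @ model.q_[:aa] + model.y_mean_
            press[a] += np.sum((pred - y[test]) ** 2)
    return np.sqrt(press / n)


def select_n_lv(
    X, y, max_lv: int = 15, folds: int = 5, seed: int = 0, scale: bool = False
) -> tuple[int, np.ndarray]:
    """CV-optimal latent-variable count (ties -> smaller) plus the RMSECV curve.

    Curve values within a 1e-9 relative band of the minimum count as ties,
    so numerically indistinguishable fits resolve to the simpler model.
    """
    curve = rmsecv_curve(X, y, max_lv, folds=folds, seed=seed, scale=scale)
    cutoff = curve.min() * (1 + 1e-9) + 1e-12
    return int(np.argmax(curve <= cutoff) + 1), curve


class GRNNRegressor(BaseEstimator, RegressorMixin):
    """Generalized regression neural network (Gaussian Nadaraya-Watson).

    yhat(x) = sum_i y_i K_i / sum_i K_i with K_i = exp(-||x - x_i||^2 / 2 sigma^2).
    The kernel is normalized after subtracting the smallest squared distance
    per query, so predictions stay finite for any sigma > 0.
    """

    def __init__(self, sigma: float = 1.0):
        self.sigma = sigma

    def fit(self, X, y):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.X_ = np.atleast_2d(np.asarray(X, dtype=float))
        self.y_ = np.asarray(y, dtype=float).ravel()
        if self.X_.shape[0] == 0:
            raise ValueError("empty calibration set")
        if self.y_.shape[0] != self.X_.shape[0]:
            raise ValueError("X and y disagree on n_samples")
        return self

    def predict(self, X):
        Xq = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((Xq[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        d2 = d2 - d2.min(axis=1, keepdims=True)  # underflow guard
        w = np.exp(-d2 / (2.0 * self.sigma**2))
        return (w @ self.y_) / w.sum(axis=1)


def grnn_predict(Xc, yc, Xq, sigma: float) -> np.ndarray:
    return GRNNRegressor(sigma=sigma).fit(Xc, yc).predict(Xq)


class LSSVMRegressor(BaseEstimator, RegressorMixin):
    """Least-squares SVM regression with an RBF kernel.

    Solves [[0, 1'], [1, K + I/gamma]] [b; alpha] = [0; y] and predicts
    yhat(x) = sum_i alpha_i k(x, x_i) + b with
    k(x, z) = exp(-||x - z||^2 / (2 width^2)).
    """

    def __init__(self, gamma: float = 10.0, width: float = 1.0):
        self.gamma = gamma
        self.width = width

    def _kernel(self, A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.width**2))

    def fit(self, X, y):
        if self.gamma <= 0 or self.width <= 0:
            raise ValueError("gamma and width must be > 0")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        K = self._kernel(X, X)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], y])
        try:
            sol = solve(A, rhs)
        except LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "LSSVM system is singular; increase gamma or perturb the data"
            ) from exc
        self.X_ = X
        self.bias_ = float(sol[0])
        self.alpha_ = sol[1:]
        self._residual_ = float(np.linalg.norm(A @ sol - rhs))
        return self

    def predict(self, X):
        Xq = np.atleast_2d(np.asarray(X, dtype=float))
        return self._kernel(Xq, self.X_) @ self.alpha_ + self.bias_


def lssvm_fit(X, y, gamma: float, width: float) -> LSSVMRegressor:
    return LSSVMRegressor(gamma=gamma, width=width).fit(X, y)


def lssvm_predict(model: LSSVMRegressor, Xq) -> np.ndarray:
    return model.predict(Xq)


class EpsilonSVR(BaseEstimator, RegressorMixin):
    """Epsilon-SVR behind the shared fit/predict contract (delegates to
    an established sequential-minimal-optimization solver)."""

    def __init__(self, C: float = 10.0, epsilon: float = 0.1, gamma="scale"):
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma

    def fit(self, X, y):
        self._X_train_ = np.atleast_2d(np.asarray(X, float))
        self._y_train_ = np.asarray(y, float).ravel()
        self._svr_ = _SkSVR(C=self.C, epsilon=self.epsilon, gamma=self.gamma)
        self._svr_.fit(self._X_train_, self._y_train_)
        return self

    def predict(self, X):
        return self._svr_.predict(np.atleast_2d(np.asarray(X, float)))


def grid_search_cv(
    estimator_factory,
    grid: list[dict],
    X,
    y,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Pick the grid point with minimal k-fold RMSECV (ties -> first listed)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best, best_rmse = None, np.inf
    for params in grid:
        press = 0.0
        for train, test in splits:
            model = estimator_factory(**params).fit(X[train], y[train])
            press += np.sum((model.predict(X[test]) - y[test]) ** 2)
        rmse_cv = np.sqrt(press / len(y))
        if rmse_cv < best_rmse:
            best, best_rmse = params, rmse_cv
    return {**best, "rmsecv": float(best_rmse)}
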