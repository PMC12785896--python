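"""Mixture-of-experts 1-D CNN regressor for spectral calibration, plus its
gating-ablated CNN control.

Architecture (lengths for the default 901-point grid)::

    input (1, 901)
    Conv1d 1->2, k5 s1 p2  -> (2, 901)   + BatchNorm + ReLU
    AvgPool k2 s2          -> (2, 450)
    Conv1d 2->4, k3 s1 p1  -> (4, 450)   + BatchNorm + ReLU
    Flatten                -> 1800
    Gate   1800 -> n_experts  (softmax weights w, sum to 1)
    Expert_i 1800 -> 600 (+ReLU), i = 1..n_experts
    Fusion  f = sum_i w_i * E_i          (the gating-expert fusion step)
    Head    600 -> 1

The ablated CNN replaces gate/experts/fusion by a single 1800 -> 600 linear
(+ReLU) path into the same head. Both are trained with Adam (lr 0.001) on a
mean-squared-error loss; inputs are z-scored per wavelength and the target is
z-scored, using calibration-set statistics stored in the model. The whole
network is implemented in numpy (forward and backward passes written out),
which keeps the package dependency-light and fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MoECNNConfig",
    "MoECNNRegressor",
    "CNNRegressor",
    "build_model",
    "build_ablated_cnn",
    "train",
    "predict",
    "gef_fuse",
    "conv_output_length",
    "flatten_dim",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def conv_output_length(length: int, kernel: int, stride: int, padding: int) -> int:
    """L_out = floor((L + 2P - K)/S) + 1."""
    return (length + 2 * padding - kernel) // stride + 1


@dataclass
class MoECNNConfig:
    """Hyperparameters of the MoE-CNN (defaults match the reference design)."""

    input_length: int = 901
    conv1_out: int = 2
    conv1_kernel: int = 5
    conv1_pad: int = 2
    pool_kernel: int = 2
    pool_stride: int = 2
    conv2_out: int = 4
    conv2_kernel: int = 3
    conv2_pad: int = 1
    n_experts: int = 2
    expert_dim: int = 600
    lr: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    seed: int = 42

    @property
    def pooled_length(self) -> int:
        l1 = conv_output_length(self.input_length, self.conv1_kernel, 1, self.conv1_pad)
        return conv_output_length(l1, self.pool_kernel, self.pool_stride, 0)

    @property
    def flatten_dim(self) -> int:
        l2 = conv_output_length(self.pooled_length, self.conv2_kernel, 1, self.conv2_pad)
        return self.conv2_out * l2

    @property
    def gate_dim(self) -> int:
        return self.n_experts


def flatten_dim(config: MoECNNConfig) -> int:
    return config.flatten_dim


def gef_fuse(expert_outputs: np.ndarray, gate_logits: np.ndarray) -> np.ndarray:
    """Gating-expert fusion: softmax the logits, convex-combine the experts.

    ``expert_outputs``: (N, expert_dim) stack of N expert vectors;
    ``gate_logits``: (N,) scores. Returns the fused vector of length
    expert_dim: f = sum_i softmax(logits)_i * E_i.
    """
    E = np.atleast_2d(np.asarray(expert_outputs, dtype=float))
    logits = np.asarray(gate_logits, dtype=float).ravel()
    if E.shape[0] != logits.size:
        raise ValueError("one gate logit per expert output required")
    if E.shape[0] < 1:
        raise ValueError("need at least one expert")
    w = _softmax(logits[None, :])[0]
    return w @ E


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# layer primitives (batch-first, float64)

def _conv1d_forward(x, W, b, pad):
    """x (N,Cin,L), W (Cout,Cin,K) -> out (N,Cout,L'), cached im2col."""
    N, Cin, L = x.shape
    Cout, _, K = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, K, axis=2)          # (N,Cin,L',K)
    cols = win.transpose(0, 2, 1, 3).reshape(N, -1, Cin * K)  # (N,L',Cin*K)
    out = cols @ W.reshape(Cout, -1).T + b            # (N,L',Cout)
    return out.transpose(0, 2, 1), cols


def _conv1d_backward(dout, cols, W, pad, in_shape):
    N, Cin, L = in_shape
    Cout, _, K = W.shape
    doutr = dout.transpose(0, 2, 1)                   # (N,L',Cout)
    dW = np.einsum("nlc,nlk->ck", doutr, cols).reshape(Cout, Cin, K)
    db = doutr.sum(axis=(0, 1))
    dcols = doutr @ W.reshape(Cout, -1)               # (N,L',Cin*K)
    dcols = dcols.reshape(N, -1, Cin, K).transpose(0, 2, 1, 3)
    dxp = np.zeros((N, Cin, L + 2 * pad))
    Lp = dcols.shape[2]
    for k in range(K):
        dxp[:, :, k : k + Lp] += dcols[:, :, :, k]
    return dxp[:, :, pad : pad + L], dW, db


def _bn_forward(x, gamma, beta, running, training, momentum=0.1, eps=1e-5):
    """Channel batch-norm over (N,C,L)."""
    if training:
        mu = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu[None, :, None]) * inv[None, :, None]
    out = gamma[None, :, None] * xhat + beta[None, :, None]
    return out, (xhat, inv)


def _bn_backward(dout, cache, gamma):
    xhat, inv = cache
    N, C, L = dout.shape
    M = N * L
    dgamma = (dout * xhat).sum(axis=(0, 2))
    dbeta = dout.sum(axis=(0, 2))
    dxhat = dout * gamma[None, :, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2), keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / M
    ) * inv[None, :, None]
    return dx, dgamma, dbeta


def _avgpool_forward(x, k, s):
    N, C, L = x.shape
    Lp = (L - k) // s + 1
    idx = (np.arange(Lp) * s)[:, None] + np.arange(k)[None, :]
    return x[:, :, idx].mean(axis=3), (L, Lp, idx)


def _avgpool_backward(dout, cache, k):
    L, Lp, idx = cache
    N, C, _ = dout.shape
    dx = np.zeros((N, C, L))
    for j in range(k):
        np.add.at(dx, (slice(None), slice(None), idx[:, j]), dout / k)
    return dx


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------

class MoECNNRegressor(BaseEstimator, RegressorMixin):
    """The mixture-of-experts CNN as a sklearn-style regressor.

    Attributes after fit: ``params_`` (all weights), ``running_bn_``
    (batch-norm statistics), ``history_`` (per-epoch training loss),
    ``x_mean_/x_sd_/y_mean_/y_sd_`` (normalization state),
    ``fitted_values_`` (eval-mode predictions on the calibration rows).
    """

    _gated = True

    def __init__(
        self,
        epochs: int = 500,
        batch_size: int = 32,
        lr: float = 0.001,
        n_experts: int = 2,
        expert_dim: int = 600,
        seed: int = 42,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_experts = n_experts
        self.expert_dim = expert_dim
        self.seed = seed

    # -- construction ----------------------------------------------------
    def _make_config(self, input_length: int) -> MoECNNConfig:
        return MoECNNConfig(
            input_length=input_length,
            n_experts=self.n_experts,
            expert_dim=self.expert_dim,
            lr=self.lr,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def _init_params(self, cfg: MoECNNConfig, rng: np.random.Generator) -> dict:
        def lin(fan_in, *shape):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        F, D, E = cfg.flatten_dim, cfg.expert_dim, cfg.n_experts
        params = {
            "W1": lin(1 * cfg.conv1_kernel, cfg.conv1_out, 1, cfg.conv1_kernel),
            "b1": lin(1 * cfg.conv1_kernel, cfg.conv1_out),
            "g1": np.ones(cfg.conv1_out),
            "be1": np.zeros(cfg.conv1_out),
            "W2": lin(cfg.conv1_out * cfg.conv2_kernel,
                      cfg.conv2_out, cfg.conv1_out, cfg.conv2_kernel),
            "b2": lin(cfg.conv1_out * cfg.conv2_kernel, cfg.conv2_out),
            "g2": np.ones(cfg.conv2_out),
            "be2": np.zeros(cfg.conv2_out),
            "Wh": lin(D, 1, D),
            "bh": lin(D, 1),
        }
        if self._gated:
            params["Wg"] = lin(F, E, F)
            params["bg"] = lin(F, E)
            params["We"] = lin(F, E, D, F)
            params["be"] = lin(F, E, D)
        else:
            params["We"] = lin(F, 1, D, F)
            params["be"] = lin(F, 1, D)
        return params

    # -- forward ---------------------------------------------------------
    def _backbone_forward(self, X, training):
        p = self.params_
        x = X[:, None, :]
        o1, cols1 = _conv1d_forward(x, p["W1"], p["b1"], self.config_.conv1_pad)
        n1, bn1c = _bn_forward(o1, p["g1"], p["be1"], self.running_bn_["bn1"], training)
        r1 = np.maximum(n1, 0.0)
        pl, poolc = _avgpool_forward(r1, self.config_.pool_kernel, self.config_.pool_stride)
        o2, cols2 = _conv1d_forward(pl, p["W2"], p["b2"], self.config_.conv2_pad)
        n2, bn2c = _bn_forward(o2, p["g2"], p["be2"], self.running_bn_["bn2"], training)
        r2 = np.maximum(n2, 0.0)
        N = X.shape[0]
        flat = r2.reshape(N, -1)
        cache = (x, cols1, n1, bn1c, r1, poolc, pl, cols2, n2, bn2c, r2)
        return flat, cache

    def _head_forward(self, flat):
        p = self.params_
        E, D = self.config_.n_experts if self._gated else 1, self.config_.expert_dim
        N = flat.shape[0]
        We2 = p["We"].reshape(-1, flat.shape[1])
        Z = (flat @ We2.T).reshape(N, -1, D) + p["be"][None]
        H = np.maximum(Z, 0.0)
        if self._gated:
            logits = flat @ p["Wg"].T + p["bg"]
            w = _softmax(logits)
            fused = np.einsum("ne,ned->nd", w, H)
        else:
            w = None
            fused = H[:, 0, :]
        yhat = fused @ p["Wh"].T + p["bh"]
        return yhat[:, 0], (Z, H, w, fused)

    def _forward(self, X, training):
        flat, bcache = self._backbone_forward(X, training)
        yhat, hcache = self._head_forward(flat)
        return yhat, flat, bcache, hcache

    # -- backward --------------------------------------------------------
    def _backward(self, X, dyhat, flat, bcache, hcache):
        p = self.params_
        cfg = self.config_
        grads = {}
        Z, H, w, fused = hcache
        N, D = fused.shape
        dy = dyhat[:, None]
        grads["Wh"] = dy.T @ fused
        grads["bh"] = dy.sum(axis=0)
        dfused = dy @ p["Wh"]
        if self._gated:
            dH = w[:, :, None] * dfused[:, None, :]
            dw = np.einsum("nd,ned->ne", dfused, H)
            dlogits = w * (dw - (dw * w).sum(axis=1, keepdims=True))
            grads["Wg"] = dlogits.T @ flat
            grads["bg"] = dlogits.sum(axis=0)
            dflat = dlogits @ p["Wg"]
        else:
            dH = dfused[:, None, :]
            dflat = np.zeros_like(flat)
        dZ = dH * (Z > 0)
        dZ2 = dZ.reshape(N, -1)
        We2 = p["We"].reshape(-1, flat.shape[1])
        grads["We"] = (dZ2.T @ flat).reshape(p["We"].shape)
        grads["be"] = dZ.sum(axis=0)
        dflat = dflat + dZ2 @ We2

        x, cols1, n1, bn1c, r1, poolc, pl, cols2, n2, bn2c, r2 = bcache
        dr2 = dflat.reshape(r2.shape)
        dn2 = dr2 * (n2 > 0)
        do2, grads["g2"], grads["be2"] = _bn_backward(dn2, bn2c, p["g2"])
        dpl, grads["W2"], grads["b2"] = _conv1d_backward(
            do2, cols2, p["W2"], cfg.conv2_pad, pl.shape
        )
        dr1 = _avgpool_backward(dpl, poolc, cfg.pool_kernel)
        dn1 = dr1 * (n1 > 0)
        do1, grads["g1"], grads["be1"] = _bn_backward(dn1, bn1c, p["g1"])
        _, grads["W1"], grads["b1"] = _conv1d_backward(
            do1, cols1, p["W1"], cfg.conv1_pad, x.shape
        )
        return grads

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, L = X.shape
        if y.shape != (n,):
            raise ValueError("y length must equal n_samples")
        self.config_ = self._make_config(L)
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(self.config_, rng)
        self.running_bn_ = {
            "bn1": {"mean": np.zeros(self.config_.conv1_out),
                    "var": np.ones(self.config_.conv1_out)},
            "bn2": {"mean": np.zeros(self.config_.conv2_out),
                    "var": np.ones(self.config_.conv2_out)},
        }
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd_ = np.where(sd == 0, 1.0, sd)
        self.y_mean_ = float(y.mean())
        ysd = float(y.std())
        self.y_sd_ = ysd if ysd > 0 else 1.0
        Xn = (X - self.x_mean_) / self.x_sd_
        yn = (y - self.y_mean_) / self.y_sd_

        opt = _Adam(self.params_, self.lr)
        bs = self.batch_size if n >= self.batch_size else n  # full-batch fallback
        self.history_ = []
        for _ in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = perm[start : start + bs]
                yhat, flat, bc, hc = self._forward(Xn[idx], training=True)
                resid = yhat - yn[idx]
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise DivergenceError("training loss became non-finite")
                dyhat = 2.0 * resid / idx.size
                grads = self._backward(Xn[idx], dyhat, flat, bc, hc)
                opt.step(self.params_, grads)
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        self.fitted_values_ = self.predict(X)
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config_.input_length:
            raise ValueError(
                f"X has {X.shape[1]} wavelengths; model expects "
                f"{self.config_.input_length}"
            )
        Xn = (X - self.x_mean_) / self.x_sd_
        yhat, *_ = self._forward(Xn, training=False)
        return yhat * self.y_sd_ + self.y_mean_

    def gate_weights(self, X):
        """Per-sample softmax gate weights (rows sum to 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = (X - self.x_mean_) / self.x_sd_
        flat, _ = self._backbone_forward(Xn, training=False)
        return _softmax(flat @ self.params_["Wg"].T + self.params_["bg"])

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params_.values()))


class CNNRegressor(MoECNNRegressor):
    """Gating-ablated control: identical backbone, single linear path
    flatten -> expert_dim (+ReLU) -> 1, no gate and one branch only."""

    _gated = False

    def __init__(
        self,
        epochs: int = 500,
        batch_size: int = 32,
        lr: float = 0.001,
        expert_dim: int = 600,
        seed: int = 42,
    ):
        super().__init__(
            epochs=epochs, batch_size=batch_size, lr=lr,
            n_experts=1, expert_dim=expert_dim, seed=seed,
        )

    def gate_weights(self, X):  # pragma: no cover - contract guard
        raise AttributeError("the ablated CNN has no gating unit")


# -- functional wrappers -----------------------------------------------------

def build_model(config: MoECNNConfig) -> MoECNNRegressor:
    model = MoECNNRegressor(
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
        n_experts=config.n_experts, expert_dim=config.expert_dim,
        seed=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    model.config_ = config
    model.params_ = model._init_params(config, rng)
    return model


def build_ablated_cnn(config: MoECNNConfig) -> CNNRegressor:
    model = CNNRegressor(
        epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
        expert_dim=config.expert_dim, seed=config.seed,
    )
    rng = np.random.default_rng(config.seed)
    cfg = MoECNNConfig(**{**config.__dict__, "n_experts": 1})
    model.config_ = cfg
    model.params_ = model._init_params(cfg, rng)
    return model


def train(model: MoECNNRegressor, Xc, yc, config: MoECNNConfig | None = None):
    if config is not None:
        model.set_params(
            epochs=config.epochs, batch_size=config.batch_size,
            lr=config.lr, seed=config.seed,
        )
    return model.fit(Xc, yc)


def predict(model: MoECNNRegressor, Xq) -> np.ndarray:
    return model.predict(Xq)
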