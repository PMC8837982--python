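"""Minimal single-layer LSTM regressor (pure numpy, full BPTT).

Maps a short window of per-epoch normalized soil features (soil
temperature, moisture content, electrical conductivity) to the
normalized NDVI at the window's final epoch. The cell is the textbook
gated recurrence:

    z   = tanh(W  ·[x_t, h_{t−1}] + b)        candidate value
    z_i = σ(W_i·[x_t, h_{t−1}] + b_i)         input gate
    z_f = σ(W_f·[x_t, h_{t−1}] + b_f)         forget gate
    z_o = σ(W_o·[x_t, h_{t−1}] + b_o)         output gate
    c_t = z_f ⊙ c_{t−1} + z_i ⊙ z
    h_t = z_o ⊙ tanh(c_t)
    y   = σ(W′·h_L + b′)                      scalar readout

The sigmoid readout keeps predictions in (0, 1), matching min–max
normalized NDVI targets. Training is full-batch gradient descent with
Adam updates on the mean-squared error; the dataset is at most a few
dozen windows, so there is no mini-batching. Analytic gradients are
exposed (:func:`loss_and_grads`) so they can be checked against finite
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .metrics import MetricReport, score
from .preprocess import MinMaxParams, normalize

__all__ = [
    "LSTMParams",
    "SequenceDataset",
    "init_params",
    "cell_forward",
    "forward",
    "loss_and_grads",
    "train",
    "make_sequences",
    "LstmModel",
    "LstmResults",
]

DEFAULT_HIDDEN = 16
DEFAULT_LR = 0.01
DEFAULT_EPOCHS = 500
INIT_SCALE = 0.1


class TrainingError(RuntimeError):
    def __init__(self, msg, last_finite_epoch=None, history=None):
        super().__init__(msg)
        self.last_finite_epoch = last_finite_epoch
        self.history = history


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMParams:
    """Gate weight blocks acting on the concatenation [x_t, h_{t−1}].

    Each W* has shape (H, D + H) with the matching bias of shape (H,);
    the readout ``Wy`` has shape (H,) with scalar bias ``by``.
    """

    Wz: np.ndarray
    Wi: np.ndarray
    Wf: np.ndarray
    Wo: np.ndarray
    bz: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bo: np.ndarray
    Wy: np.ndarray
    by: np.ndarray  # 0-d array so it is mutable in place

    @property
    def hidden_size(self) -> int:
        return self.Wz.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[1] - self.Wz.shape[0]

    def copy(self) -> "LSTMParams":
        return replace(self, **{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def arrays(self):
        return [getattr(self, f.name) for f in fields(self)]

    def check_finite(self):
        for f in fields(self):
            if not np.all(np.isfinite(getattr(self, f.name))):
                norms = {g.name: float(np.linalg.norm(getattr(self, g.name)))
                         for g in fields(self)}
                raise TrainingError(f"non-finite parameters; norms: {norms}")


def init_params(input_size: int, hidden_size: int, seed: int = 0,
                scale: float = INIT_SCALE) -> LSTMParams:
    """Small-uniform initialisation in ±scale, deterministic under seed."""
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    rng = np.random.default_rng(seed)

    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    d = input_size + hidden_size
    return LSTMParams(
        Wz=u(hidden_size, d), Wi=u(hidden_size, d),
        Wf=u(hidden_size, d), Wo=u(hidden_size, d),
        bz=u(hidden_size), bi=u(hidden_size),
        bf=u(hidden_size), bo=u(hidden_size),
        Wy=u(hidden_size), by=np.asarray(u()),
    )


def cell_forward(x_t, h_prev, c_prev, params: LSTMParams):
    """One cell step; accepts (D,)/(H,) vectors or (N, D)/(N, H) batches."""
    x_t = np.atleast_2d(np.asarray(x_t, float))
    h_prev = np.atleast_2d(np.asarray(h_prev, float))
    c_prev = np.atleast_2d(np.asarray(c_prev, float))
    concat = np.concatenate([x_t, h_prev], axis=1)
    z = np.tanh(concat @ params.Wz.T + params.bz)
    zi = _sigmoid(concat @ params.Wi.T + params.bi)
    zf = _sigmoid(concat @ params.Wf.T + params.bf)
    zo = _sigmoid(concat @ params.Wo.T + params.bo)
    c_t = zf * c_prev + zi * z
    tanh_c = np.tanh(c_t)
    h_t = zo * tanh_c
    if not (np.all(np.isfinite(h_t)) and np.all(np.isfinite(c_t))):
        params.check_finite()
        raise TrainingError("non-finite cell activation")
    cache = (concat, z, zi, zf, zo, c_prev, c_t, tanh_c)
    return h_t, c_t, cache


def forward(X, params: LSTMParams):
    """Unroll over a window; returns predictions in (0, 1).

    ``X`` is (L, D) for one window or (N, L, D) for a batch; the
    initial hidden and cell states are zero.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    n, length, _ = X.shape
    if length < 1:
        raise ValueError("window length must be >= 1")
    h = np.zeros((n, params.hidden_size))
    c = np.zeros((n, params.hidden_size))
    for t in range(length):
        h, c, _ = cell_forward(X[:, t, :], h, c, params)
    y = _sigmoid(h @ params.Wy + float(params.by))
    return float(y[0]) if single else y


def loss_and_grads(params: LSTMParams, X, y):
    """Mean-squared-error loss and analytic gradients via BPTT."""
    X = np.asarray(X, dtype=float)
    t = np.asarray(y, dtype=float).ravel()
    n, length, _ = X.shape
    h = np.zeros((n, params.hidden_size))
    c = np.zeros((n, params.hidden_size))
    caches, hs = [], [h]
    for step in range(length):
        h, c, cache = cell_forward(X[:, step, :], h, c, params)
        caches.append(cache)
        hs.append(h)
    pre = hs[-1] @ params.Wy + float(params.by)
    yhat = _sigmoid(pre)
    err = yhat - t
    loss = float(np.mean(err**2))

    g = init_params(params.input_size, params.hidden_size, seed=0)
    for arr in g.arrays():
        arr[...] = 0.0
    dpre = (2.0 / n) * err * yhat * (1.0 - yhat)        # (n,)
    g.Wy[...] = hs[-1].T @ dpre
    g.by[...] = dpre.sum()
    dh = np.outer(dpre, params.Wy)
    dc = np.zeros_like(dh)
    hidden = params.hidden_size
    for step in reversed(range(length)):
        concat, z, zi, zf, zo, c_prev, _c_t, tanh_c = caches[step]
        dc = dc + dh * zo * (1.0 - tanh_c**2)
        dzo = dh * tanh_c
        dzf = dc * c_prev
        dzi = dc * z
        dz = dc * zi
        da_z = dz * (1.0 - z**2)
        da_i = dzi * zi * (1.0 - zi)
        da_f = dzf * zf * (1.0 - zf)
        da_o = dzo * zo * (1.0 - zo)
        g.Wz += da_z.T @ concat
        g.Wi += da_i.T @ concat
        g.Wf += da_f.T @ concat
        g.Wo += da_o.T @ concat
        g.bz += da_z.sum(axis=0)
        g.bi += da_i.sum(axis=0)
        g.bf += da_f.sum(axis=0)
        g.bo += da_o.sum(axis=0)
        dconcat = (
            da_z @ params.Wz + da_i @ params.Wi
            + da_f @ params.Wf + da_o @ params.Wo
        )
        dh = dconcat[:, -hidden:]
        dc = dc * zf
    return loss, g


def train(X, y, hidden_size: int = DEFAULT_HIDDEN, lr: float = DEFAULT_LR,
          epochs: int = DEFAULT_EPOCHS, seed: int = 0):
    """Full-batch Adam training; returns (params, loss history).

    Raises :class:`TrainingError` carrying the last finite epoch if the
    loss diverges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 3 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be (n, L, D) with matching non-empty targets")
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    params = init_params(X.shape[2], hidden_size, seed=seed)
    m = params.copy()
    v = params.copy()
    for arr in (*m.arrays(), *v.arrays()):
        arr[...] = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history = []
    for epoch in range(1, epochs + 1):
        loss, g = loss_and_grads(params, X, y)
        if not np.isfinite(loss):
            raise TrainingError(
                f"training diverged at epoch {epoch}",
                last_finite_epoch=epoch - 1,
                history=history,
            )
        history.append(loss)
        b1c = 1.0 - beta1**epoch
        b2c = 1.0 - beta2**epoch
        for p_arr, g_arr, m_arr, v_arr in zip(
            params.arrays(), g.arrays(), m.arrays(), v.arrays()
        ):
            m_arr[...] = beta1 * m_arr + (1 - beta1) * g_arr
            v_arr[...] = beta2 * v_arr + (1 - beta2) * g_arr**2
            p_arr[...] = p_arr - lr * (m_arr / b1c) / (np.sqrt(v_arr / b2c) + eps)
    return params, np.asarray(history)


# ---------------------------------------------------------------------------
# Sequence construction


@dataclass(frozen=True)
class SequenceDataset:
    """Chronological windows of normalized features with aligned targets."""

    X: np.ndarray                    # (n, L, D)
    y: np.ndarray                    # (n,)
    target_indices: np.ndarray       # epoch index of each window's target
    feature_params: tuple            # MinMaxParams per feature column
    target_params: MinMaxParams

    def __len__(self):
        return len(self.y)


def make_sequences(
    table: pd.DataFrame,
    lookback: int = 2,
    n_train: int = 50,
    feature_cols=("st", "smc", "sec"),
    target_col: str = "ndvi_filtered",
):
    """Build chronological train/test window datasets from an epoch table.

    A window covers ``lookback`` consecutive epochs of the three soil
    features; its target is the NDVI at the window's final epoch. With
    72 epochs and lookback 2 there are 71 windows, split 50 train / 21
    test by default. Min–max normalization parameters for features and
    target are fitted on the training portion only and then applied to
    the test windows (no leakage).
    """
    n_rows = len(table)
    if lookback < 1:
        raise ValueError("lookback must be >= 1")
    n_windows = n_rows - lookback + 1
    if n_windows < 2:
        raise ValueError(f"lookback {lookback} leaves fewer than 2 windows")
    if not 1 <= n_train < n_windows:
        raise ValueError(f"n_train must be in [1, {n_windows - 1}], got {n_train}")
    feats = table[list(feature_cols)].to_numpy(float)
    targets = table[target_col].to_numpy(float)
    # rows touched by training windows: epochs 0 .. n_train + lookback - 2
    train_rows = slice(0, n_train + lookback - 1)
    feat_params, norm_cols = [], []
    for j in range(feats.shape[1]):
        _, prm = normalize(feats[train_rows, j])
        scaled, _ = normalize(feats[:, j], prm)
        feat_params.append(prm)
        norm_cols.append(scaled)
    feats_n = np.column_stack(norm_cols)
    target_idx = np.arange(lookback - 1, n_rows)
    _, tprm = normalize(targets[target_idx[:n_train]])
    targets_n, _ = normalize(targets, tprm)
    X = np.stack([feats_n[k:k + lookback] for k in range(n_windows)])
    y = targets_n[target_idx]
    mk = lambda sl: SequenceDataset(
        X=X[sl], y=y[sl], target_indices=target_idx[sl],
        feature_params=tuple(feat_params), target_params=tprm,
    )
    return mk(slice(0, n_train)), mk(slice(n_train, n_windows))


# ---------------------------------------------------------------------------
# Model / Results wrappers


class LstmModel:
    """NDVI sequence regressor in the Model/Results idiom.

    Holds the training windows; :meth:`fit` trains and returns an
    :class:`LstmResults`.
    """

    def __init__(self, train_data: SequenceDataset, hidden_size: int = DEFAULT_HIDDEN):
        self.train_data = train_data
        self.hidden_size = hidden_size

    def fit(self, lr: float = DEFAULT_LR, epochs: int = DEFAULT_EPOCHS,
            seed: int = 0) -> "LstmResults":
        params, history = train(
            self.train_data.X, self.train_data.y,
            hidden_size=self.hidden_size, lr=lr, epochs=epochs, seed=seed,
        )
        return LstmResults(self, params, history, lr=lr, epochs=epochs, seed=seed)


class LstmResults:
    def __init__(self, model: LstmModel, params: LSTMParams, loss_history,
                 lr: float, epochs: int, seed: int):
        self.model = model
        self.params = params
        self.loss_history = np.asarray(loss_history)
        self.lr = lr
        self.epochs = epochs
        self.seed = seed

    def predict(self, data: SequenceDataset | np.ndarray) -> np.ndarray:
        X = data.X if isinstance(data, SequenceDataset) else np.asarray(data, float)
        return forward(X, self.params)

    def score(self, data: SequenceDataset) -> MetricReport:
        """Five-metric report on the normalized NDVI scale."""
        return score(data.y, self.predict(data))

    def summary(self) -> str:
        return (
            f"LSTM regressor: H={self.params.hidden_size}, lr={self.lr:g}, "
            f"{self.epochs} epochs, seed={self.seed}\n"
            f"  final training MSE = {self.loss_history[-1]:.6g} "
            f"({len(self.model.train_data)} windows)"
        )
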