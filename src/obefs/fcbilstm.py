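"""Fuzzy-weighted convolutional bidirectional LSTM classifier (numpy backend).

Architecture: each input row (the masked feature vector, standardized with
training statistics and scaled by the fuzzy Gaussian relevance weights) is
presented as a length-D sequence of 1-dimensional tokens and fed to two
parallel branches:

- a 1-D convolutional branch (stacked tanh convolutions, global average
  pooling) producing a C-dimensional summary;
- a bidirectional LSTM branch whose final forward and backward hidden states
  are concatenated into a 2H-dimensional summary.

The branches are fused by multimodal factorized bilinear pooling: both
summaries are projected into a shared (factor_dim x output_dim) space,
multiplied elementwise, and sum-pooled over the factor dimension; a linear
readout yields the binary logit.  Training minimizes cross-entropy with Adam;
all gradients are computed analytically (verified against finite differences
in the test suite), and all randomness flows from the config seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .classifier import fuzzy_weights
from .datamodel import FeatureTable


@dataclasses.dataclass
class FcbilstmConfig:
    conv_filters: list[int] = dataclasses.field(default_factory=lambda: [16])
    kernel_size: int = 3
    lstm_units: int = 16
    mfb_factor_dim: int = 8
    mfb_output_dim: int = 4
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_filters:
            raise ValueError("conv_filters must name at least one layer")
        if min(self.conv_filters) < 1 or min(
            self.kernel_size, self.lstm_units, self.mfb_factor_dim, self.mfb_output_dim
        ) < 1:
            raise ValueError("all architecture sizes must be >= 1")


def _init_params(d: int, cfg: FcbilstmConfig, rng: np.random.Generator) -> dict:
    k, h = cfg.kernel_size, cfg.lstm_units
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for l, c_out in enumerate(cfg.conv_filters):
        scale = 1.0 / np.sqrt(k * c_in)
        params[f"Wc{l}"] = rng.normal(0, scale, size=(c_out, k, c_in))
        params[f"bc{l}"] = np.zeros(c_out)
        c_in = c_out
    for direction in ("f", "b"):
        params[f"Wx_{direction}"] = rng.normal(0, 0.5, size=4 * h)
        params[f"Wh_{direction}"] = rng.normal(0, 1.0 / np.sqrt(h), size=(4 * h, h))
        bias = np.zeros(4 * h)
        bias[h : 2 * h] = 1.0  # forget-gate bias
        params[f"b_{direction}"] = bias
    c_last = cfg.conv_filters[-1]
    mo = cfg.mfb_factor_dim * cfg.mfb_output_dim
    params["U"] = rng.normal(0, 1.0 / np.sqrt(c_last), size=(c_last, mo))
    params["V"] = rng.normal(0, 1.0 / np.sqrt(2 * h), size=(2 * h, mo))
    params["w_out"] = rng.normal(0, 1.0 / np.sqrt(cfg.mfb_output_dim), size=cfg.mfb_output_dim)
    params["b_out"] = np.zeros(1)
    return params


# ---------------------------------------------------------------------------
# branch forward/backward


def _conv_forward(seq: np.ndarray, params: dict, cfg: FcbilstmConfig):
    """seq: (B, D, 1) -> pooled (B, C_last); caches for backward."""
    x = seq
    caches = []
    for l in range(len(cfg.conv_filters)):
        W, b = params[f"Wc{l}"], params[f"bc{l}"]
        win = sliding_window_view(x, cfg.kernel_size, axis=1)  # (B, L, C_in, k)
        pre = np.einsum("bpiq,cqi->bpc", win, W) + b
        z = np.tanh(pre)
        caches.append((win, z, x.shape))
        x = z
    pooled = x.mean(axis=1)
    return pooled, (caches, x.shape[1])


def _conv_backward(dpooled: np.ndarray, params: dict, cfg: FcbilstmConfig, cache) -> dict:
    caches, l_last = cache
    grads: dict[str, np.ndarray] = {}
    dz = np.repeat(dpooled[:, None, :] / l_last, l_last, axis=1)
    for l in reversed(range(len(cfg.conv_filters))):
        win, z, in_shape = caches[l]
        W = params[f"Wc{l}"]
        dpre = dz * (1.0 - z * z)
        grads[f"Wc{l}"] = np.einsum("bpc,bpiq->cqi", dpre, win)
        grads[f"bc{l}"] = dpre.sum(axis=(0, 1))
        if l > 0:
            din = np.zeros(in_shape)
            l_out = dpre.shape[1]
            for q in range(cfg.kernel_size):
                din[:, q : q + l_out, :] += np.einsum("bpc,ci->bpi", dpre, W[:, q, :])
            dz = din
    return grads


def _lstm_forward(x_seq: np.ndarray, params: dict, direction: str, h: int):
    """x_seq: (B, D) scalar tokens; returns final hidden state (B, H) + cache."""
    Wx, Wh, b = params[f"Wx_{direction}"], params[f"Wh_{direction}"], params[f"b_{direction}"]
    B, D = x_seq.shape
    order = range(D) if direction == "f" else range(D - 1, -1, -1)
    h_t = np.zeros((B, h))
    c_t = np.zeros((B, h))
    steps = []
    for t in order:
        x_t = x_seq[:, t]
        pre = x_t[:, None] * Wx[None, :] + h_t @ Wh.T + b
        i = expit(pre[:, :h])
        f = expit(pre[:, h : 2 * h])
        g = np.tanh(pre[:, 2 * h : 3 * h])
        o = expit(pre[:, 3 * h :])
        c_new = f * c_t + i * g
        tanh_c = np.tanh(c_new)
        steps.append((x_t, h_t, c_t, i, f, g, o, tanh_c))
        h_t = o * tanh_c
        c_t = c_new
    return h_t, steps


def _lstm_backward(dh_final: np.ndarray, params: dict, direction: str, h: int, steps) -> dict:
    Wx, Wh = params[f"Wx_{direction}"], params[f"Wh_{direction}"]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h)
    dh_next = dh_final
    dc_next = np.zeros_like(dh_final)
    for x_t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(steps):
        dh = dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c * tanh_c)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dpre = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += (x_t[:, None] * dpre).sum(axis=0)
        dWh += dpre.T @ h_prev
        db += dpre.sum(axis=0)
        dh_next = dpre @ Wh
        dc_next = dc * f
    return {f"Wx_{direction}": dWx, f"Wh_{direction}": dWh, f"b_{direction}": db}


def _forward(x: np.ndarray, params: dict, cfg: FcbilstmConfig):
    """x: (B, D) fuzzy-weighted standardized rows -> logits (B,) + cache."""
    seq = x[:, :, None]
    a, conv_cache = _conv_forward(seq, params, cfg)
    hf, steps_f = _lstm_forward(x, params, "f", cfg.lstm_units)
    hb, steps_b = _lstm_forward(x, params, "b", cfg.lstm_units)
    bfeat = np.concatenate([hf, hb], axis=1)
    t1 = a @ params["U"]
    t2 = bfeat @ params["V"]
    prod = t1 * t2
    z = prod.reshape(len(x), cfg.mfb_output_dim, cfg.mfb_factor_dim).sum(axis=2)
    logit = z @ params["w_out"] + params["b_out"][0]
    cache = (a, conv_cache, steps_f, steps_b, bfeat, t1, t2, z)
    return logit, cache


def _backward(dlogit: np.ndarray, x: np.ndarray, params: dict, cfg: FcbilstmConfig, cache) -> dict:
    a, conv_cache, steps_f, steps_b, bfeat, t1, t2, z = cache
    h = cfg.lstm_units
    grads = {
        "w_out": z.T @ dlogit,
        "b_out": np.array([dlogit.sum()]),
    }
    dz = dlogit[:, None] * params["w_out"][None, :]
    dprod = np.repeat(dz, cfg.mfb_factor_dim, axis=1).reshape(
        len(x), cfg.mfb_output_dim, cfg.mfb_factor_dim
    ).reshape(len(x), -1)
    dt1 = dprod * t2
    dt2 = dprod * t1
    grads["U"] = a.T @ dt1
    grads["V"] = bfeat.T @ dt2
    da = dt1 @ params["U"].T
    dbfeat = dt2 @ params["V"].T
    grads.update(_conv_backward(da, params, cfg, conv_cache))
    grads.update(_lstm_backward(dbfeat[:, :h], params, "f", h, steps_f))
    grads.update(_lstm_backward(dbfeat[:, h:], params, "b", h, steps_b))
    return grads


def loss_and_grads(
    x: np.ndarray, y: np.ndarray, params: dict, cfg: FcbilstmConfig
) -> tuple[float, dict]:
    """Mean binary cross-entropy and analytic parameter gradients."""
    logit, cache = _forward(x, params, cfg)
    p = expit(logit)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogit = (p - y) / len(y)
    return loss, _backward(dlogit, x, params, cfg, cache)


# ---------------------------------------------------------------------------
# model + training


@dataclasses.dataclass
class FcbilstmModel:
    config: FcbilstmConfig
    columns: np.ndarray
    feature_weight: np.ndarray  # fuzzy relevance weights over masked columns
    mean: np.ndarray
    std: np.ndarray
    params: dict
    loss_history: list[float]

    def _prepare(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        xm = rows[:, self.columns]
        return (xm - self.mean) / self.std * self.feature_weight


def train_fcbilstm(
    table: FeatureTable, mask: np.ndarray, config: FcbilstmConfig | None = None
) -> FcbilstmModel:
    cfg = config or FcbilstmConfig()
    mask = np.asarray(mask, dtype=np.int8)
    cols = np.flatnonzero(mask)
    min_len = len(cfg.conv_filters) * (cfg.kernel_size - 1) + 1
    if len(cols) < min_len:
        raise ValueError(
            f"mask selects {len(cols)} features; the convolutional stack needs >= {min_len}"
        )
    sub = table.subset_columns(cols)
    fw = fuzzy_weights(sub).weight
    mean = sub.values.mean(axis=0)
    std = sub.values.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    X = (sub.values - mean) / std * fw
    y = table.label.astype(float)

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(len(cols), cfg, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses = []
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = loss_and_grads(X[idx], y[idx], params, cfg)
            epoch_loss += loss * len(idx)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
            for key, g in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                params[key] = params[key] - lr_t * m[key] / (np.sqrt(v[key]) + eps)
        losses.append(epoch_loss / n)
    return FcbilstmModel(
        config=cfg,
        columns=cols,
        feature_weight=fw,
        mean=mean,
        std=std,
        params=params,
        loss_history=losses,
    )


def predict_proba_fcbilstm(model: FcbilstmModel, rows: np.ndarray) -> np.ndarray:
    logit, _ = _forward(model._prepare(rows), model.params, model.config)
    return expit(logit)


def predict_fcbilstm(model: FcbilstmModel, rows: np.ndarray) -> np.ndarray:
    return (predict_proba_fcbilstm(model, rows) > 0.5).astype(int)
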