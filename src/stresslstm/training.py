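"""Training: loss, analytic backpropagation, Adam, dropout, fit loop.

The loss is binary cross-entropy with an L2 penalty on the weight
matrices (biases excluded):

    J = -(1/N) * sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]
        + lambda_r * sum(W^2)

Gradients are computed by hand-written backpropagation through the whole
architecture (head -> decoder cell -> attention -> combiner -> both
directional encoder cells) and are verified against central-difference
numerical differentiation in the test suite; that gradient check is the
single most important test of this module.

Optimization uses Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8, bias
correction) by default; plain SGD is available behind a config switch.
A ``momentum`` field exists in the configuration for completeness but is
inert under Adam.  Dropout (inverted scaling) is applied to the
encoder's combined per-step states during training only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as _m
from .model import ELSTMParams, FeatureScaler, init_params, is_bias
from .schema import BINARY_LEVELS, BINARY_VARS, FEATURES, LABEL, LABEL_LEVELS

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "FitResult",
    "bce_l2_loss",
    "gradients",
    "finite_difference_gradients",
    "init_moments",
    "adam_step",
    "sgd_step",
    "build_features",
    "fit",
    "predict_cohort",
]

_EPS_PROB = 1e-7  # probability clipping inside the loss


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the fit loop.

    ``preset(1)`` and ``preset(2)`` return the two published
    configurations (learning rate 0.0005/0.0003, batch 768/1024, dropout
    0.2/0.3, 150/100 epochs, momentum 0.1/0).  ``momentum`` is recorded
    but unused under Adam.  ``n_hidden`` (the hidden-layer width) is not
    part of the published settings; 16 is this package's default.
    """

    learning_rate: float = 0.0005
    beta1: float = 0.9  # Adam first-moment decay ("decay factor")
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 768
    epochs: int = 150
    dropout_rate: float = 0.2
    l2: float = 1e-5
    momentum: float = 0.1  # recorded; inert under Adam
    seed: int = 0
    threshold: float = 0.5
    optimizer: str = "adam"  # "adam" | "sgd"
    n_hidden: int = 16
    decoder_steps: int = 1
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0 or self.n_hidden < 1:
            raise ValueError("batch_size/n_hidden must be >= 1 and epochs >= 0")

    @classmethod
    def preset(cls, which: int) -> "TrainingConfig":
        if which == 1:
            return cls()
        if which == 2:
            return cls(
                learning_rate=0.0003,
                batch_size=1024,
                dropout_rate=0.3,
                epochs=100,
                momentum=0.0,
            )
        raise ValueError(f"unknown preset {which!r} (expected 1 or 2)")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss/accuracy and optional validation ones."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        }


@dataclass
class FitResult:
    params: ELSTMParams
    history: TrainingHistory
    scaler: FeatureScaler
    feature_names: tuple[str, ...]
    train_index: np.ndarray
    val_index: np.ndarray
    config: TrainingConfig


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_l2_loss(y: Sequence[float], y_hat: Sequence[float],
                params: ELSTMParams | None = None, l2: float = 0.0) -> float:
    """Mean binary cross-entropy plus L2 penalty on weight matrices.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logs; the
    penalty sums the squares of every weight array of ``params`` (biases
    excluded) scaled by ``l2``.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {p.shape}")
    p = np.clip(p, _EPS_PROB, 1.0 - _EPS_PROB)
    data = -float(np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    penalty = 0.0
    if params is not None and l2 > 0.0:
        penalty = l2 * sum(
            float(np.sum(a * a)) for name, a in params.named_arrays() if not is_bias(name)
        )
    return data + penalty


# ---------------------------------------------------------------------------
# backpropagation
# ---------------------------------------------------------------------------

def _zero_grads(params: ELSTMParams) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(np.asarray(a)) for name, a in params.named_arrays()}


def _cell_backward(p, cache, dc_in, dh_in, grads, prefix):
    """Backward pass of one (peephole) cell step.

    ``dc_in``/``dh_in`` are the incoming gradients on this step's outputs
    (c_t, h_t).  Returns gradients on (c_{t-1}, h_{t-1}, x_t) and
    accumulates weight gradients into ``grads``.
    """
    X, c_prev, h_prev, i, f, cbar, c, o, tc = cache
    n = p.n

    do = dh_in * tc
    da_o = do * o * (1.0 - o)
    dc = dc_in + dh_in * o * (1.0 - tc * tc)
    if p.peephole:
        dc = dc + da_o @ p.W_o[:, :n]

    di = dc * cbar
    df = dc * c_prev
    dcbar = dc * i
    da_i = di * i * (1.0 - i)
    da_f = df * f * (1.0 - f)
    da_cb = dcbar * (1.0 - cbar * cbar)

    if p.peephole:
        Zg = np.concatenate([c_prev, h_prev, X], axis=1)
        Zo = np.concatenate([c, h_prev, X], axis=1)
        h_off = n
    else:
        Zg = np.concatenate([h_prev, X], axis=1)
        Zo = Zg
        h_off = 0
    Zc = np.concatenate([h_prev, X], axis=1)

    grads[prefix + "W_i"] += da_i.T @ Zg
    grads[prefix + "W_f"] += da_f.T @ Zg
    grads[prefix + "W_o"] += da_o.T @ Zo
    grads[prefix + "W_c"] += da_cb.T @ Zc
    grads[prefix + "b_i"] += da_i.sum(axis=0)
    grads[prefix + "b_f"] += da_f.sum(axis=0)
    grads[prefix + "b_o"] += da_o.sum(axis=0)
    grads[prefix + "b_c"] += da_cb.sum(axis=0)

    dc_prev = dc * f
    if p.peephole:
        dc_prev = dc_prev + da_i @ p.W_i[:, :n] + da_f @ p.W_f[:, :n]
    dh_prev = (
        da_i @ p.W_i[:, h_off:h_off + n]
        + da_f @ p.W_f[:, h_off:h_off + n]
        + da_o @ p.W_o[:, h_off:h_off + n]
        + da_cb @ p.W_c[:, :n]
    )
    dx = (
        da_i @ p.W_i[:, h_off + n:]
        + da_f @ p.W_f[:, h_off + n:]
        + da_o @ p.W_o[:, h_off + n:]
        + da_cb @ p.W_c[:, n:]
    )
    return dc_prev, dh_prev, dx


def _loss_and_grads(params: ELSTMParams, X: np.ndarray, y: np.ndarray,
                    l2: float, steps: int,
                    dropout_mask: np.ndarray | None):
    """Forward + full analytic backward pass over one batch."""
    B, T, m = X.shape
    n = params.n
    prob, cache = _m._forward_batch(params, X, steps=steps, dropout_mask=dropout_mask)
    _, enc_cache, _, Hd, dec_caches, h_final, logit, _, _ = cache
    fwd_caches, bwd_caches, HC, H = enc_cache
    loss = bce_l2_loss(y, prob, params, l2)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss (min/max prob {prob.min():.3g}/{prob.max():.3g})"
        )

    grads = _zero_grads(params)

    # head: d loss / d logit = (p - y) / B  (sigmoid + BCE)
    dlogit = (prob - y) / B
    grads["head.w"] += dlogit @ h_final
    grads["head.b"] += np.array(dlogit.sum())
    dh = dlogit[:, None] * params.head_w[None, :]
    dc = np.zeros((B, n))

    # decoder steps in reverse; attention feeds gradient into Hd and into
    # the memory vector used for scoring (the step's c_prev).
    dHd = np.zeros_like(Hd)
    dec = params.decoder
    for s in range(len(dec_caches) - 1, -1, -1):
        e, w, ctx, cell_cache = dec_caches[s]
        dc_prev, dh_prev, dctx = _cell_backward(dec, cell_cache, dc, dh, grads, "decoder.")
        # attention backward: ctx = sum_t w_t Hd_t, w = softmax(e),
        # e_t = c_prev . Hd_t
        dw = np.einsum("bn,btn->bt", dctx, Hd)
        dHd += w[:, :, None] * dctx[:, None, :]
        de = w * (dw - np.sum(w * dw, axis=1, keepdims=True))
        dc_prev = dc_prev + np.einsum("bt,btn->bn", de, Hd)
        dHd += de[:, :, None] * cell_cache[1][:, None, :]  # c_prev of this step
        dc, dh = dc_prev, dh_prev
    # dc, dh at the zero initial decoder state are discarded.

    # dropout and combiner
    dH = dHd if dropout_mask is None else dHd * dropout_mask
    dA = dH * (1.0 - H * H)  # (B, T, n)
    V = params.encoder.V
    grads["encoder.V"] += np.einsum("btn,btk->nk", dA, HC)
    grads["encoder.k"] += dA.sum(axis=(0, 1))
    dHC = np.einsum("btn,nk->btk", dA, V)
    dHF = dHC[:, :, :n]
    dHB = dHC[:, :, n:]

    # forward-direction cell BPTT (t = T-1 .. 0)
    dc_f = np.zeros((B, n))
    dh_f = np.zeros((B, n))
    for t in range(T - 1, -1, -1):
        dc_f, dh_f, _ = _cell_backward(
            params.encoder.forward, fwd_caches[t], dc_f, dh_f + dHF[:, t, :],
            grads, "encoder.forward.",
        )
    # backward-direction cell processed positions T-1..0; BPTT visits its
    # processing order in reverse, i.e. positions 0..T-1.
    dc_b = np.zeros((B, n))
    dh_b = np.zeros((B, n))
    for idx in range(len(bwd_caches) - 1, -1, -1):
        t = T - 1 - idx  # position consumed at processing step idx
        dc_b, dh_b, _ = _cell_backward(
            params.encoder.backward, bwd_caches[idx], dc_b, dh_b + dHB[:, t, :],
            grads, "encoder.backward.",
        )

    if l2 > 0.0:
        for name, a in params.named_arrays():
            if not is_bias(name):
                grads[name] += 2.0 * l2 * np.asarray(a)
    return loss, grads, prob


def gradients(batch: tuple[np.ndarray, np.ndarray], params: ELSTMParams,
              config: TrainingConfig,
              dropout_mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Analytic gradients of the regularized loss for one batch.

    ``batch`` is ``(X, y)`` with X of shape (B, T, m) and y in {0, 1}.
    One gradient array per trainable array, matching
    ``params.named_arrays()``; agrees with central differences to
    relative 1e-5 (verified in the test suite).
    """
    X, y = batch
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("batch must be non-empty with X of shape (B, T, m)")
    _, grads, _ = _loss_and_grads(
        params, X, y, config.l2, config.decoder_steps, dropout_mask
    )
    return grads


def finite_difference_gradients(batch, params: ELSTMParams, config: TrainingConfig,
                                step: float = 1e-6,
                                dropout_mask: np.ndarray | None = None,
                                ) -> dict[str, np.ndarray]:
    """Central-difference gradients of the same loss (diagnostic oracle)."""
    X, y = batch
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def loss_at(p: ELSTMParams) -> float:
        prob, _ = _m._forward_batch(p, X, steps=config.decoder_steps,
                                    dropout_mask=dropout_mask)
        return bce_l2_loss(y, prob, p, config.l2)

    out = {}
    base = {name: np.array(a, dtype=float) for name, a in params.named_arrays()}
    for name, a in base.items():
        g = np.zeros_like(a)
        flat = a.reshape(-1)
        gflat = g.reshape(-1)
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + step
            hi = loss_at(params.replace_arrays({name: a}))
            flat[j] = orig - step
            lo = loss_at(params.replace_arrays({name: a}))
            flat[j] = orig
            gflat[j] = (hi - lo) / (2.0 * step)
        out[name] = g
    return out


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def init_moments(params: ELSTMParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        name: (np.zeros_like(np.asarray(a)), np.zeros_like(np.asarray(a)))
        for name, a in params.named_arrays()
    }


def adam_step(params: ELSTMParams, grads: dict[str, np.ndarray],
              moments: dict[str, tuple[np.ndarray, np.ndarray]],
              config: TrainingConfig, t: int):
    """One bias-corrected Adam update; returns (new params, new moments)."""
    if t < 1:
        raise ValueError("Adam step index t must be >= 1")
    b1, b2, eps, lr = config.beta1, config.beta2, config.eps, config.learning_rate
    new_arrays = {}
    new_moments = {}
    for name, a in params.named_arrays():
        g = grads[name]
        m_prev, v_prev = moments[name]
        m = b1 * m_prev + (1.0 - b1) * g
        v = b2 * v_prev + (1.0 - b2) * g * g
        m_hat = m / (1.0 - b1 ** t)
        v_hat = v / (1.0 - b2 ** t)
        new_arrays[name] = np.asarray(a) - lr * m_hat / (np.sqrt(v_hat) + eps)
        new_moments[name] = (m, v)
    return params.replace_arrays(new_arrays), new_moments


def sgd_step(params: ELSTMParams, grads: dict[str, np.ndarray],
             config: TrainingConfig) -> ELSTMParams:
    """Plain gradient-descent update."""
    new_arrays = {
        name: np.asarray(a) - config.learning_rate * grads[name]
        for name, a in params.named_arrays()
    }
    return params.replace_arrays(new_arrays)


# ---------------------------------------------------------------------------
# feature extraction and the fit loop
# ---------------------------------------------------------------------------

def build_features(cohort: pd.DataFrame,
                   feature_names: Sequence[str] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Cohort table -> (X raw feature matrix, y labels in {0,1}, names).

    Binary variables are coded {0, 1} by their level order (man/no = 0);
    the label is 1 for the high-stress group.  Feature order always
    follows the canonical schema order regardless of the order given.
    """
    if feature_names is None:
        feature_names = FEATURES
    unknown = [f for f in feature_names if f not in FEATURES]
    if unknown:
        raise ValueError(f"unknown feature(s): {unknown}")
    names = tuple(f for f in FEATURES if f in set(feature_names))
    cols = []
    for f in names:
        if f in BINARY_VARS:
            second = BINARY_LEVELS[f][1]
            cols.append((cohort[f] == second).to_numpy(dtype=float))
        else:
            cols.append(cohort[f].to_numpy(dtype=float))
    X = np.column_stack(cols)
    y = (cohort[LABEL] == LABEL_LEVELS[1]).to_numpy(dtype=float)
    return X, y, names


def _stratified_split(y: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _epoch_metrics(params, X, y, l2, steps, threshold):
    prob, _ = _m._forward_batch(params, X, steps=steps)
    loss = bce_l2_loss(y, prob, params, l2)
    acc = float(np.mean((prob >= threshold) == (y == 1.0)))
    return loss, acc


def fit(cohort: pd.DataFrame, config: TrainingConfig | None = None,
        seed: int | None = None,
        feature_names: Sequence[str] | None = None) -> FitResult:
    """Train the classifier on a cohort table.

    The cohort is split into stratified train/validation parts (default
    80/20, seeded); the scaler is fitted on the training part only; each
    epoch runs shuffled mini-batches with fresh dropout masks on the
    encoder states.  Everything is reproducible from the single seed.
    """
    config = config or TrainingConfig()
    seed = config.seed if seed is None else seed
    X_raw, y, names = build_features(cohort, feature_names)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both stress classes")

    children = np.random.SeedSequence(seed).spawn(4)
    split_rng = np.random.default_rng(children[0])
    init_seed = int(children[1].generate_state(1)[0] % (2**31))
    shuffle_rng = np.random.default_rng(children[2])
    dropout_rng = np.random.default_rng(children[3])
    train_idx, val_idx = _stratified_split(y, config.val_fraction, split_rng)
    scaler = FeatureScaler.fit(X_raw[train_idx], names)
    X = scaler.transform(X_raw)[:, :, None]  # (N, T, 1)
    T = X.shape[1]

    params = init_params(T=T, n=config.n_hidden, m=1, seed=init_seed)
    moments = init_moments(params)
    history = TrainingHistory()
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    t = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(train_idx.size)
        for start in range(0, order.size, config.batch_size):
            sel = order[start:start + config.batch_size]
            Xb, yb = Xtr[sel], ytr[sel]
            mask = None
            if config.dropout_rate > 0.0:
                keep = 1.0 - config.dropout_rate
                mask = (
                    dropout_rng.random((Xb.shape[0], T, config.n_hidden)) < keep
                ) / keep
            _, grads, _ = _loss_and_grads(
                params, Xb, yb, config.l2, config.decoder_steps, mask
            )
            if config.optimizer == "adam":
                t += 1
                params, moments = adam_step(params, grads, moments, config, t)
            else:
                params = sgd_step(params, grads, config)
        loss, acc = _epoch_metrics(
            params, Xtr, ytr, config.l2, config.decoder_steps, config.threshold
        )
        history.train_loss.append(loss)
        history.train_accuracy.append(acc)
        if val_idx.size:
            vloss, vacc = _epoch_metrics(
                params, Xval, yval, config.l2, config.decoder_steps, config.threshold
            )
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)

    return FitResult(
        params=params,
        history=history,
        scaler=scaler,
        feature_names=names,
        train_index=train_idx,
        val_index=val_idx,
        config=config,
    )


def predict_cohort(params: ELSTMParams, scaler: FeatureScaler,
                   cohort: pd.DataFrame, steps: int = 1) -> np.ndarray:
    """High-stress probabilities for every record of a cohort table."""
    X_raw, _, names = build_features(cohort, scaler.feature_names)
    if names != scaler.feature_names:
        raise ValueError("cohort is missing features the model was trained on")
    X = scaler.transform(X_raw)[:, :, None]
    prob, _ = _m._forward_batch(params, X, steps=steps)
    return prob
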