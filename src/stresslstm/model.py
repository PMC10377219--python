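"""Feature-attention peephole LSTM classifier.

The architecture, end to end:

1.  Each subject's screened variables are standardized and read as a
    length-T sequence of scalars (one feature per time step, width m=1),
    so the attention distribution computed later is a distribution over
    *features*.
2.  A bidirectional **peephole LSTM encoder** consumes the sequence in
    both directions.  In a peephole cell the input and forget gates also
    see the previous memory cell, and the output gate sees the *current*
    memory cell:

        i_t = sigmoid(W_i [c_{t-1}; h_{t-1}; x_t] + b_i)
        f_t = sigmoid(W_f [c_{t-1}; h_{t-1}; x_t] + b_f)
        cbar_t = tanh(W_c [h_{t-1}; x_t] + b_c)
        c_t = f_t * c_{t-1} + i_t * cbar_t
        o_t = sigmoid(W_o [c_t; h_{t-1}; x_t] + b_o)
        h_t = o_t * tanh(c_t)

    With the peephole flag off the memory-cell columns disappear and the
    cell is the standard LSTM.  Per step the two directional hidden
    vectors are combined through a learned projection,
    h_k = tanh(V [h_fwd_k ; h_bwd_k] + k).
3.  A **dot-product attention layer** scores each combined state against
    the decoder's memory vector, e_k = c^T h_k, normalizes the scores
    with a numerically stable softmax, and forms the context vector
    ctx = sum_k w_k h_k.
4.  A single-step (configurable) **peephole decoder cell** consumes the
    context as its input; its hidden state is mapped through a dense
    weight vector and a sigmoid to the probability of the high-stress
    class.

All arrays are float64 numpy; every public function is pure (no input is
mutated) and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "CellState",
    "CellParams",
    "EncoderParams",
    "ELSTMParams",
    "AttentionResult",
    "ParameterCount",
    "FeatureScaler",
    "init_params",
    "cell_step",
    "encode",
    "attend",
    "decode",
    "forward",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # Numerically stable logistic function.
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class CellState:
    """Memory cell ``c`` and hidden vector ``h`` of one LSTM cell."""

    c: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class CellParams:
    """Weights of one (peephole) LSTM cell.

    With ``peephole=True`` the gate matrices ``W_i/W_f/W_o`` act on the
    concatenation ``[c, h, x]`` and have shape (n, 2n+m); with
    ``peephole=False`` they act on ``[h, x]`` and have shape (n, n+m).
    The candidate matrix ``W_c`` always acts on ``[h, x]``.
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray
    peephole: bool = True

    @property
    def n(self) -> int:
        return self.b_i.shape[0]

    @property
    def m(self) -> int:
        return self.W_c.shape[1] - self.n

    def __post_init__(self) -> None:
        n = self.b_i.shape[0]
        m = self.W_c.shape[1] - n
        gate_cols = 2 * n + m if self.peephole else n + m
        for name in ("W_i", "W_f", "W_o"):
            w = getattr(self, name)
            if w.shape != (n, gate_cols):
                raise ValueError(
                    f"{name} must have shape {(n, gate_cols)}, got {w.shape}"
                )
        if self.W_c.shape != (n, n + m) or m < 1:
            raise ValueError(f"W_c must have shape (n, n+m) with m >= 1, got {self.W_c.shape}")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            b = getattr(self, name)
            if b.shape != (n,):
                raise ValueError(f"{name} must have shape {(n,)}, got {b.shape}")
        for name, w in self.named_arrays():
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite values")

    def named_arrays(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in ("W_i", "W_f", "W_o", "W_c", "b_i", "b_f", "b_o", "b_c"):
            yield prefix + name, getattr(self, name)


@dataclass(frozen=True)
class EncoderParams:
    """Forward/backward cells plus the per-step combiner (V, k, tanh)."""

    forward: CellParams
    backward: CellParams
    V: np.ndarray
    k: np.ndarray

    @property
    def n(self) -> int:
        return self.forward.n

    @property
    def m(self) -> int:
        return self.forward.m

    def __post_init__(self) -> None:
        if (self.forward.n, self.forward.m) != (self.backward.n, self.backward.m):
            raise ValueError("forward and backward cells must share (n, m)")
        n = self.forward.n
        if self.V.shape != (n, 2 * n):
            raise ValueError(f"V must have shape {(n, 2 * n)}, got {self.V.shape}")
        if self.k.shape != (n,):
            raise ValueError(f"k must have shape {(n,)}, got {self.k.shape}")

    def named_arrays(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        yield from self.forward.named_arrays(prefix + "forward.")
        yield from self.backward.named_arrays(prefix + "backward.")
        yield prefix + "V", self.V
        yield prefix + "k", self.k


@dataclass(frozen=True)
class AttentionResult:
    """Scores, softmax weights and context vector of one attention pass."""

    scores: np.ndarray  # (T,)
    weights: np.ndarray  # (T,), nonnegative, sums to 1
    context: np.ndarray  # (n,)


@dataclass(frozen=True)
class ELSTMParams:
    """All trainable weights of the full classifier."""

    encoder: EncoderParams
    decoder: CellParams
    head_w: np.ndarray  # (n,)
    head_b: np.ndarray  # scalar, shape ()
    T: int

    @property
    def n(self) -> int:
        return self.encoder.n

    @property
    def m(self) -> int:
        return self.encoder.m

    def __post_init__(self) -> None:
        n = self.encoder.n
        if not self.decoder.peephole:
            raise ValueError("decoder cell must use peephole connections")
        if (self.decoder.n, self.decoder.m) != (n, n):
            raise ValueError("decoder must have hidden size n and input width n")
        if self.head_w.shape != (n,):
            raise ValueError(f"head_w must have shape {(n,)}, got {self.head_w.shape}")
        if np.ndim(self.head_b) != 0:
            raise ValueError("head_b must be a scalar array")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def named_arrays(self) -> Iterator[tuple[str, np.ndarray]]:
        yield from self.encoder.named_arrays("encoder.")
        yield from self.decoder.named_arrays("decoder.")
        yield "head.w", self.head_w
        yield "head.b", np.asarray(self.head_b)

    def replace_arrays(self, arrays: dict[str, np.ndarray]) -> "ELSTMParams":
        """New parameter set with the given named arrays substituted."""

        def cell(prefix: str, old: CellParams) -> CellParams:
            kw = {
                name: arrays.get(prefix + name, getattr(old, name))
                for name in ("W_i", "W_f", "W_o", "W_c", "b_i", "b_f", "b_o", "b_c")
            }
            return replace(old, **kw)

        enc = EncoderParams(
            forward=cell("encoder.forward.", self.encoder.forward),
            backward=cell("encoder.backward.", self.encoder.backward),
            V=arrays.get("encoder.V", self.encoder.V),
            k=arrays.get("encoder.k", self.encoder.k),
        )
        return ELSTMParams(
            encoder=enc,
            decoder=cell("decoder.", self.decoder),
            head_w=arrays.get("head.w", self.head_w),
            head_b=np.asarray(arrays.get("head.b", self.head_b)).reshape(()),
            T=self.T,
        )


def is_bias(name: str) -> bool:
    """True for arrays excluded from the L2 penalty (biases, k, head bias)."""
    leaf = name.rsplit(".", 1)[-1]
    return leaf.startswith("b") or leaf == "k"


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_cell(rng: np.random.Generator, n: int, m: int, peephole: bool) -> CellParams:
    gate_cols = 2 * n + m if peephole else n + m
    return CellParams(
        W_i=_glorot(rng, (n, gate_cols)),
        W_f=_glorot(rng, (n, gate_cols)),
        W_o=_glorot(rng, (n, gate_cols)),
        W_c=_glorot(rng, (n, n + m)),
        b_i=np.zeros(n),
        b_f=np.ones(n),  # standard forget-bias offset, helps gradient flow
        b_o=np.zeros(n),
        b_c=np.zeros(n),
        peephole=peephole,
    )


def init_params(T: int, n: int, m: int = 1, seed: int = 0) -> ELSTMParams:
    """Seeded Glorot-style initialization of all trainable weights.

    Weight matrices are uniform in ±sqrt(6 / (fan_in + fan_out)); all
    biases are zero except the forget-gate bias, which starts at one.
    """
    if T < 1 or n < 1 or m < 1:
        raise ValueError(f"T, n, m must all be >= 1, got T={T}, n={n}, m={m}")
    rng = np.random.default_rng(seed)
    enc = EncoderParams(
        forward=_init_cell(rng, n, m, peephole=True),
        backward=_init_cell(rng, n, m, peephole=True),
        V=_glorot(rng, (n, 2 * n)),
        k=np.zeros(n),
    )
    dec = _init_cell(rng, n, n, peephole=True)
    head_w = rng.uniform(-np.sqrt(6.0 / (n + 1)), np.sqrt(6.0 / (n + 1)), size=n)
    return ELSTMParams(encoder=enc, decoder=dec, head_w=head_w, head_b=np.zeros(()), T=T)


# ---------------------------------------------------------------------------
# batched primitives (B = batch size); caches feed backpropagation
# ---------------------------------------------------------------------------

def _cell_forward(p: CellParams, X: np.ndarray, c_prev: np.ndarray, h_prev: np.ndarray):
    if p.peephole:
        Zg = np.concatenate([c_prev, h_prev, X], axis=1)
    else:
        Zg = np.concatenate([h_prev, X], axis=1)
    i = _sigmoid(Zg @ p.W_i.T + p.b_i)
    f = _sigmoid(Zg @ p.W_f.T + p.b_f)
    Zc = np.concatenate([h_prev, X], axis=1)
    cbar = np.tanh(Zc @ p.W_c.T + p.b_c)
    c = f * c_prev + i * cbar
    Zo = np.concatenate([c, h_prev, X], axis=1) if p.peephole else Zc
    o = _sigmoid(Zo @ p.W_o.T + p.b_o)
    tc = np.tanh(c)
    h = o * tc
    cache = (X, c_prev, h_prev, i, f, cbar, c, o, tc)
    return c, h, cache


def _attend_batch(c_dec: np.ndarray, H: np.ndarray):
    # c_dec: (B, n), H: (B, T, n) -> scores (B, T), weights, context (B, n)
    e = np.einsum("bn,btn->bt", c_dec, H)
    shifted = e - e.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    w /= w.sum(axis=1, keepdims=True)
    ctx = np.einsum("bt,btn->bn", w, H)
    return e, w, ctx


def _encode_batch(enc: EncoderParams, X: np.ndarray):
    """Run both directions and the combiner over a batch.

    X has shape (B, T, m).  Returns combined states H (B, T, n), the
    combined final candidate (B, n) and a cache for backpropagation.
    """
    B, T, _ = X.shape
    n = enc.n
    cf = np.zeros((B, n))
    hf = np.zeros((B, n))
    cb = np.zeros((B, n))
    hb = np.zeros((B, n))
    fwd_caches, bwd_caches = [], []
    HF = np.empty((B, T, n))
    HB = np.empty((B, T, n))
    for t in range(T):
        cf, hf, cache = _cell_forward(enc.forward, X[:, t, :], cf, hf)
        fwd_caches.append(cache)
        HF[:, t, :] = hf
    for t in range(T - 1, -1, -1):
        cb, hb, cache = _cell_forward(enc.backward, X[:, t, :], cb, hb)
        bwd_caches.append(cache)  # stored in processing order T-1..0
        HB[:, t, :] = hb
    HC = np.concatenate([HF, HB], axis=2)  # (B, T, 2n)
    A = HC @ enc.V.T + enc.k
    H = np.tanh(A)
    # Combined final candidate: each direction's last candidate state
    # projected through the same (V, k, tanh) combiner.
    cbar_last = np.concatenate([fwd_caches[-1][5], bwd_caches[-1][5]], axis=1)
    cbar_combined = np.tanh(cbar_last @ enc.V.T + enc.k)
    cache = (fwd_caches, bwd_caches, HC, H)
    return H, cbar_combined, cache


def _decode_batch(dec: CellParams, H: np.ndarray, steps: int):
    B, _, n = H.shape
    c = np.zeros((B, n))
    h = np.zeros((B, n))
    step_caches = []
    for _ in range(steps):
        e, w, ctx = _attend_batch(c, H)
        c_prev = c
        c, h, cell_cache = _cell_forward(dec, ctx, c_prev, h)
        step_caches.append((e, w, ctx, cell_cache))
    return c, h, step_caches


def _forward_batch(params: ELSTMParams, X: np.ndarray, steps: int = 1,
                   dropout_mask: np.ndarray | None = None):
    """Full forward pass over a batch; returns probabilities and caches.

    ``dropout_mask`` (B, T, n), already inverted-scaled, multiplies the
    encoder's combined states during training.
    """
    H, cbar_combined, enc_cache = _encode_batch(params.encoder, X)
    Hd = H if dropout_mask is None else H * dropout_mask
    _, h, dec_caches = _decode_batch(params.decoder, Hd, steps)
    logit = h @ params.head_w + params.head_b
    prob = _sigmoid(logit)
    cache = (X, enc_cache, dropout_mask, Hd, dec_caches, h, logit, prob, cbar_combined)
    return prob, cache


# ---------------------------------------------------------------------------
# public single-sample operations
# ---------------------------------------------------------------------------

def cell_step(x: Sequence[float], prev: CellState, p: CellParams) -> CellState:
    """One LSTM step on a single input vector.

    All gate activations lie strictly in (0, 1) and every component of
    the returned hidden vector lies in (-1, 1).
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if x.shape[1] != p.m:
        raise ValueError(f"input has width {x.shape[1]}, cell expects m={p.m}")
    c_prev = np.asarray(prev.c, dtype=float).reshape(1, -1)
    h_prev = np.asarray(prev.h, dtype=float).reshape(1, -1)
    if c_prev.shape[1] != p.n or h_prev.shape[1] != p.n:
        raise ValueError(
            f"state has sizes ({c_prev.shape[1]}, {h_prev.shape[1]}), cell expects n={p.n}"
        )
    c, h, _ = _cell_forward(p, x, c_prev, h_prev)
    return CellState(c=c[0], h=h[0])


def encode(seq: Sequence[float], enc: EncoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Encode one feature sequence.

    Returns the T combined per-step states (T, n) and the combined final
    candidate vector (n,).  Both directions start from zero states.
    """
    X = _as_sequence_array(seq, enc.m)
    H, cbar, _ = _encode_batch(enc, X[None, :, :])
    return H[0], cbar[0]


def attend(c_prev: Sequence[float], H: np.ndarray) -> AttentionResult:
    """Dot-product attention of a decoder memory vector over encoder states.

    Scores are ``e_k = c_prev . h_k``; weights are their softmax (with
    max subtraction for overflow safety); the context is the weighted sum
    of the encoder states.
    """
    c = np.asarray(c_prev, dtype=float)
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or c.ndim != 1 or H.shape[1] != c.shape[0]:
        raise ValueError(
            f"incompatible shapes: c_prev {c.shape}, H {H.shape} (need (T, n) and (n,))"
        )
    e, w, ctx = _attend_batch(c[None, :], H[None, :, :])
    return AttentionResult(scores=e[0], weights=w[0], context=ctx[0])


def decode(H: np.ndarray, dec: CellParams, steps: int = 1) -> np.ndarray:
    """Run the attention-fed decoder cell and return its final hidden vector.

    The decoder starts from a zero state; at every step the attention
    context computed from its *current* memory vector is the cell input.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] != dec.n:
        raise ValueError(f"H must have shape (T, n={dec.n}), got {H.shape}")
    _, h, _ = _decode_batch(dec, H[None, :, :], steps)
    return h[0]


def forward(seq: Sequence[float], params: ELSTMParams, steps: int = 1) -> float:
    """Probability of the high-stress class for one feature sequence.

    encode -> decode -> dense head -> sigmoid.  Strictly inside (0, 1);
    deterministic given the parameters (dropout is a training-time-only
    concept and never applies here).
    """
    X = _as_sequence_array(seq, params.m)
    if X.shape[0] != params.T:
        raise ValueError(f"sequence has length {X.shape[0]}, model expects T={params.T}")
    prob, _ = _forward_batch(params, X[None, :, :], steps=steps)
    return float(prob[0])


def _as_sequence_array(seq: Sequence[float], m: int) -> np.ndarray:
    X = np.asarray(seq, dtype=float)
    if X.ndim == 1:
        if m != 1:
            raise ValueError(f"flat sequence given but per-step width is m={m}")
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != m:
        raise ValueError(f"sequence must have shape (T, m={m}), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("sequence contains non-finite values")
    return X


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterCount:
    """Exact trainable-scalar count plus the conventional nominal figure."""

    exact: int
    nominal: int

    def __int__(self) -> int:
        return self.exact


def count_parameters(params: ELSTMParams) -> ParameterCount:
    """Count trainable scalars.

    ``exact`` sums the sizes of every trainable array.  ``nominal`` is
    the conventional complexity figure 7*(n^2 + n*m + n) often quoted for
    this architecture; it does not follow from the shape rules and is
    reported for reference only.
    """
    exact = sum(int(a.size) for _, a in params.named_arrays())
    n, m = params.n, params.m
    nominal = 7 * (n * n + n * m + n)
    return ParameterCount(exact=exact, nominal=nominal)


# ---------------------------------------------------------------------------
# feature scaling and checkpointing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature z-scoring, fitted on training data only.

    Binary variables are mapped to {0, 1} upstream and then z-scored
    exactly like the continuous ones.
    """

    mean: np.ndarray  # (T,)
    sd: np.ndarray  # (T,)
    feature_names: tuple[str, ...]

    @classmethod
    def fit(cls, X: np.ndarray, feature_names: Sequence[str]) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd <= 0):
            bad = [feature_names[j] for j in np.flatnonzero(sd <= 0)]
            raise ValueError(f"constant feature(s) in training data: {bad}")
        return cls(mean=mean, sd=sd, feature_names=tuple(feature_names))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def save_checkpoint(path: str | Path, params: ELSTMParams, scaler: FeatureScaler,
                    meta: dict | None = None) -> None:
    """Write a flat array archive (.npz) plus a JSON sidecar (.json).

    The sidecar records the model shape, feature order and scaler
    statistics; loading reconstructs bitwise-identical forward behaviour.
    """
    path = Path(path)
    arrays = {name: np.asarray(a) for name, a in params.named_arrays()}
    np.savez(path, **arrays)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "n": params.n,
        "T": params.T,
        "m": params.m,
        "feature_names": list(scaler.feature_names),
        "scaler_mean": scaler.mean.tolist(),
        "scaler_sd": scaler.sd.tolist(),
        "meta": meta or {},
    }
    npz_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[ELSTMParams, FeatureScaler, dict]:
    """Inverse of :func:`save_checkpoint`."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    with np.load(npz_path) as data:
        arrays = {name: data[name] for name in data.files}
    template = init_params(T=sidecar["T"], n=sidecar["n"], m=sidecar["m"], seed=0)
    params = template.replace_arrays(arrays)
    scaler = FeatureScaler(
        mean=np.asarray(sidecar["scaler_mean"], dtype=float),
        sd=np.asarray(sidecar["scaler_sd"], dtype=float),
        feature_names=tuple(sidecar["feature_names"]),
    )
    return params, scaler, sidecar.get("meta", {})
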