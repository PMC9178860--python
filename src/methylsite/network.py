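"""The dilated-convolution + BiLSTM (DCB) site classifier.

Two layers of implementation live here on purpose:

* **Reference functions** (`dilated_conv1d_ref`, `lstm_step_ref`,
  `bilstm_ref`) — literal, per-element transcriptions of the defining
  equations, written for clarity and used as independent oracles in the
  test suite. The dilated convolution reference places its taps at offsets
  r, 2r, ..., Nr from the output position (the printed one-sided form);
  `dilated_conv1d_standard` gives the common framework convention with taps
  at 0, r, ..., (N-1)r, which is the reference form shifted left by r.

* **The trainable network** (`DCBNetwork`) — a vectorized, batched numpy
  implementation with hand-written backpropagation, trained by Adam on
  binary cross-entropy. Architecture: three parallel blocks of
  [dilated conv (ReLU, valid padding, dilation 1/2/3) -> max-pool ->
  dropout], right-cropped to a common length and concatenated along
  channels, a bidirectional LSTM, dropout, flatten, a ReLU dense stack
  with dropout, and a single sigmoid output giving the modification
  probability.

The two layers are deliberately independent code paths; the suite checks
them against each other and checks every analytic gradient against central
finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Literal

import numpy as np

EncoderKind = Literal["onehot", "embedding", "rglove"]


# ---------------------------------------------------------------------------
# small math helpers
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# reference implementations (test oracles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DilatedConvSpec:
    """One dilated filter: taps ``weights`` (length N), scalar ``bias``,
    dilation rate ``r`` >= 1, and elementwise activation ``f``."""

    weights: np.ndarray
    bias: float = 0.0
    rate: int = 1
    activation: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.rate < 1:
            raise ValueError("dilation rate must be >= 1")
        if len(self.weights) < 1:
            raise ValueError("filter length must be >= 1")


def dilated_conv1d_ref(x: np.ndarray, spec: DilatedConvSpec) -> np.ndarray:
    """Literal one-sided dilated convolution.

    y_j = f( sum_{n=1..N} x_{j + r*n} * w_n + b ) for j = 1..L - rN
    (1-based); output length L - rN. Requires L >= rN + 1.
    """
    x = np.asarray(x, dtype=float)
    N, r = len(spec.weights), spec.rate
    L = len(x)
    if L < r * N + 1:
        raise ValueError(f"input length {L} < r*N + 1 = {r * N + 1}")
    out = np.empty(L - r * N)
    for j in range(L - r * N):  # 0-based output position
        acc = spec.bias
        for n in range(1, N + 1):
            acc += x[j + r * n] * spec.weights[n - 1]
        out[j] = acc
    return spec.activation(out) if spec.activation else out


def dilated_conv1d_standard(x: np.ndarray, spec: DilatedConvSpec) -> np.ndarray:
    """Framework-convention dilated convolution: taps at offsets
    0, r, ..., (N-1)r; output length L - r(N-1). Equals the one-sided
    reference shifted left by r on a common support."""
    x = np.asarray(x, dtype=float)
    N, r = len(spec.weights), spec.rate
    L = len(x)
    if L < r * (N - 1) + 1:
        raise ValueError(f"input length {L} < r*(N-1) + 1 = {r * (N - 1) + 1}")
    out = np.empty(L - r * (N - 1))
    for j in range(len(out)):
        acc = spec.bias
        for n in range(N):
            acc += x[j + r * n] * spec.weights[n]
        out[j] = acc
    return spec.activation(out) if spec.activation else out


@dataclass
class LSTMCellParams:
    """Per-gate LSTM parameters with the classical naming: input weights W,
    recurrent weights U and biases b for the forget (f), input (i),
    candidate (c) and output (o) gates. Hidden size H."""

    Wf: np.ndarray
    Wi: np.ndarray
    Wc: np.ndarray
    Wo: np.ndarray
    Uf: np.ndarray
    Ui: np.ndarray
    Uc: np.ndarray
    Uo: np.ndarray
    bf: np.ndarray
    bi: np.ndarray
    bc: np.ndarray
    bo: np.ndarray

    @property
    def H(self) -> int:
        return self.Wf.shape[0]

    @property
    def input_dim(self) -> int:
        return self.Wf.shape[1]

    def __post_init__(self) -> None:
        H, d = self.Wf.shape
        for name in ("Wf", "Wi", "Wc", "Wo"):
            if getattr(self, name).shape != (H, d):
                raise ValueError(f"{name} shape mismatch")
        for name in ("Uf", "Ui", "Uc", "Uo"):
            if getattr(self, name).shape != (H, H):
                raise ValueError(f"{name} shape mismatch")
        for name in ("bf", "bi", "bc", "bo"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} shape mismatch")

    @classmethod
    def zeros(cls, input_dim: int, H: int) -> "LSTMCellParams":
        z = np.zeros
        return cls(
            Wf=z((H, input_dim)), Wi=z((H, input_dim)),
            Wc=z((H, input_dim)), Wo=z((H, input_dim)),
            Uf=z((H, H)), Ui=z((H, H)), Uc=z((H, H)), Uo=z((H, H)),
            bf=z(H), bi=z(H), bc=z(H), bo=z(H),
        )

    def to_packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pack as (Wx (d, 4H), Wh (H, 4H), b (4H,)) in gate order
        (i, f, c, o) — the layout the vectorized layer uses."""
        Wx = np.concatenate([self.Wi.T, self.Wf.T, self.Wc.T, self.Wo.T], axis=1)
        Wh = np.concatenate([self.Ui.T, self.Uf.T, self.Uc.T, self.Uo.T], axis=1)
        b = np.concatenate([self.bi, self.bf, self.bc, self.bo])
        return Wx, Wh, b

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray,
                    b: np.ndarray) -> "LSTMCellParams":
        H = Wh.shape[0]
        Wi, Wf, Wc, Wo = (Wx[:, k * H:(k + 1) * H].T for k in range(4))
        Ui, Uf, Uc, Uo = (Wh[:, k * H:(k + 1) * H].T for k in range(4))
        bi, bf, bc, bo = (b[k * H:(k + 1) * H] for k in range(4))
        return cls(Wf=Wf, Wi=Wi, Wc=Wc, Wo=Wo, Uf=Uf, Ui=Ui, Uc=Uc, Uo=Uo,
                   bf=bf, bi=bi, bc=bc, bo=bo)


def lstm_step_ref(
    x_t: np.ndarray, h_prev: np.ndarray, C_prev: np.ndarray,
    params: LSTMCellParams,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """One LSTM transition, literally:

    f_t = sigma(W^f x_t + U^f h_{t-1} + b^f)
    i_t = sigma(W^i x_t + U^i h_{t-1} + b^i)
    C~_t = tanh(W^c x_t + U^c h_{t-1} + b^c)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigma(W^o x_t + U^o h_{t-1} + b^o)
    h_t = o_t * tanh(C_t)

    Returns (h_t, C_t, gates dict with f, i, o, C_tilde).
    """
    p = params
    if x_t.shape != (p.input_dim,) or h_prev.shape != (p.H,) \
            or C_prev.shape != (p.H,):
        raise ValueError("input/state shape mismatch")
    f_t = sigmoid(p.Wf @ x_t + p.Uf @ h_prev + p.bf)
    i_t = sigmoid(p.Wi @ x_t + p.Ui @ h_prev + p.bi)
    C_tilde = np.tanh(p.Wc @ x_t + p.Uc @ h_prev + p.bc)
    C_t = f_t * C_prev + i_t * C_tilde
    o_t = sigmoid(p.Wo @ x_t + p.Uo @ h_prev + p.bo)
    h_t = o_t * np.tanh(C_t)
    return h_t, C_t, {"f": f_t, "i": i_t, "o": o_t, "C_tilde": C_tilde}


def bilstm_ref(
    X: np.ndarray, fwd: LSTMCellParams, bwd: LSTMCellParams
) -> np.ndarray:
    """Bidirectional LSTM by iterating the reference step.

    Row t of the (L, 2H) output concatenates the forward hidden state after
    reading X[0..t] with the backward hidden state after reading X[L-1..t].
    """
    L = X.shape[0]
    if X.shape[1] != fwd.input_dim or fwd.input_dim != bwd.input_dim:
        raise ValueError("input dimension mismatch")
    h, C = np.zeros(fwd.H), np.zeros(fwd.H)
    fwd_h = np.empty((L, fwd.H))
    for t in range(L):
        h, C, _ = lstm_step_ref(X[t], h, C, fwd)
        fwd_h[t] = h
    h, C = np.zeros(bwd.H), np.zeros(bwd.H)
    bwd_h = np.empty((L, bwd.H))
    for t in range(L - 1, -1, -1):
        h, C, _ = lstm_step_ref(X[t], h, C, bwd)
        bwd_h[t] = h
    return np.concatenate([fwd_h, bwd_h], axis=1)


def dilated_conv_batch(
    X: np.ndarray, W: np.ndarray, b: np.ndarray, rate: int
) -> np.ndarray:
    """Batched multi-channel dilated convolution, framework convention.

    X (B, L, d), taps W (N, d, F), bias b (F,); output (B, L - r(N-1), F)
    summing channel contributions, no activation. This is the layer the
    trainable network uses; per output position and filter it equals
    summing `dilated_conv1d_standard` over input channels.
    """
    B, L, d = X.shape
    N, _, F = W.shape
    lc = L - rate * (N - 1)
    if lc < 1:
        raise ValueError(f"input length {L} < r*(N-1) + 1 = {rate * (N - 1) + 1}")
    z = np.broadcast_to(b, (B, lc, F)).copy()
    for n in range(N):
        z += X[:, n * rate : n * rate + lc, :] @ W[n]
    return z


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DCBConfig:
    """Architecture and training hyperparameters.

    The architecture defaults are the grid-searched operating point:
    64 kernels of size 3 per dilated block with dilation rates (1, 2, 3),
    max-pool windows of 2, conv dropout 0.2, a 64-unit BiLSTM with dropout
    0.2, dense layers of 256/128/64 ReLU units with dropout 0.5, and a
    sigmoid output. Training (binary cross-entropy, Adam with learning
    rate 1e-3, batch 32, 10 epochs, optional early stopping on validation
    loss) is this package's choice and fully overridable.
    """

    n_filters: int = 64
    kernel_size: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    pool_size: int = 2
    conv_dropout: float = 0.2
    bilstm_units: int = 64
    bilstm_dropout: float = 0.2
    dense_sizes: tuple[int, ...] = (256, 128, 64)
    dense_dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    val_fraction: float = 0.0
    patience: int = 3
    class_weight: bool = False

    def __post_init__(self) -> None:
        if min(self.n_filters, self.kernel_size, self.pool_size,
               self.bilstm_units, *self.dense_sizes, *self.dilation_rates) < 1:
            raise ValueError("all architecture sizes must be positive")
        for d in (self.conv_dropout, self.bilstm_dropout, self.dense_dropout):
            if not 0 <= d < 1:
                raise ValueError("dropout rates must be in [0, 1)")

    def min_input_length(self) -> int:
        """Smallest token-sequence length the architecture accepts."""
        rmax = max(self.dilation_rates)
        return rmax * (self.kernel_size - 1) + self.pool_size


# ---------------------------------------------------------------------------
# trainable network
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class DCBNetwork:
    """Vectorized DCB classifier with hand-written backpropagation.

    ``input_shape`` is (L, d): token-sequence length and per-token feature
    dimension. For the ``embedding`` encoder the network owns a trainable
    embedding table of shape (vocab_size + 1, embed_dim) (row 0 = pad,
    frozen at zero) and expects integer index inputs (B, L); for ``onehot``
    and ``rglove`` it expects already-encoded float inputs (B, L, d).
    """

    def __init__(
        self,
        cfg: DCBConfig,
        input_shape: tuple[int, int],
        encoder_kind: EncoderKind = "onehot",
        vocab_size: int | None = None,
    ) -> None:
        L, d = input_shape
        if L < cfg.min_input_length():
            raise ValueError(
                f"input length {L} too short for dilation rates "
                f"{cfg.dilation_rates}: minimum is {cfg.min_input_length()}"
            )
        if encoder_kind == "embedding" and vocab_size is None:
            raise ValueError("embedding encoder requires vocab_size")
        self.cfg = cfg
        self.L, self.d = L, d
        self.encoder_kind = encoder_kind
        self.vocab_size = vocab_size
        rng = np.random.default_rng(cfg.seed)
        N, F = cfg.kernel_size, cfg.n_filters
        self.params: dict[str, np.ndarray] = {}
        if encoder_kind == "embedding":
            self.params["embed"] = rng.uniform(-0.05, 0.05, (vocab_size + 1, d))
            self.params["embed"][0] = 0.0

        # conv block r: taps at offsets 0, r, ..., (N-1)r, valid padding
        self.conv_out_len: dict[int, int] = {}
        self.pool_out_len: dict[int, int] = {}
        for r in cfg.dilation_rates:
            lc = L - r * (N - 1)
            self.conv_out_len[r] = lc
            self.pool_out_len[r] = lc // cfg.pool_size
            self.params[f"convW{r}"] = _glorot(rng, (N, d, F), N * d, F)
            self.params[f"convb{r}"] = np.zeros(F)
        self.T = min(self.pool_out_len.values())  # common cropped length
        C = F * len(cfg.dilation_rates)  # concatenated channels
        H = cfg.bilstm_units
        for direction in ("fw", "bw"):
            self.params[f"{direction}_Wx"] = _glorot(rng, (C, 4 * H), C, H)
            self.params[f"{direction}_Wh"] = _glorot(rng, (H, 4 * H), H, H)
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias init
            self.params[f"{direction}_b"] = b
        flat = self.T * 2 * H
        prev = flat
        for li, size in enumerate(cfg.dense_sizes):
            self.params[f"denseW{li}"] = _glorot(rng, (prev, size), prev, size)
            self.params[f"denseb{li}"] = np.zeros(size)
            prev = size
        self.params["outW"] = _glorot(rng, (prev, 1), prev, 1)
        self.params["outb"] = np.zeros(1)

    # -- forward ----------------------------------------------------------

    def _embed(self, X: np.ndarray) -> np.ndarray:
        if self.encoder_kind == "embedding":
            if X.dtype.kind not in "iu" or X.ndim != 2:
                raise ValueError("embedding encoder expects integer (B, L) input")
            return self.params["embed"][X]
        if X.ndim != 3 or X.shape[1:] != (self.L, self.d):
            raise ValueError(
                f"expected float input of shape (B, {self.L}, {self.d}) "
                f"for encoder {self.encoder_kind!r}, got {X.shape}"
            )
        return np.asarray(X, dtype=float)

    def forward(
        self, X: np.ndarray, training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Compute probabilities (B,) and a cache for backprop."""
        cfg = self.cfg
        if training and rng is None:
            rng = np.random.default_rng(cfg.seed)
        cache: dict = {"X_raw": X, "training": training}
        E = self._embed(X)
        cache["E"] = E
        B = E.shape[0]
        N, F, P = cfg.kernel_size, cfg.n_filters, cfg.pool_size

        blocks = []
        for r in cfg.dilation_rates:
            W, b = self.params[f"convW{r}"], self.params[f"convb{r}"]
            lc = self.conv_out_len[r]
            z = dilated_conv_batch(E, W, b, r)
            a = relu(z)
            cache[f"relu_mask{r}"] = z > 0
            lp = self.pool_out_len[r]
            view = a[:, : lp * P, :].reshape(B, lp, P, F)
            arg = view.argmax(axis=2)
            pooled = np.take_along_axis(view, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache[f"pool_arg{r}"] = arg
            if training and cfg.conv_dropout > 0:
                mask = rng.random(pooled.shape) >= cfg.conv_dropout
                pooled = pooled * mask / (1.0 - cfg.conv_dropout)
                cache[f"conv_dropmask{r}"] = mask
            blocks.append(pooled[:, : self.T, :])
        concat = np.concatenate(blocks, axis=2)  # (B, T, 3F)
        cache["concat"] = concat

        Hseq_f, cache["lstm_fw"] = self._lstm_forward(concat, "fw")
        Hseq_b_rev, cache["lstm_bw"] = self._lstm_forward(concat[:, ::-1], "bw")
        Hseq_b = Hseq_b_rev[:, ::-1]
        bi = np.concatenate([Hseq_f, Hseq_b], axis=2)  # (B, T, 2H)
        if training and cfg.bilstm_dropout > 0:
            mask = rng.random(bi.shape) >= cfg.bilstm_dropout
            bi = bi * mask / (1.0 - cfg.bilstm_dropout)
            cache["bilstm_dropmask"] = mask
        flat = bi.reshape(B, -1)
        cache["flat"] = flat

        h = flat
        for li in range(len(cfg.dense_sizes)):
            z = h @ self.params[f"denseW{li}"] + self.params[f"denseb{li}"]
            cache[f"dense_mask{li}"] = z > 0
            h = relu(z)
            if training and cfg.dense_dropout > 0:
                mask = rng.random(h.shape) >= cfg.dense_dropout
                h = h * mask / (1.0 - cfg.dense_dropout)
                cache[f"dense_dropmask{li}"] = mask
            cache[f"dense_out{li}"] = h
        logit = (h @ self.params["outW"] + self.params["outb"])[:, 0]
        cache["logit"] = logit
        cache["dense_in"] = flat
        return sigmoid(logit), cache

    def _lstm_forward(self, X: np.ndarray, direction: str):
        """One LSTM direction over (B, T, C); gate order (i, f, c, o)."""
        Wx = self.params[f"{direction}_Wx"]
        Wh = self.params[f"{direction}_Wh"]
        b = self.params[f"{direction}_b"]
        B, T, _ = X.shape
        H = self.cfg.bilstm_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hseq = np.empty((B, T, H))
        gates, cells, hs = [], [], []
        Xp = X @ Wx  # (B, T, 4H), input projections for all steps
        for t in range(T):
            z = Xp[:, t] + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            Hseq[:, t] = h
            gates.append((i, f, g, o))
            cells.append((c_prev, c))
            hs.append(h)
        return Hseq, {"X": X, "gates": gates, "cells": cells, "hs": hs}

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, y: np.ndarray,
                 sample_weight: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        cfg = self.cfg
        B = len(y)
        p = sigmoid(cache["logit"])
        dlogit = (p - y) / B
        if sample_weight is not None:
            dlogit = dlogit * sample_weight
        grads: dict[str, np.ndarray] = {}

        h_last = cache[f"dense_out{len(cfg.dense_sizes) - 1}"] \
            if cfg.dense_sizes else cache["dense_in"]
        grads["outW"] = h_last.T @ dlogit[:, None]
        grads["outb"] = np.array([dlogit.sum()])
        dh = dlogit[:, None] @ self.params["outW"].T

        for li in range(len(cfg.dense_sizes) - 1, -1, -1):
            if cache["training"] and cfg.dense_dropout > 0:
                dh = dh * cache[f"dense_dropmask{li}"] / (1.0 - cfg.dense_dropout)
            dz = dh * cache[f"dense_mask{li}"]
            prev = cache[f"dense_out{li - 1}"] if li > 0 else cache["dense_in"]
            grads[f"denseW{li}"] = prev.T @ dz
            grads[f"denseb{li}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"denseW{li}"].T

        H = cfg.bilstm_units
        dbi = dh.reshape(B, self.T, 2 * H)
        if cache["training"] and cfg.bilstm_dropout > 0:
            dbi = dbi * cache["bilstm_dropmask"] / (1.0 - cfg.bilstm_dropout)
        dconcat = np.zeros_like(cache["concat"])
        dX_f, gW = self._lstm_backward(dbi[:, :, :H], cache["lstm_fw"], "fw")
        grads.update(gW)
        dconcat += dX_f
        dX_b, gW = self._lstm_backward(
            dbi[:, ::-1, H:], cache["lstm_bw"], "bw")
        grads.update(gW)
        dconcat += dX_b[:, ::-1]

        N, F, P = cfg.kernel_size, cfg.n_filters, cfg.pool_size
        E = cache["E"]
        dE = np.zeros_like(E)
        for bi_idx, r in enumerate(cfg.dilation_rates):
            dpool_cropped = dconcat[:, :, bi_idx * F:(bi_idx + 1) * F]
            lp = self.pool_out_len[r]
            dpool = np.zeros((B, lp, F))
            dpool[:, : self.T, :] = dpool_cropped
            if cache["training"] and cfg.conv_dropout > 0:
                dpool = dpool * cache[f"conv_dropmask{r}"] / (1.0 - cfg.conv_dropout)
            lc = self.conv_out_len[r]
            da = np.zeros((B, lp, P, F))
            np.put_along_axis(
                da, cache[f"pool_arg{r}"][:, :, None, :], dpool[:, :, None, :],
                axis=2)
            da_full = np.zeros((B, lc, F))
            da_full[:, : lp * P, :] = da.reshape(B, lp * P, F)
            dz = da_full * cache[f"relu_mask{r}"]
            W = self.params[f"convW{r}"]
            gW_c = np.zeros_like(W)
            for n in range(N):
                Eslice = E[:, n * r : n * r + lc, :]
                gW_c[n] = np.einsum("blc,blf->cf", Eslice, dz)
                dE[:, n * r : n * r + lc, :] += dz @ W[n].T
            grads[f"convW{r}"] = gW_c
            grads[f"convb{r}"] = dz.sum(axis=(0, 1))

        if self.encoder_kind == "embedding":
            gE = np.zeros_like(self.params["embed"])
            np.add.at(gE, cache["X_raw"], dE)
            gE[0] = 0.0  # pad row frozen
            grads["embed"] = gE
        return grads

    def _lstm_backward(self, dH: np.ndarray, cache: dict, direction: str):
        Wx = self.params[f"{direction}_Wx"]
        Wh = self.params[f"{direction}_Wh"]
        X = cache["X"]
        B, T, C = X.shape
        H = self.cfg.bilstm_units
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["gates"][t]
            c_prev, c = cache["cells"][t]
            tanh_c = np.tanh(c)
            dh = dH[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g**2), do * o * (1 - o)], axis=1)
            h_prev = cache["hs"][t - 1] if t > 0 else np.zeros((B, H))
            dWx += X[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dh_next = da @ Wh.T
            dX[:, t] = da @ Wx.T
        return dX, {f"{direction}_Wx": dWx, f"{direction}_Wh": dWh,
                    f"{direction}_b": db}

    # -- convenience ------------------------------------------------------

    def loss(self, probs: np.ndarray, y: np.ndarray,
             sample_weight: np.ndarray | None = None) -> float:
        eps = 1e-12
        ll = -(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        if sample_weight is not None:
            ll = ll * sample_weight
        return float(ll.mean())

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic (dropout-free) probabilities, batched."""
        out = []
        for start in range(0, len(X), batch_size):
            p, _ = self.forward(X[start:start + batch_size], training=False)
            out.append(p)
        return np.concatenate(out)

    def num_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


def build_dcb(
    cfg: DCBConfig, input_shape: tuple[int, int],
    encoder_kind: EncoderKind = "onehot", vocab_size: int | None = None,
) -> DCBNetwork:
    """Assemble an untrained DCB network for the given input shape."""
    return DCBNetwork(cfg, input_shape, encoder_kind, vocab_size)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainedPredictor:
    """A fitted DCB network plus its provenance."""

    net: DCBNetwork
    cfg: DCBConfig
    encoder_kind: EncoderKind
    history: dict[str, list[float]] = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(X)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npz`` (parameters) and ``<prefix>.json``
        (config sidecar)."""
        prefix = Path(prefix)
        np.savez(str(prefix) + ".npz", **self.net.params)
        sidecar = {
            "encoder_kind": self.encoder_kind,
            "input_shape": [self.net.L, self.net.d],
            "vocab_size": self.net.vocab_size,
            "config": asdict(self.cfg),
            "history": self.history,
        }
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedPredictor":
        prefix = str(prefix)
        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        c = sidecar["config"]
        for key in ("dilation_rates", "dense_sizes"):
            c[key] = tuple(c[key])
        cfg = DCBConfig(**c)
        net = DCBNetwork(cfg, tuple(sidecar["input_shape"]),
                         sidecar["encoder_kind"], sidecar["vocab_size"])
        data = np.load(prefix + ".npz")
        for k in net.params:
            net.params[k] = data[k]
        return cls(net=net, cfg=cfg, encoder_kind=sidecar["encoder_kind"],
                   history=sidecar["history"])


def train_predictor(
    net: DCBNetwork,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedPredictor:
    """Fit by mini-batch Adam on binary cross-entropy.

    Deterministic given ``net.cfg.seed``: shuffling and dropout masks come
    from one seeded generator. With a validation set, stops early when the
    validation loss has not improved for ``cfg.patience`` epochs and keeps
    the best-validation parameters.
    """
    cfg = net.cfg
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("need at least two aligned samples")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, lr=cfg.learning_rate)
    weights = None
    if cfg.class_weight:
        pos = y.mean()
        w_pos, w_neg = 0.5 / pos, 0.5 / (1.0 - pos)
        weights = np.where(y == 1, w_pos, w_neg)
    history: dict[str, list[float]] = {"loss": []}
    if X_val is not None:
        history["val_loss"] = []
    best_val = np.inf
    best_params = None
    stale = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(y), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, yb = X[idx], y[idx]
            wb = weights[idx] if weights is not None else None
            probs, cache = net.forward(Xb, training=True, rng=rng)
            epoch_loss += net.loss(probs, yb, wb) * len(idx)
            grads = net.backward(cache, yb, wb)
            opt.step(net.params, grads)
            if net.encoder_kind == "embedding":
                net.params["embed"][0] = 0.0
        history["loss"].append(epoch_loss / len(y))
        if X_val is not None:
            pv = net.predict_proba(X_val)
            vl = net.loss(pv, np.asarray(y_val, dtype=float))
            history["val_loss"].append(vl)
            if vl < best_val - 1e-6:
                best_val, stale = vl, 0
                best_params = {k: v.copy() for k, v in net.params.items()}
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_params is not None:
        net.params.update(best_params)
    return TrainedPredictor(net=net, cfg=cfg,
                            encoder_kind=net.encoder_kind, history=history)
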