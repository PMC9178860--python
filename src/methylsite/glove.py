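"""Gap-aware k-mer GloVe embeddings trained with RMSProp or Adagrad.

The model fits main vectors e, context vectors ẽ and biases b, b̃ so that
for every co-occurring k-mer pair (i, j)

    e_i · ẽ_j + b_i + b̃_j ≈ log Y_ij,

minimizing the weighted least-squares cost

    K = Σ_{Y_ij > 0} f(Y_ij) (e_i · ẽ_j + b_i + b̃_j − log Y_ij)²,

with the capped power weighting f(y) = (y / y_max)^β for y < y_max, else 1.
The classical fit uses Adagrad, whose per-coordinate step size shrinks
monotonically as squared gradients accumulate; the RMSProp variant replaces
the accumulated sum with a decaying average E[z²]_t = λE[z²]_{t−1} +
(1−λ)z_t², so the effective step can recover. Vectors trained with RMSProp
are the embeddings used by the "rglove" encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .encoders import KmerVocabulary, save_word_vectors


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """W×W counts Y[i, j] of token j within the context window of token i.

    Stored densely with a leading dummy row/column so that vocabulary
    indices 1..W address the matrix directly (row/col 0 unused).
    """

    W: int
    Y: np.ndarray  # (W+1, W+1), entry [0, :] and [:, 0] zero
    context_window: int

    def __post_init__(self) -> None:
        if self.Y.shape != (self.W + 1, self.W + 1):
            raise ValueError("Y must be (W+1, W+1)")
        if np.any(self.Y < 0):
            raise ValueError("co-occurrence counts must be nonnegative")

    def nonzero_cells(self) -> np.ndarray:
        """(n, 2) array of (i, j) with Y_ij > 0, row-major order."""
        ii, jj = np.nonzero(self.Y)
        return np.column_stack([ii, jj])

    def save(self, path: str | Path) -> None:
        """3-column TSV of nonzero cells: i, j, Y_ij."""
        with open(path, "w") as fh:
            fh.write(f"# W={self.W}\tcontext_window={self.context_window}\n")
            for i, j in self.nonzero_cells():
                y = self.Y[i, j]
                val = int(y) if float(y).is_integer() else float(y)
                fh.write(f"{i}\t{j}\t{val}\n")

    @classmethod
    def load(cls, path: str | Path) -> "CooccurrenceMatrix":
        lines = Path(path).read_text().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split("\t"))
        W = int(header["W"])
        Y = np.zeros((W + 1, W + 1))
        for line in lines[1:]:
            if not line.strip():
                continue
            i, j, y = line.split("\t")
            Y[int(i), int(j)] = float(y)
        return cls(W=W, Y=Y, context_window=int(header["context_window"]))


@dataclass
class RGloVeConfig:
    """Hyperparameters for co-occurrence weighting and embedding training.

    Defaults: D=300 dimensions, context window c=30 tokens, weighting cap
    y_max=100 with fractional power β=0.75, RMSProp with α=0.001, λ=0.9,
    δ=1e−8 (the Adagrad alternative uses α=0.05, the original GloVe
    default). ``init_scale`` defaults to 0.5/D.
    """

    D: int = 300
    context_window: int = 30
    y_max: float = 100.0
    beta: float = 0.75
    optimizer: Literal["rmsprop", "adagrad"] = "rmsprop"
    alpha: float | None = None
    lam: float = 0.9
    delta: float = 1e-8
    epochs: int = 50
    seed: int = 0
    init_scale: float | None = None
    early_stop_rel: float = 1e-4
    distance_weighting: bool = False  # 1/distance co-occurrence increments
    export_sum: bool = False  # export e + ẽ instead of e

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.y_max <= 0:
            raise ValueError("y_max must be positive")
        if not 0 <= self.lam < 1:
            raise ValueError("lambda must be in [0, 1)")
        if self.alpha is None:
            self.alpha = 0.001 if self.optimizer == "rmsprop" else 0.05
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.init_scale is None:
            self.init_scale = 0.5 / self.D


@dataclass
class EmbeddingModel:
    """Fitted GloVe parameters, rows addressable by vocabulary index 1..W.

    ``e``/``e_tilde`` are (W+1, D) with row 0 an all-zero unknown/pad slot;
    ``b``/``b_tilde`` are (W+1,) biases.
    """

    e: np.ndarray
    e_tilde: np.ndarray
    b: np.ndarray
    b_tilde: np.ndarray

    @property
    def W(self) -> int:
        return self.e.shape[0] - 1

    @property
    def D(self) -> int:
        return self.e.shape[1]

    def score(self, i: int, j: int) -> float:
        """The model's fit e_i·ẽ_j + b_i + b̃_j for a cell."""
        return float(self.e[i] @ self.e_tilde[j] + self.b[i] + self.b_tilde[j])

    def export_vectors(self, sum_context: bool = False) -> np.ndarray:
        """Token vectors for downstream encoding: e, or e + ẽ on request."""
        return self.e + self.e_tilde if sum_context else self.e.copy()

    def save(self, vocab: KmerVocabulary, path: str | Path,
             sum_context: bool = False) -> None:
        save_word_vectors(self.export_vectors(sum_context), vocab, path)


@dataclass
class OptimizerState:
    """Per-parameter squared-gradient accumulators.

    Adagrad accumulates the running *sum* of squared gradients (monotone
    nondecreasing); RMSProp keeps the decaying *average* E[z²].
    """

    kind: Literal["rmsprop", "adagrad"]
    acc: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def for_model(cls, kind: str, model: EmbeddingModel) -> "OptimizerState":
        return cls(
            kind=kind,  # type: ignore[arg-type]
            acc={
                "e": np.zeros_like(model.e),
                "e_tilde": np.zeros_like(model.e_tilde),
                "b": np.zeros_like(model.b),
                "b_tilde": np.zeros_like(model.b_tilde),
            },
        )


def build_cooccurrence(
    corpus: Sequence[Sequence[int]],
    W: int,
    c: int,
    distance_weighting: bool = False,
) -> CooccurrenceMatrix:
    """Count context co-occurrences within a token window of size ``c``.

    For every ordered pair of positions (p, q) in the same sequence with
    1 ≤ |p−q| ≤ c, Y[token_p, token_q] is incremented — by 1, or by
    1/|p−q| when ``distance_weighting`` is on. Contexts never cross
    sequence boundaries. Index 0 entries (unknown/pad) are skipped.
    """
    if c < 1:
        raise ValueError("context window must be >= 1")
    Y = np.zeros((W + 1, W + 1))
    for seq in corpus:
        arr = np.asarray(seq, dtype=np.int64)
        if arr.size and (arr.min() < 0 or arr.max() > W):
            raise ValueError(f"token index out of range [0, {W}]")
        n = arr.size
        for d in range(1, min(c, n - 1) + 1):
            w = 1.0 / d if distance_weighting else 1.0
            a, bb = arr[:-d], arr[d:]
            keep = (a > 0) & (bb > 0)
            np.add.at(Y, (a[keep], bb[keep]), w)
            np.add.at(Y, (bb[keep], a[keep]), w)
    return CooccurrenceMatrix(W=W, Y=Y, context_window=c)


def cooc_weight(y: float | np.ndarray, y_max: float, beta: float):
    """The capped power weighting f(y) = (y/y_max)^β for y < y_max, else 1."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("co-occurrence counts must be nonnegative")
    out = np.where(y < y_max, np.power(y / y_max, beta), 1.0)
    return float(out) if out.ndim == 0 else out


def glove_loss(model: EmbeddingModel, cooc: CooccurrenceMatrix,
               cfg: RGloVeConfig) -> float:
    """The weighted least-squares cost K over cells with Y_ij > 0."""
    if model.W != cooc.W:
        raise ValueError(f"model W={model.W} != cooccurrence W={cooc.W}")
    ii, jj = np.nonzero(cooc.Y)
    y = cooc.Y[ii, jj]
    diff = (
        np.einsum("nd,nd->n", model.e[ii], model.e_tilde[jj])
        + model.b[ii]
        + model.b_tilde[jj]
        - np.log(y)
    )
    return float(np.sum(cooc_weight(y, cfg.y_max, cfg.beta) * diff**2))


def adagrad_step(
    phi: np.ndarray, z: np.ndarray, acc: np.ndarray, alpha: float, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """One Adagrad update: acc += z²; φ ← φ − α·z/√(acc + δ)."""
    if phi.shape != z.shape or phi.shape != acc.shape:
        raise ValueError("parameter/gradient/accumulator shape mismatch")
    acc = acc + z**2
    return phi - alpha * z / np.sqrt(acc + delta), acc


def rmsprop_step(
    phi: np.ndarray, z: np.ndarray, acc: np.ndarray,
    alpha: float, lam: float, delta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One RMSProp update: E ← λE + (1−λ)z²; φ ← φ − α·z/√(E + δ)."""
    if phi.shape != z.shape or phi.shape != acc.shape:
        raise ValueError("parameter/gradient/accumulator shape mismatch")
    acc = lam * acc + (1.0 - lam) * z**2
    return phi - alpha * z / np.sqrt(acc + delta), acc


def cell_gradients(
    model: EmbeddingModel, i: int, j: int, y: float, cfg: RGloVeConfig
) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """Analytic partials of one cell's weighted squared residual.

    Returns (diff, de_i, dẽ_j, db_i, db̃_j) where the per-cell objective is
    f(y)·(e_i·ẽ_j + b_i + b̃_j − log y)².
    """
    diff = model.score(i, j) - np.log(y)
    g = 2.0 * cooc_weight(y, cfg.y_max, cfg.beta) * diff
    return diff, g * model.e_tilde[j], g * model.e[i], g, g


def train_embeddings(
    cooc: CooccurrenceMatrix, cfg: RGloVeConfig
) -> tuple[EmbeddingModel, list[float]]:
    """Fit the embedding model by per-cell stochastic steps.

    Parameters initialize uniformly in [−init_scale, +init_scale] from
    ``cfg.seed``. Each epoch visits every nonzero cell once in a seeded
    shuffled order, taking one optimizer step per cell on that cell's
    weighted squared residual. Returns the fitted model and the per-epoch
    full-loss trace (entry 0 is the pre-training loss). Stops early when
    the relative epoch improvement drops below ``early_stop_rel``.
    """
    cells = cooc.nonzero_cells()
    if len(cells) == 0:
        raise ValueError("co-occurrence matrix has no positive cells")
    rng = np.random.default_rng(cfg.seed)
    W, D = cooc.W, cfg.D
    model = EmbeddingModel(
        e=rng.uniform(-cfg.init_scale, cfg.init_scale, (W + 1, D)),
        e_tilde=rng.uniform(-cfg.init_scale, cfg.init_scale, (W + 1, D)),
        b=rng.uniform(-cfg.init_scale, cfg.init_scale, W + 1),
        b_tilde=rng.uniform(-cfg.init_scale, cfg.init_scale, W + 1),
    )
    # row 0 is the unknown/pad slot; keep it at zero
    for arr in (model.e, model.e_tilde):
        arr[0] = 0.0
    model.b[0] = model.b_tilde[0] = 0.0

    state = OptimizerState.for_model(cfg.optimizer, model)
    logy = {(i, j): np.log(cooc.Y[i, j]) for i, j in map(tuple, cells)}
    fw = {
        (i, j): cooc_weight(cooc.Y[i, j], cfg.y_max, cfg.beta)
        for i, j in map(tuple, cells)
    }
    trace = [glove_loss(model, cooc, cfg)]
    for _ in range(cfg.epochs):
        order = rng.permutation(len(cells))
        for idx in order:
            i, j = int(cells[idx, 0]), int(cells[idx, 1])
            diff = model.score(i, j) - logy[(i, j)]
            g = 2.0 * fw[(i, j)] * diff
            ge_i = g * model.e_tilde[j]
            ge_j = g * model.e[i]
            if cfg.optimizer == "adagrad":
                model.e[i], state.acc["e"][i] = adagrad_step(
                    model.e[i], ge_i, state.acc["e"][i], cfg.alpha, cfg.delta)
                model.e_tilde[j], state.acc["e_tilde"][j] = adagrad_step(
                    model.e_tilde[j], ge_j, state.acc["e_tilde"][j],
                    cfg.alpha, cfg.delta)
                bnew, anew = adagrad_step(
                    model.b[i : i + 1], np.array([g]),
                    state.acc["b"][i : i + 1], cfg.alpha, cfg.delta)
                model.b[i], state.acc["b"][i] = bnew[0], anew[0]
                bnew, anew = adagrad_step(
                    model.b_tilde[j : j + 1], np.array([g]),
                    state.acc["b_tilde"][j : j + 1], cfg.alpha, cfg.delta)
                model.b_tilde[j], state.acc["b_tilde"][j] = bnew[0], anew[0]
            else:
                model.e[i], state.acc["e"][i] = rmsprop_step(
                    model.e[i], ge_i, state.acc["e"][i],
                    cfg.alpha, cfg.lam, cfg.delta)
                model.e_tilde[j], state.acc["e_tilde"][j] = rmsprop_step(
                    model.e_tilde[j], ge_j, state.acc["e_tilde"][j],
                    cfg.alpha, cfg.lam, cfg.delta)
                bnew, anew = rmsprop_step(
                    model.b[i : i + 1], np.array([g]),
                    state.acc["b"][i : i + 1], cfg.alpha, cfg.lam, cfg.delta)
                model.b[i], state.acc["b"][i] = bnew[0], anew[0]
                bnew, anew = rmsprop_step(
                    model.b_tilde[j : j + 1], np.array([g]),
                    state.acc["b_tilde"][j : j + 1],
                    cfg.alpha, cfg.lam, cfg.delta)
                model.b_tilde[j], state.acc["b_tilde"][j] = bnew[0], anew[0]
        trace.append(glove_loss(model, cooc, cfg))
        if len(trace) >= 2 and trace[-2] > 0:
            if abs(trace[-2] - trace[-1]) / trace[-2] < cfg.early_stop_rel:
                break
    return model, trace


def save_loss_trace(trace: list[float], path: str | Path) -> None:
    """Loss trace as CSV (epoch, K); epoch 0 is the pre-training loss."""
    with open(path, "w") as fh:
        fh.write("epoch,K\n")
        for epoch, k in enumerate(trace):
            fh.write(f"{epoch},{k!r}\n")
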