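"""k-mer tokenization, vocabularies, and the three window encodings.

A window of length L0 is tokenized into overlapping k-mers with stride s,
yielding L = floor((L0 - k)/s) + 1 tokens. Three tensor encodings are
produced from a window:

* one-hot — (L0, 5) with column order (A, C, G, T, -);
* index — length-L integer vector of vocabulary indices (0 = unknown/pad);
* embedding — (L, D) matrix gathering each token's trained vector.

The canonical vocabulary admits every k-mer over {A,C,G,T}, every k-mer
whose gaps form a single contiguous run anchored at exactly one end (the
shapes window padding can produce), and the all-gap k-mer; for k=3 this
gives 105 entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .seqio import ALPHABET, GAP

#: fixed one-hot column order, (A, C, G, T, -)
ONEHOT_ORDER = ALPHABET
_ONEHOT_COL = {ch: i for i, ch in enumerate(ONEHOT_ORDER)}

#: index reserved for unknown tokens / padding in index encodings
UNKNOWN_INDEX = 0


class UnknownTokenError(KeyError):
    """Raised by strict embedding encoding on an out-of-vocabulary token."""


@dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between k-mers and contiguous integer indices 1..W.

    Index 0 is reserved for unknown/pad so downstream embedding layers can
    mask it.
    """

    k: int
    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        idx = sorted(self.token_to_index.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("indices must be contiguous 1..W")
        if any(len(t) != self.k for t in self.token_to_index):
            raise ValueError(f"all tokens must have length k={self.k}")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        """Index of ``token``, or :data:`UNKNOWN_INDEX` if absent."""
        return self.token_to_index.get(token, UNKNOWN_INDEX)

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}

    def save(self, path: str | Path) -> None:
        """Write as two-column TSV ``kmer<TAB>index``, index order."""
        with open(path, "w") as fh:
            for tok, i in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        mapping: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            tok, idx = line.split("\t")
            mapping[tok] = int(idx)
        if not mapping:
            raise ValueError(f"{path}: empty vocabulary file")
        k = len(next(iter(mapping)))
        return cls(k=k, token_to_index=mapping)


def tokenize_kmers(window: str, k: int = 3, s: int = 1) -> list[str]:
    """Split ``window`` into overlapping k-mers with stride ``s``.

    Returns exactly ``floor((L0 - k)/s) + 1`` tokens; token ``i`` (1-based)
    starts at offset ``1 + (i-1)s``.
    """
    if k < 1 or s < 1:
        raise ValueError("k and s must be >= 1")
    if len(window) < k:
        raise ValueError(f"window length {len(window)} < k = {k}")
    return [window[p : p + k] for p in range(0, len(window) - k + 1, s)]


def num_tokens(length: int, k: int = 3, s: int = 1) -> int:
    """The token count L = floor((L0 - k)/s) + 1."""
    if length < k:
        raise ValueError("length < k")
    return (length - k) // s + 1


def _admissible(kmer: str) -> bool:
    """Gap-run rule: gaps, if any, form one run anchored at exactly one end,
    or the k-mer is all gaps."""
    if GAP not in kmer:
        return True
    stripped_l = kmer.lstrip(GAP)
    stripped_r = kmer.rstrip(GAP)
    if not stripped_l:  # all gaps
        return True
    # gaps only as a prefix run, or only as a suffix run (not both, not interior)
    if stripped_l != kmer and stripped_r != kmer:
        return False
    core = stripped_l if stripped_l != kmer else stripped_r
    return GAP not in core


def canonical_vocabulary(k: int = 3) -> KmerVocabulary:
    """The normative gap-aware vocabulary, lexicographic index assignment.

    Size is ``4^k + 2 * sum_{i=1}^{k-1} 4^i + 1`` — 105 for k=3.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = sorted(
        "".join(tup)
        for tup in product(ALPHABET, repeat=k)
        if _admissible("".join(tup))
    )
    return KmerVocabulary(k=k, token_to_index={t: i + 1 for i, t in enumerate(tokens)})


def build_vocabulary(corpus: list[list[str]]) -> KmerVocabulary:
    """Vocabulary of distinct observed tokens, first-occurrence order."""
    if not corpus:
        raise ValueError("empty corpus")
    mapping: dict[str, int] = {}
    for tokens in corpus:
        for tok in tokens:
            if tok not in mapping:
                mapping[tok] = len(mapping) + 1
    if not mapping:
        raise ValueError("corpus contains no tokens")
    k = len(next(iter(mapping)))
    return KmerVocabulary(k=k, token_to_index=mapping)


def encode_onehot(window: str) -> np.ndarray:
    """One-hot encode a window: (L0, 5), columns in (A,C,G,T,-) order."""
    try:
        cols = [_ONEHOT_COL[ch] for ch in window]
    except KeyError as exc:
        raise ValueError(f"disallowed character {exc.args[0]!r}") from exc
    out = np.zeros((len(window), len(ONEHOT_ORDER)))
    out[np.arange(len(window)), cols] = 1.0
    return out


def decode_onehot(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_onehot` (argmax per row)."""
    return "".join(ONEHOT_ORDER[j] for j in np.argmax(matrix, axis=1))


def encode_indices(
    tokens: list[str], vocab: KmerVocabulary
) -> tuple[np.ndarray, int]:
    """Map tokens to vocabulary indices.

    Unknown tokens map to :data:`UNKNOWN_INDEX` (0) and are tallied; returns
    ``(index_vector, n_unknown)``.
    """
    idx = np.array([vocab.index(t) for t in tokens], dtype=np.int64)
    return idx, int(np.sum(idx == UNKNOWN_INDEX))


def encode_embedding(
    tokens: list[str], vectors: np.ndarray, vocab: KmerVocabulary
) -> np.ndarray:
    """Gather each token's embedding row: (L, D).

    ``vectors`` has shape (W+1, D) with row 0 the unknown/pad slot and row i
    the vector of vocabulary index i. Strict: unknown tokens raise
    :class:`UnknownTokenError` naming the token.
    """
    if vectors.shape[0] != vocab.size + 1:
        raise ValueError(
            f"vectors rows {vectors.shape[0]} != vocab size + 1 = {vocab.size + 1}"
        )
    rows = []
    for tok in tokens:
        i = vocab.index(tok)
        if i == UNKNOWN_INDEX:
            raise UnknownTokenError(tok)
        rows.append(i)
    return vectors[np.array(rows, dtype=np.int64)]


def encode_windows(
    windows: list[str],
    kind: str,
    vocab: KmerVocabulary | None = None,
    vectors: np.ndarray | None = None,
    k: int = 3,
    s: int = 1,
) -> np.ndarray:
    """Stack a corpus of equal-length windows into one model-input tensor.

    ``onehot`` -> (B, L0, 5) floats; ``index`` (the trainable-embedding
    network input) -> (B, L) int64; ``rglove`` -> (B, L, D) floats gathered
    from pretrained ``vectors``.
    """
    if kind == "onehot":
        return np.stack([encode_onehot(w) for w in windows])
    token_lists = [tokenize_kmers(w, k, s) for w in windows]
    if kind == "index":
        if vocab is None:
            raise ValueError("index encoding requires a vocabulary")
        return np.stack([encode_indices(t, vocab)[0] for t in token_lists])
    if kind == "rglove":
        if vocab is None or vectors is None:
            raise ValueError("rglove encoding requires a vocabulary and vectors")
        return np.stack(
            [encode_embedding(t, vectors, vocab) for t in token_lists]
        )
    raise ValueError(f"unknown encoding kind {kind!r}")


def save_word_vectors(
    vectors: np.ndarray, vocab: KmerVocabulary, path: str | Path
) -> None:
    """Standard word-vector text format: ``W D`` header then
    ``token v1 ... vD`` per line."""
    W = vocab.size
    D = vectors.shape[1]
    inv = vocab.index_to_token
    with open(path, "w") as fh:
        fh.write(f"{W} {D}\n")
        for i in range(1, W + 1):
            vals = " ".join(repr(float(v)) for v in vectors[i])
            fh.write(f"{inv[i]} {vals}\n")


def load_word_vectors(path: str | Path) -> tuple[np.ndarray, KmerVocabulary]:
    """Read the word-vector text format back into ``(vectors, vocab)``.

    Returned ``vectors`` has shape (W+1, D) with row 0 zeros (unknown/pad).
    """
    lines = Path(path).read_text().splitlines()
    W, D = (int(x) for x in lines[0].split())
    vectors = np.zeros((W + 1, D))
    mapping: dict[str, int] = {}
    for i, line in enumerate(lines[1 : W + 1], start=1):
        parts = line.split(" ")
        mapping[parts[0]] = i
        vectors[i] = [float(v) for v in parts[1 : D + 1]]
    k = len(next(iter(mapping)))
    return vectors, KmerVocabulary(k=k, token_to_index=mapping)
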