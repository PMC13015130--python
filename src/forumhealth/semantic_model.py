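"""Skip-gram word embeddings with negative sampling, and cosine queries.

The trainer implements the classic skip-gram objective: given a center word,
predict the words inside a sliding window around it, so that words occurring
in similar local contexts receive similar vectors. Training uses negative
sampling (a handful of noise words drawn from the unigram distribution raised
to the 3/4 power per positive pair) and the standard dynamically shrunk
window: for each center position an effective radius is drawn uniformly from
1..window, which weights nearby context words more heavily.

The inner loop is compiled with numba and runs single-threaded with a seeded
RNG, so training is bit-reproducible for a fixed seed — a deliberate contract
(multithreaded embedding trainers are not reproducible).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .corpus_io import TokenizedPost
from .errors import VocabularyError

__all__ = [
    "EmbeddingParams",
    "EmbeddingModel",
    "train_skipgram",
    "cosine",
    "neighbors",
    "save_word2vec",
    "load_word2vec",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Skip-gram hyperparameters.

    ``window`` is the one-sided context radius in tokens (default 10).
    ``dimension``, ``epochs``, ``negative_samples`` and ``min_count`` default
    to conventional word2vec settings (100 / 5 / 5 / 5); all are configurable.
    ``initial_lr`` decays linearly to ``min_lr`` over training.
    """

    window: int = 10
    dimension: int = 100
    epochs: int = 5
    negative_samples: int = 5
    min_count: int = 5
    seed: int = 0
    initial_lr: float = 0.025
    min_lr: float = 1e-4

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if min(self.epochs, self.negative_samples, self.min_count) < 1:
            raise ValueError("epochs, negative_samples and min_count must be positive")


class EmbeddingModel:
    """A vocabulary with one dense vector per term.

    Vectors are stored as trained; L2-normalized copies are computed once,
    lazily, for cosine queries.
    """

    def __init__(
        self,
        vocabulary: Sequence[str],
        vectors: np.ndarray,
        params: EmbeddingParams | None = None,
    ):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(vocabulary):
            raise ValueError("vectors must be (len(vocabulary), dimension)")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("vectors contain NaN or Inf")
        self.vocabulary: tuple[str, ...] = tuple(vocabulary)
        self.vectors = vectors
        self.params = params
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        self._unit: np.ndarray | None = None

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self._idx(term)]

    def _idx(self, term: str) -> int:
        try:
            return self._index[term]
        except KeyError:
            raise VocabularyError(f"term {term!r} not in vocabulary")

    @property
    def unit_vectors(self) -> np.ndarray:
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            self._unit = self.vectors / norms
        return self._unit


def cosine(model: EmbeddingModel, term_a: str, term_b: str) -> float:
    """Cosine similarity between two vocabulary terms, in [-1, 1]."""
    u = model.unit_vectors
    value = float(u[model._idx(term_a)] @ u[model._idx(term_b)])
    return max(-1.0, min(1.0, value))


def neighbors(
    model: EmbeddingModel, term: str, threshold: float
) -> list[tuple[str, float]]:
    """All terms with cosine similarity strictly above ``threshold``,
    sorted by descending similarity (ties broken lexicographically).
    The query term itself is excluded."""
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [-1, 1]")
    i = model._idx(term)
    u = model.unit_vectors
    sims = u @ u[i]
    out = [
        (model.vocabulary[j], float(min(1.0, max(-1.0, sims[j]))))
        for j in range(len(model))
        if j != i and sims[j] > threshold
    ]
    out.sort(key=lambda p: (-p[1], p[0]))
    return out


# ---------------------------------------------------------------------------
# training


@njit(cache=False)
def _sgns_kernel(
    tokens: np.ndarray,       # int32 token ids, all sentences concatenated
    offsets: np.ndarray,      # int64 sentence boundaries, len = n_sent + 1
    w_in: np.ndarray,         # (V, d) float32, updated in place
    w_out: np.ndarray,        # (V, d) float32, updated in place
    neg_table: np.ndarray,    # int32 unigram^0.75 sampling table
    window: int,
    epochs: int,
    negative: int,
    lr0: float,
    lr_min: float,
    seed: int,
):  # pragma: no cover - exercised via train_skipgram
    np.random.seed(seed)
    dim = w_in.shape[1]
    table_size = neg_table.shape[0]
    n_tokens = tokens.shape[0]
    total = epochs * n_tokens
    processed = 0
    neu1e = np.empty(dim, dtype=np.float32)
    for _epoch in range(epochs):
        for s in range(offsets.shape[0] - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                lr = lr0 * (1.0 - processed / total)
                if lr < lr_min:
                    lr = lr_min
                processed += 1
                center = tokens[i]
                reduced = np.random.randint(0, window)  # in [0, window)
                lo = i - (window - reduced)
                hi = i + (window - reduced) + 1
                if lo < start:
                    lo = start
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    context = tokens[j]
                    for k in range(dim):
                        neu1e[k] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = context
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(0, table_size)]
                            if target == context:
                                continue
                            label = 0.0
                        dot = 0.0
                        for k in range(dim):
                            dot += w_in[center, k] * w_out[target, k]
                        if dot > 8.0:
                            f = 1.0
                        elif dot < -8.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - f) * lr
                        for k in range(dim):
                            neu1e[k] += g * w_out[target, k]
                            w_out[target, k] += g * w_in[center, k]
                    for k in range(dim):
                        w_in[center, k] += neu1e[k]


def _negative_table(counts: np.ndarray, size: int = 200_000) -> np.ndarray:
    weights = counts.astype(np.float64) ** 0.75
    weights /= weights.sum()
    boundaries = np.cumsum(weights) * size
    table = np.zeros(size, dtype=np.int32)
    idx = 0
    for pos in range(size):
        while idx < len(boundaries) - 1 and pos >= boundaries[idx]:
            idx += 1
        table[pos] = idx
    return table


def train_skipgram(
    corpus: Iterable[TokenizedPost] | Iterable[Sequence[str]],
    params: EmbeddingParams | None = None,
    **overrides,
) -> EmbeddingModel:
    """Train skip-gram embeddings on a tokenized corpus.

    ``corpus`` may be TokenizedPost objects or plain token sequences. The
    vocabulary keeps terms with corpus frequency >= ``min_count``, ordered by
    descending frequency (ties lexicographic). Deterministic for a fixed
    ``params.seed``.
    """
    if params is None:
        params = EmbeddingParams()
    if overrides:
        params = replace(params, **overrides)

    sentences: list[Sequence[str]] = [
        p.tokens if isinstance(p, TokenizedPost) else p for p in corpus
    ]
    counts = Counter(t for sent in sentences for t in sent)
    vocab = sorted(
        (t for t, c in counts.items() if c >= params.min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise VocabularyError(
            f"no term reaches min_count={params.min_count}; effective vocabulary empty"
        )
    index = {t: i for i, t in enumerate(vocab)}
    vocab_counts = np.array([counts[t] for t in vocab], dtype=np.int64)

    encoded: list[np.ndarray] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        if len(ids) > 1:
            encoded.append(np.array(ids, dtype=np.int32))
    if not encoded:
        # vocabulary exists but no sentence retains two in-vocabulary tokens
        rng = np.random.default_rng(params.seed)
        vecs = (rng.random((len(vocab), params.dimension)) - 0.5) / params.dimension
        return EmbeddingModel(vocab, vecs, params)

    tokens = np.concatenate(encoded)
    offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
    np.cumsum([len(e) for e in encoded], out=offsets[1:])

    rng = np.random.default_rng(params.seed)
    w_in = ((rng.random((len(vocab), params.dimension)) - 0.5) / params.dimension).astype(
        np.float32
    )
    w_out = np.zeros((len(vocab), params.dimension), dtype=np.float32)
    neg_table = _negative_table(vocab_counts)

    _sgns_kernel(
        tokens,
        offsets,
        w_in,
        w_out,
        neg_table,
        params.window,
        params.epochs,
        params.negative_samples,
        params.initial_lr,
        params.min_lr,
        int(params.seed) % (2**31 - 1),
    )
    return EmbeddingModel(vocab, w_in.astype(np.float64), params)


# ---------------------------------------------------------------------------
# persistence (word2vec text format: header "n d", then "term v1 ... vd")


def save_word2vec(model: EmbeddingModel, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(model)} {model.vectors.shape[1]}\n")
        for term, vec in zip(model.vocabulary, model.vectors):
            fh.write(term + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def load_word2vec(path: str | Path) -> EmbeddingModel:
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        vocab: list[str] = []
        vectors = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab.append(parts[0])
            vectors[i] = [float(x) for x in parts[1 : d + 1]]
    return EmbeddingModel(vocab, vectors)
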