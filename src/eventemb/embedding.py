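"""Skip-Gram-with-negative-sampling training of event coordinates.

Each sampled environment is one training sentence (center token first,
then its s context tokens) and the context window spans the whole sentence,
so every context token co-occurs with its center.  Training is plain SGD
over (center, context) pairs with a unigram^0.75 noise distribution,
single-threaded and therefore bit-reproducible under a fixed seed.

The inner loop is JIT-compiled with numba when available; a vectorized
mini-batch numpy fallback keeps the module importable without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from eventemb.sampling import Environment
from eventemb.temporal_io import Event

__all__ = ["SkipGramParams", "EventEmbedding", "train_embedding", "load_word2vec_text"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class SkipGramParams:
    """Hyper-parameters; defaults follow standard word-embedding practice."""

    window: Optional[int] = None  # None => whole sentence
    pair_mode: str = "all"  # "all": every within-window pair; "center": (center, context) pairs only
    tied_weights: bool = True  # share input/output matrices (better geometry on sparse graphs)
    negative_samples: int = 5
    epochs: int = 5
    initial_learning_rate: float = 0.025
    min_learning_rate: float = 0.0001
    min_count: int = 1
    seed: int = 0


@dataclass
class EventEmbedding:
    """d-dimensional coordinates per event token."""

    dimension: int
    tokens: List[str]
    matrix: np.ndarray  # (n_tokens, dimension)
    trainer_params: Optional[SkipGramParams] = None
    _index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.tokens), self.dimension):
            raise ValueError("matrix shape does not match tokens/dimension")
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    def __contains__(self, key: Union[str, Event]) -> bool:
        return self._key(key) in self._index

    def _key(self, key: Union[str, Event]) -> str:
        return key.token if isinstance(key, Event) else key

    def vector(self, key: Union[str, Event]) -> np.ndarray:
        tok = self._key(key)
        try:
            return self.matrix[self._index[tok]]
        except KeyError:
            raise KeyError(f"token {tok!r} has no embedding vector") from None

    def euclidean_distance(self, a: Union[str, Event], b: Union[str, Event]) -> float:
        return float(np.linalg.norm(self.vector(a) - self.vector(b)))

    def save_word2vec_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.dimension}\n")
            for tok, row in zip(self.tokens, self.matrix):
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def load_word2vec_text(path) -> EventEmbedding:
    with open(path, "r", encoding="utf-8") as fh:
        n, d = map(int, fh.readline().split())
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1 : d + 1]])
    if len(tokens) != n:
        raise ValueError(f"header promised {n} tokens, file has {len(tokens)}")
    return EventEmbedding(d, tokens, np.asarray(rows, dtype=np.float32))


@njit(cache=False)
def _sgns_kernel(pairs, w_in, w_out, noise, epochs, neg, lr0, lr_min, seed):  # pragma: no cover
    np.random.seed(seed)
    n_pairs = pairs.shape[0]
    dim = w_in.shape[1]
    total = n_pairs * epochs
    step = 0
    grad = np.empty(dim, dtype=np.float32)
    for _ in range(epochs):
        for p in range(n_pairs):
            lr = lr0 * (1.0 - step / total)
            if lr < lr_min:
                lr = lr_min
            c = pairs[p, 0]
            for d in range(dim):
                grad[d] = 0.0
            for k in range(neg + 1):
                if k == 0:
                    target = pairs[p, 1]
                    label = 1.0
                else:
                    target = noise[np.random.randint(noise.shape[0])]
                    if target == pairs[p, 1]:
                        continue
                    label = 0.0
                score = 0.0
                for d in range(dim):
                    score += w_in[c, d] * w_out[target, d]
                if score > 6.0:
                    f = 1.0
                elif score < -6.0:
                    f = 0.0
                else:
                    f = 1.0 / (1.0 + math.exp(-score))
                g = (label - f) * lr
                for d in range(dim):
                    grad[d] += g * w_out[target, d]
                    w_out[target, d] += g * w_in[c, d]
            for d in range(dim):
                w_in[c, d] += grad[d]
            step += 1


def _sgns_numpy(pairs, w_in, w_out, noise, epochs, neg, lr0, lr_min, seed, batch=512):
    """Mini-batch fallback: within-batch updates are accumulated, which is a
    coarser approximation of per-pair SGD but preserves determinism."""
    rng = np.random.default_rng(seed)
    n_pairs = pairs.shape[0]
    total = n_pairs * epochs
    step = 0
    for _ in range(epochs):
        for start in range(0, n_pairs, batch):
            block = pairs[start : start + batch]
            m = block.shape[0]
            lr = max(lr_min, lr0 * (1.0 - step / total))
            centers = block[:, 0]
            targets = np.empty((m, neg + 1), dtype=np.int64)
            targets[:, 0] = block[:, 1]
            targets[:, 1:] = noise[rng.integers(0, len(noise), size=(m, neg))]
            labels = np.zeros((m, neg + 1), dtype=np.float32)
            labels[:, 0] = 1.0
            # accidental positives among negatives are masked out
            mask = np.ones((m, neg + 1), dtype=bool)
            mask[:, 1:] = targets[:, 1:] != block[:, 1:2]
            v = w_in[centers]  # (m, dim)
            u = w_out[targets]  # (m, neg+1, dim)
            score = np.clip(np.einsum("md,mkd->mk", v, u), -6.0, 6.0)
            f = 1.0 / (1.0 + np.exp(-score))
            g = ((labels - f) * lr * mask).astype(np.float32)
            np.add.at(w_in, centers, np.einsum("mk,mkd->md", g, u))
            np.add.at(w_out.reshape(-1, w_out.shape[1]), targets.ravel(),
                      (g[:, :, None] * v[:, None, :]).reshape(-1, w_out.shape[1]))
            step += m
    return


def _corpus_sentences(corpus: Iterable) -> List[List[str]]:
    sentences = []
    for item in corpus:
        if isinstance(item, Environment):
            sentences.append(item.tokens)
        else:
            sentences.append([t.token if isinstance(t, Event) else str(t) for t in item])
    return sentences


def train_embedding(
    corpus: Sequence, d: int, params: Optional[SkipGramParams] = None
) -> EventEmbedding:
    """Train Skip-Gram vectors on a corpus of environments.

    Parameters
    ----------
    corpus:
        Environments (or pre-tokenized sentences). Each sentence contributes
        every ordered within-window token pair as a (center, context)
        training example.
    d:
        Embedding dimension, >= 1.
    """
    params = params or SkipGramParams()
    if d < 1:
        raise ValueError("dimension must be >= 1")
    sentences = _corpus_sentences(corpus)
    if not sentences:
        raise ValueError("empty corpus")

    counts: Dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError("no token satisfies min_count")
    index = {tok: i for i, tok in enumerate(vocab)}

    pair_list = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        n = len(ids)
        if params.pair_mode == "center":
            # first token is the sampled center; it co-occurs with every
            # context token, in both skip-gram directions
            for b in range(1, n):
                if ids[b] != ids[0]:
                    pair_list.append((ids[0], ids[b]))
                    pair_list.append((ids[b], ids[0]))
        elif params.pair_mode == "all":
            win = params.window if params.window is not None else n
            for a in range(n):
                lo, hi = max(0, a - win), min(n, a + win + 1)
                for b in range(lo, hi):
                    # token-identical pairs are artifacts of with-replacement
                    # sampling and carry no co-occurrence information
                    if b != a and ids[b] != ids[a]:
                        pair_list.append((ids[a], ids[b]))
        else:
            raise ValueError(f"unknown pair_mode {params.pair_mode!r}")
    if not pair_list:
        raise ValueError("corpus yields no training pairs")
    pairs = np.asarray(pair_list, dtype=np.int64)

    # unigram^0.75 noise table, word2vec-style
    freq = np.array([counts[tok] for tok in vocab], dtype=np.float64) ** 0.75
    freq /= freq.sum()
    table_size = max(len(vocab) * 10, 100_000)
    noise = np.repeat(
        np.arange(len(vocab)), np.maximum(1, np.round(freq * table_size).astype(np.int64))
    )

    rng = np.random.default_rng(params.seed)
    w_in = ((rng.random((len(vocab), d)) - 0.5) / d).astype(np.float32)
    # tied weights make positive pairs attract and negatives repel within one
    # coordinate space, which markedly improves the embedding geometry on
    # sparse event graphs; the untied variant is the word2vec classic
    w_out = w_in if params.tied_weights else np.zeros((len(vocab), d), dtype=np.float32)
    # pair order is shuffled once up front so consecutive updates decorrelate
    pairs = pairs[rng.permutation(len(pairs))]

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    if _HAVE_NUMBA:
        _sgns_kernel(
            pairs, w_in, w_out, noise, params.epochs, params.negative_samples,
            np.float32(params.initial_learning_rate), np.float32(params.min_learning_rate),
            kernel_seed,
        )
    else:
        _sgns_numpy(
            pairs, w_in, w_out, noise, params.epochs, params.negative_samples,
            params.initial_learning_rate, params.min_learning_rate, kernel_seed,
        )
    return EventEmbedding(d, vocab, w_in, trainer_params=params)
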