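"""Skip-gram with negative sampling (SGNS), vectorized in numpy.

The corpora produced from ontology axioms and gene annotations are small
(thousands of short sentences), so training runs comfortably on one CPU in
plain numpy.  The implementation follows the standard word2vec recipe:
unigram^0.75 noise distribution, sigmoid/logistic loss on (center, context)
pairs, linearly decaying learning rate.  A fixed (rather than randomly
shrunk) context window is used so that training is exactly reproducible
under a fixed seed with a single worker.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

__all__ = ["train_sgns"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _build_vocab(
    sentences: Sequence[Sequence[str]],
    min_count: int,
    keep_tokens: frozenset[str],
) -> tuple[dict[str, int], np.ndarray]:
    counts = Counter(token for sentence in sentences for token in sentence)
    vocab_tokens = sorted(
        t for t, c in counts.items() if c >= min_count or t in keep_tokens
    )
    if not vocab_tokens:
        raise ValueError("no token reaches min_count and no kept tokens occur")
    index = {t: i for i, t in enumerate(vocab_tokens)}
    freqs = np.array([counts[t] for t in vocab_tokens], dtype=np.float64)
    return index, freqs


def _training_pairs(
    sentences: Sequence[Sequence[str]], index: dict[str, int], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for sentence in sentences:
        ids = [index[t] for t in sentence if t in index]
        for i, center in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(center)
                    contexts.append(ids[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_sgns(
    sentences: Iterable[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    min_count: int = 5,
    epochs: int = 60,
    negative: int = 5,
    learning_rate: float = 0.025,
    seed: int = 0,
    keep_tokens: Iterable[str] = (),
    batch_size: int = 256,
) -> dict[str, np.ndarray]:
    """Train skip-gram embeddings and return a token -> vector map.

    Tokens occurring fewer than ``min_count`` times are dropped from the
    vocabulary unless listed in ``keep_tokens`` (used to guarantee a vector
    for every annotated gene regardless of its annotation count).
    """
    sentences = [list(s) for s in sentences]
    if not sentences:
        raise ValueError("empty corpus")
    keep = frozenset(keep_tokens)
    index, freqs = _build_vocab(sentences, min_count, keep)
    centers, contexts = _training_pairs(sentences, index, window)
    if centers.size == 0:
        raise ValueError("corpus yields no training pairs after vocabulary pruning")

    vocab_size = len(index)
    rng = np.random.default_rng(seed)
    W = (rng.random((vocab_size, dim)) - 0.5) / dim  # input (word) vectors
    C = np.zeros((vocab_size, dim))  # output (context) vectors

    noise = freqs**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    n_pairs = centers.size
    total_batches = max(1, epochs * -(-n_pairs // batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            lr = learning_rate * max(1e-4, 1.0 - batch_no / total_batches)
            batch_no += 1
            idx = order[start : start + batch_size]
            c, o = centers[idx], contexts[idx]
            neg = np.searchsorted(noise_cdf, rng.random((idx.size, negative)))

            wc, co = W[c], C[o]
            g_pos = _sigmoid(np.einsum("bd,bd->b", wc, co)) - 1.0
            grad_w = g_pos[:, None] * co
            grad_o = g_pos[:, None] * wc

            cn = C[neg]
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", wc, cn))
            g_neg[neg == o[:, None]] = 0.0  # accidental hits of the true context
            grad_w += np.einsum("bk,bkd->bd", g_neg, cn)
            grad_n = g_neg[..., None] * wc[:, None, :]

            np.add.at(W, c, -lr * grad_w)
            np.add.at(C, o, -lr * grad_o)
            np.add.at(C, neg.ravel(), -lr * grad_n.reshape(-1, dim))

    return {token: W[i].copy() for token, i in index.items()}
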