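"""Skip-gram-with-negative-sampling (SGNS) embeddings trained on walk corpora.

Each gene ends up with one dense vector; genes whose walk neighborhoods
overlap (i.e. that live in the same network community) end up close in the
embedding space.  The objective per (center c, context o) pair is

    log sigma(u_c . v_o) + sum_k E_{n~P_n} log sigma(-u_c . v_n)

with P_n the unigram distribution raised to the 3/4 power.  Training is
plain SGD with linear learning-rate decay, single-threaded and fully
deterministic for a fixed seed; the inner loop is JIT-compiled.  The input
(center) vectors are the exported representation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from numba import njit

from .errors import ParseError, ValidationError
from .walks import WalkCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbedParams:
    dimension: int = 512
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dimension", "window", "negatives", "epochs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not self.learning_rate > 0:
            raise ValidationError(f"learning_rate must be > 0, got {self.learning_rate}")


@dataclass
class EmbeddingMatrix:
    """Ordered gene ids and one row vector per id."""

    ids: list[str]
    vectors: np.ndarray  # shape (len(ids), dimension)

    def __post_init__(self) -> None:
        if len(self.ids) != self.vectors.shape[0]:
            raise ValidationError("ids / vectors row count mismatch")
        self._index = {g: i for i, g in enumerate(self.ids)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, gene: str) -> np.ndarray:
        return self.vectors[self._index[gene]]

    def rows(self, genes: list[str]) -> np.ndarray:
        try:
            return self.vectors[[self._index[g] for g in genes]]
        except KeyError as exc:
            raise ValidationError(f"gene {exc.args[0]!r} has no embedding row") from exc

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


def extract_pairs(corpus: WalkCorpus, window: int) -> Iterator[tuple[str, str]]:
    """Yield every (center, context) pair with |i - j| <= window, j != i."""
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    for walk in corpus.walks:
        n = len(walk)
        for i in range(n):
            for j in range(max(0, i - window), min(n, i + window + 1)):
                if j != i:
                    yield walk[i], walk[j]


def noise_distribution(corpus: WalkCorpus) -> tuple[list[str], np.ndarray]:
    """Smoothed unigram negative-sampling distribution: freq^0.75, normalized.
    Ids returned sorted."""
    counts = Counter(tok for walk in corpus.walks for tok in walk)
    ids = sorted(counts)
    freq = np.array([counts[g] for g in ids], dtype=float)
    smoothed = freq ** 0.75
    return ids, smoothed / smoothed.sum()


def _build_alias_arrays(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(p)
    scaled = p * n
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] -= 1.0 - scaled[s]
        (small if scaled[l] < 1.0 else large).append(l)
    for i in large + small:
        prob[i] = 1.0
    return prob, alias


@njit(cache=True)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state * np.uint64(2685821657736338717)


@njit(cache=True)
def _uniform(state: np.uint64) -> float:
    return float(state >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _sgns_train(tokens, offsets, w_in, w_out, window, negatives,
                alias_prob, alias_alias, lr0, lr_min, epochs, seed, epoch_loss):
    dim = w_in.shape[1]
    vocab = w_in.shape[0]
    n_walks = offsets.shape[0] - 1
    # pairs per epoch (for the LR schedule)
    pairs_per_epoch = 0
    for wi in range(n_walks):
        n = offsets[wi + 1] - offsets[wi]
        for i in range(n):
            lo = i - window
            if lo < 0:
                lo = 0
            hi = i + window
            if hi > n - 1:
                hi = n - 1
            pairs_per_epoch += hi - lo  # excludes j == i
    total_steps = epochs * pairs_per_epoch
    if total_steps < 2:
        total_steps = 2
    state = np.uint64(seed * np.uint64(2654435761) + np.uint64(1))
    step = 0
    neu = np.zeros(dim)
    for ep in range(epochs):
        loss = 0.0
        npairs = 0
        for wi in range(n_walks):
            start = offsets[wi]
            n = offsets[wi + 1] - start
            for i in range(n):
                c = tokens[start + i]
                lo = i - window
                if lo < 0:
                    lo = 0
                hi = i + window
                if hi > n - 1:
                    hi = n - 1
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    ctx = tokens[start + j]
                    lr = lr0 + (lr_min - lr0) * (step / (total_steps - 1))
                    for d in range(dim):
                        neu[d] = 0.0
                    for k in range(negatives + 1):
                        if k == 0:
                            target = ctx
                            label = 1.0
                        else:
                            state = _xorshift(state)
                            col = int(_uniform(state) * vocab)
                            if col >= vocab:
                                col = vocab - 1
                            state = _xorshift(state)
                            if _uniform(state) < alias_prob[col]:
                                target = col
                            else:
                                target = alias_alias[col]
                            label = 0.0
                        f = 0.0
                        for d in range(dim):
                            f += w_in[c, d] * w_out[target, d]
                        if f > 30.0:
                            sig = 1.0
                        elif f < -30.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        if label > 0.5:
                            loss -= np.log(sig + 1e-12)
                        else:
                            loss -= np.log(1.0 - sig + 1e-12)
                        g = (label - sig) * lr
                        for d in range(dim):
                            neu[d] += g * w_out[target, d]
                            w_out[target, d] += g * w_in[c, d]
                    for d in range(dim):
                        w_in[c, d] += neu[d]
                    step += 1
                    npairs += 1
        epoch_loss[ep] = loss / max(1, npairs)
    return pairs_per_epoch


def train_sgns(corpus: WalkCorpus, params: EmbedParams) -> EmbeddingMatrix:
    """Train SGNS vectors on the walk corpus.

    Deterministic for fixed (corpus, params); returns one row per gene that
    appears in the corpus, in sorted-id order, plus the per-epoch mean loss
    trace on the returned matrix's ``loss_trace`` attribute.
    """
    if not corpus.walks:
        raise ValidationError("cannot train on an empty corpus")
    ids, noise = noise_distribution(corpus)
    index = {g: i for i, g in enumerate(ids)}
    tokens = np.fromiter(
        (index[tok] for walk in corpus.walks for tok in walk),
        dtype=np.int32,
        count=sum(len(w) for w in corpus.walks),
    )
    offsets = np.zeros(len(corpus.walks) + 1, dtype=np.int64)
    np.cumsum([len(w) for w in corpus.walks], out=offsets[1:])
    alias_prob, alias_alias = _build_alias_arrays(noise)

    rng = np.random.default_rng(params.seed)
    dim = params.dimension
    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(len(ids), dim))
    w_out = np.zeros((len(ids), dim))
    epoch_loss = np.zeros(params.epochs)
    pairs = _sgns_train(
        tokens, offsets, w_in, w_out, params.window, params.negatives,
        alias_prob, alias_alias, params.learning_rate, params.learning_rate / 100.0,
        params.epochs, np.uint64(params.seed % (2 ** 63) + 7), epoch_loss,
    )
    logger.info("SGNS: %d genes, %d pairs/epoch, loss %.4f -> %.4f",
                len(ids), pairs, epoch_loss[0], epoch_loss[-1])
    if not np.all(np.isfinite(w_in)):
        raise ValidationError("training produced non-finite embeddings")
    matrix = EmbeddingMatrix(ids=ids, vectors=w_in)
    matrix.loss_trace = epoch_loss.tolist()
    return matrix


def save_embeddings(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """word2vec text format: header ``<count> <dim>``, then one id + vector
    per line at 10 significant digits."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(matrix.ids)} {matrix.dimension}\n")
        for gene, row in zip(matrix.ids, matrix.vectors):
            fh.write(gene + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


def load_embeddings(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: malformed header {header!r}")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer header {header!r}") from exc
        ids: list[str] = []
        vectors = np.empty((count, dim))
        for row, line in enumerate(fh):
            fields = line.rstrip("\n").split(" ")
            if len(fields) != dim + 1:
                raise ParseError(
                    f"{path}: row {row + 1} ({fields[0]!r}) has {len(fields) - 1} values, expected {dim}")
            if row >= count:
                raise ParseError(f"{path}: more rows than header count {count}")
            ids.append(fields[0])
            vectors[row] = [float(v) for v in fields[1:]]
    if len(ids) != count:
        raise ParseError(f"{path}: header promises {count} rows, found {len(ids)}")
    return EmbeddingMatrix(ids=ids, vectors=vectors)
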