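"""Shallow neural word embeddings (CBOW / skip-gram with negative sampling).

The trainer learns a map f from each corpus token w to a dense vector such
that tokens sharing textual context Cw receive similar vectors.  Training
follows the classic word2vec recipe: per-example stochastic gradient descent
on the negative-sampling log-loss, a dynamic context window of uniform width
1..window, frequent-word subsampling, a unigram^(3/4) noise distribution and
a linearly annealed learning rate.  The inner loop is numba-compiled; a
single deterministic worker is the only mode, so identical (corpus, config,
seed) give identical vectors.

The per-example loss and analytic gradients are also exposed as plain numpy
functions (:func:`example_loss_and_grads`) so the compiled kernel's
arithmetic can be validated against numerical differentiation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_prep import SentenceCorpus

__all__ = [
    "Vocabulary",
    "TrainConfig",
    "EmbeddingModel",
    "MissingTermError",
    "build_vocabulary",
    "train_embeddings",
    "cosine",
    "example_loss_and_grads",
    "corpus_loss",
]


class MissingTermError(KeyError):
    """A queried token is not in the model vocabulary."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:
        return f"term not in vocabulary: {self.token!r}"


class Vocabulary:
    """Dense token↔index mapping with corpus counts.

    Tokens are ordered by descending count, ties broken lexicographically,
    so the index assignment is a pure function of the corpus.
    """

    def __init__(self, counts: Mapping[str, int]):
        items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self.tokens: list[str] = [t for t, _ in items]
        self.counts = np.array([c for _, c in items], dtype=np.int64)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> int:
        try:
            return self.index[token]
        except KeyError:
            raise MissingTermError(token) from None

    def count(self, token: str) -> int:
        return int(self.counts[self[token]])


def build_vocabulary(
    corpus: SentenceCorpus | Iterable[Sequence[str]], min_count: int = 1
) -> Vocabulary:
    """Tally corpus tokens and drop those seen fewer than *min_count* times."""
    tally: Counter[str] = Counter()
    n_sent = 0
    for sent in corpus:
        n_sent += 1
        tally.update(sent)
    if n_sent == 0 or not tally:
        raise ValueError("empty corpus")
    return Vocabulary({t: c for t, c in tally.items() if c >= min_count})


@dataclass
class TrainConfig:
    """Embedding hyperparameters.

    Defaults follow the common word2vec settings: 150-dimensional vectors, a
    ±5-token context window, every token embedded (min_count=1), CBOW
    architecture, 5 negative samples, 5 epochs, learning rate annealed
    0.025 → 1e-4, and subsampling threshold 1e-3.
    """

    dim: int = 150
    window: int = 5
    min_count: int = 1
    architecture: str = "cbow"  # or "skipgram"
    negative: int = 5
    epochs: int = 5
    initial_lr: float = 0.025
    final_lr: float = 1e-4
    subsample_threshold: float = 1e-3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.architecture not in ("cbow", "skipgram"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class EmbeddingModel:
    """Learned embedding: vocabulary plus input and context weight matrices.

    ``input_vectors[i]`` is the vector of token i (what :meth:`vector`
    returns); ``context_vectors`` holds the output-side parameters that
    predict a token's context during training.
    """

    vocabulary: Vocabulary
    input_vectors: np.ndarray
    context_vectors: np.ndarray
    config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        V = len(self.vocabulary)
        if self.input_vectors.shape[0] != V or self.context_vectors.shape[0] != V:
            raise ValueError("weight row count != vocabulary size")
        if not (np.isfinite(self.input_vectors).all()
                and np.isfinite(self.context_vectors).all()):
            raise ValueError("non-finite entries in weight matrices")

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        """The input vector of *token*; raises MissingTermError if absent."""
        return self.input_vectors[self.vocabulary[token]]

    def similarity(self, a: str, b: str) -> float:
        return cosine(self.vector(a), self.vector(b))

    def nearest_neighbors(
        self,
        token: str,
        k: int,
        restrict_to: Iterable[str] | None = None,
    ) -> list[tuple[str, float]]:
        """Top-*k* tokens by cosine to *token*, the query itself excluded.

        If *restrict_to* is given only those tokens are eligible (silently
        ignoring any that are out of vocabulary).  Ties break
        lexicographically.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        qi = self.vocabulary[token]
        if restrict_to is None:
            cand = [i for i in range(len(self.vocabulary)) if i != qi]
        else:
            cand = sorted(
                {self.vocabulary.index[t] for t in restrict_to
                 if t in self.vocabulary and self.vocabulary.index[t] != qi}
            )
        if not cand:
            return []
        q = self.input_vectors[qi]
        M = self.input_vectors[cand]
        qn = np.linalg.norm(q)
        Mn = np.linalg.norm(M, axis=1)
        if qn == 0 or (Mn == 0).any():
            raise ValueError("undefined similarity: zero vector")
        sims = (M @ q) / (Mn * qn)
        pairs = [(self.vocabulary.tokens[i], float(s)) for i, s in zip(cand, sims)]
        pairs.sort(key=lambda ts: (-ts[1], ts[0]))
        return pairs[:k]

    def save(self, out_dir: str | Path) -> None:
        """Write vectors as TSV (token + components) and config metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "vectors.tsv", "w", encoding="utf-8") as fh:
            for i, tok in enumerate(self.vocabulary.tokens):
                row = "\t".join(repr(float(x)) for x in self.input_vectors[i])
                fh.write(f"{tok}\t{row}\n")
        with open(out / "context_vectors.tsv", "w", encoding="utf-8") as fh:
            for i, tok in enumerate(self.vocabulary.tokens):
                row = "\t".join(repr(float(x)) for x in self.context_vectors[i])
                fh.write(f"{tok}\t{row}\n")
        meta = {
            "config": asdict(self.config),
            "vocab_size": len(self.vocabulary),
            "counts": {t: int(self.vocabulary.count(t))
                       for t in self.vocabulary.tokens},
        }
        (out / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "EmbeddingModel":
        out = Path(out_dir)
        meta = json.loads((out / "model.json").read_text())
        config = TrainConfig(**meta["config"])
        vocab = Vocabulary(meta["counts"])

        def read_matrix(path: Path) -> np.ndarray:
            vecs = np.empty((len(vocab), config.dim))
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    vecs[vocab[parts[0]]] = [float(x) for x in parts[1:]]
            return vecs

        return cls(vocab, read_matrix(out / "vectors.tsv"),
                   read_matrix(out / "context_vectors.tsv"), config)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u·v / (|u||v|); errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors have different lengths")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("undefined similarity: zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


# --------------------------------------------------------------------------
# reference loss / gradients (numpy, float64) — used by tests and corpus_loss


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def example_loss_and_grads(
    w_in: np.ndarray,
    w_out: np.ndarray,
    center: int,
    context: Sequence[int],
    negatives: Sequence[int],
    architecture: str = "cbow",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative-sampling log-loss and analytic gradients for one example.

    CBOW: the hidden state is the mean of the context input vectors and the
    positive output is the center token.  Skip-gram: the hidden state is the
    center input vector and each context token is a positive output (the
    same negatives are reused for each, and the loss sums over them).

    Returns (loss, dL/dw_in, dL/dw_out), gradients as full dense matrices.
    """
    w_in = np.asarray(w_in, dtype=float)
    w_out = np.asarray(w_out, dtype=float)
    g_in = np.zeros_like(w_in)
    g_out = np.zeros_like(w_out)
    loss = 0.0

    def accumulate(h: np.ndarray, pos: int) -> np.ndarray:
        """Add output-side grads for targets (pos, negatives); return dL/dh."""
        nonlocal loss
        grad_h = np.zeros_like(h)
        for label, t in [(1.0, pos)] + [(0.0, n) for n in negatives]:
            f = _sigmoid(w_out[t] @ h)
            loss += -np.log(f if label == 1.0 else 1.0 - f)
            g = f - label  # d(-log sigma)/d(score)
            grad_h += g * w_out[t]
            g_out[t] += g * h
        return grad_h

    if architecture == "cbow":
        ctx = list(context)
        h = w_in[ctx].mean(axis=0)
        grad_h = accumulate(h, center)
        for c in ctx:
            g_in[c] += grad_h / len(ctx)
    elif architecture == "skipgram":
        h = w_in[center]
        for c in context:
            g_in[center] += accumulate(h, c)
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return loss, g_in, g_out


def corpus_loss(
    model: EmbeddingModel,
    corpus: SentenceCorpus | Iterable[Sequence[str]],
    negatives_seed: int = 0,
) -> float:
    """Mean per-center-token negative-sampling loss over the corpus.

    Negative samples are drawn from the unigram^(3/4) noise distribution
    with a dedicated seed, so two models over the same vocabulary are scored
    against identical noise draws (no subsampling, full window).
    """
    vocab = model.vocabulary
    cfg = model.config
    noise = vocab.counts.astype(float) ** 0.75
    noise /= noise.sum()
    rng = np.random.default_rng(negatives_seed)
    total, n_examples = 0.0, 0
    for sent in corpus:
        idx = [vocab.index[t] for t in sent if t in vocab.index]
        for i, center in enumerate(idx):
            lo, hi = max(0, i - cfg.window), min(len(idx), i + cfg.window + 1)
            ctx = idx[lo:i] + idx[i + 1 : hi]
            if not ctx:
                continue
            negs = rng.choice(len(vocab), size=cfg.negative, p=noise)
            loss, _, _ = example_loss_and_grads(
                model.input_vectors, model.context_vectors, center, ctx,
                list(negs), cfg.architecture,
            )
            total += loss
            n_examples += 1
    if n_examples == 0:
        raise ValueError("corpus has no training examples")
    return total / n_examples


# --------------------------------------------------------------------------
# training


def _noise_cdf(counts: np.ndarray) -> np.ndarray:
    p = counts.astype(np.float64) ** 0.75
    return np.cumsum(p / p.sum())


def _keep_probabilities(counts: np.ndarray, threshold: float) -> np.ndarray:
    """word2vec subsampling: keep token w with prob min(1, sqrt(t/f)+t/f)."""
    if threshold <= 0:
        return np.ones(len(counts))
    freq = counts / counts.sum()
    ratio = threshold / freq
    return np.minimum(1.0, np.sqrt(ratio) + ratio)


def train_embeddings(
    corpus: SentenceCorpus | Iterable[Sequence[str]],
    config: TrainConfig | None = None,
) -> EmbeddingModel:
    """Train an :class:`EmbeddingModel` on a tokenised corpus.

    Input vectors start uniform in ±0.5/dim, context vectors at zero (the
    standard word2vec initialisation).  Deterministic for a fixed
    (corpus, config) pair.
    """
    from . import _w2v_kernel  # deferred: numba compilation is slow to import

    config = config or TrainConfig()
    if isinstance(corpus, SentenceCorpus):
        sentences = corpus.sentences
    else:
        sentences = [list(s) for s in corpus]
    vocab = build_vocabulary(sentences, config.min_count)
    V = len(vocab)

    flat: list[int] = []
    starts = [0]
    for sent in sentences:
        idx = [vocab.index[t] for t in sent if t in vocab.index]
        if idx:
            flat.extend(idx)
            starts.append(len(flat))
    tokens = np.asarray(flat, dtype=np.int32)
    sent_starts = np.asarray(starts, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    w_in = rng.uniform(-0.5 / config.dim, 0.5 / config.dim,
                       size=(V, config.dim)).astype(np.float32)
    w_out = np.zeros((V, config.dim), dtype=np.float32)

    if len(tokens) > 0:
        _w2v_kernel.train(
            tokens,
            sent_starts,
            w_in,
            w_out,
            _noise_cdf(vocab.counts),
            _keep_probabilities(vocab.counts, config.subsample_threshold),
            config.window,
            config.negative,
            config.architecture == "cbow",
            config.epochs,
            config.initial_lr,
            config.final_lr,
            config.seed,
        )

    model = EmbeddingModel(vocab, w_in.astype(np.float64),
                           w_out.astype(np.float64), config)
    return model
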