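"""2D similarity maps of drug/disease vectors and projection diagnostics.

t-SNE places each term's embedding vector on a 2D scatter plot so clusters
of similar drugs or diseases can be inspected visually.  Because t-SNE
distances are not metrically faithful, the projection is for display only —
candidate selection always runs in the original embedding space — and its
neighborhood fidelity is quantified with the rank-based trustworthiness
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .corpus_prep import EntityLexicon

__all__ = ["Map2D", "project_2d", "trustworthiness", "export_map"]


@dataclass
class Map2D:
    """2D coordinates per term plus the projection parameters used."""

    points: dict[str, tuple[float, float]]
    perplexity: float
    seed: int
    iterations: int

    def __len__(self) -> int:
        return len(self.points)

    def coordinates(self, terms: list[str] | None = None) -> np.ndarray:
        terms = terms if terms is not None else sorted(self.points)
        return np.array([self.points[t] for t in terms])


def project_2d(
    vectors: Mapping[str, np.ndarray],
    perplexity: float = 30.0,
    seed: int = 0,
    iterations: int = 1000,
) -> Map2D:
    """Project term vectors onto 2D with t-SNE (PCA initialisation).

    Deterministic for fixed inputs and seed.  Requires at least 3 terms and
    perplexity strictly below the number of terms.
    """
    terms = sorted(vectors)
    n = len(terms)
    if n < 3:
        raise ValueError(f"need at least 3 terms to project, got {n}")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of terms ({n})")
    X = np.asarray([np.asarray(vectors[t], dtype=float) for t in terms])
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=iterations,
    )
    Y = tsne.fit_transform(X)
    if not np.isfinite(Y).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    points = {t: (float(x), float(y)) for t, (x, y) in zip(terms, Y)}
    return Map2D(points, perplexity, seed, iterations)


def trustworthiness(
    high: Mapping[str, np.ndarray], low: Map2D, k: int
) -> float:
    """Rank-based trustworthiness of the 2D layout, in [0, 1].

    T(k) = 1 − 2 / (n·k·(2n − 3k − 1)) · Σ_i Σ_{j ∈ U_i(k)} (r(i, j) − k),
    where U_i(k) are the k nearest low-dimensional neighbors of i that are
    not among its k nearest high-dimensional neighbors, and r(i, j) is j's
    neighbor rank of i in the high-dimensional space.  1 means every 2D
    neighborhood is genuine; random layouts score markedly lower.
    """
    terms = sorted(high)
    if set(terms) != set(low.points):
        raise ValueError("term sets of high- and low-dimensional spaces differ")
    n = len(terms)
    if not 1 <= k < n / 2:
        raise ValueError(f"k must satisfy 1 <= k < n/2 (n={n}, k={k})")
    X = np.asarray([np.asarray(high[t], dtype=float) for t in terms])
    Y = low.coordinates(terms)

    d_high = cdist(X, X)
    d_low = cdist(Y, Y)
    np.fill_diagonal(d_high, np.inf)
    np.fill_diagonal(d_low, np.inf)

    # r[i, j]: rank of j among i's high-dim neighbors (nearest = 1)
    order_high = np.argsort(d_high, axis=1, kind="stable")
    ranks = np.empty_like(order_high)
    rows = np.arange(n)[:, None]
    ranks[rows, order_high] = np.arange(1, n + 1)[None, :]
    ranks[np.arange(n), np.arange(n)] = 0

    knn_low = np.argsort(d_low, axis=1, kind="stable")[:, :k]
    penalty = 0
    for i in range(n):
        high_knn = set(order_high[i, :k])
        for j in knn_low[i]:
            if j not in high_knn:
                penalty += ranks[i, j] - k
    return 1.0 - 2.0 * penalty / (n * k * (2 * n - 3 * k - 1))


def export_map(
    map2d: Map2D,
    lexicon: EntityLexicon,
    path: str | Path,
    entity_type: str | None = None,
) -> int:
    """Write plot data (term, x, y, entity_type, canonical_id) as TSV.

    Terms absent from the lexicon get type "other" and an empty ID.  With
    *entity_type* given, only terms of that type are written.  Returns the
    number of rows written.
    """
    rows = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tx\ty\tentity_type\tcanonical_id\n")
        for term in sorted(map2d.points):
            entry = lexicon.entry_for_token(term)
            etype = entry.entity_type if entry else "other"
            cid = entry.canonical_id if entry else ""
            if entity_type is not None and etype != entity_type:
                continue
            x, y = map2d.points[term]
            fh.write(f"{term}\t{x!r}\t{y!r}\t{etype}\t{cid}\n")
            rows += 1
    return rows


def load_map(path: str | Path) -> Map2D:
    """Round-trip reader for :func:`export_map` output (coordinates only)."""
    points: dict[str, tuple[float, float]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            term, x, y, _etype, _cid = line.rstrip("\n").split("\t")
            points[term] = (float(x), float(y))
    return Map2D(points, perplexity=float("nan"), seed=-1, iterations=0)
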