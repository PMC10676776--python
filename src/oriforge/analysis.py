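"""Sequence-set statistics: GC deciles and cosine similarity in Z-space.

Replication origins are markedly GC-richer than both random and
genome-background sequence, so two simple summaries go a long way: a decile
histogram of per-sequence GC content, and the mean pairwise cosine of the
angle between Z-space encodings, which quantifies how tightly a set clusters
and how it relates to other sets.  The literature often calls the latter
"cosine distance" while using it on the similarity scale (1 = parallel,
0 = unrelated, -1 = opposed); here it is named similarity throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import DnaSequence, gc_content  # noqa: F401  (re-export)
from .zcurve import ZVector


@dataclass(frozen=True)
class GcHistogram:
    """Counts per GC decile L1..L10; bin i covers (0.1*(i-1), 0.1*i], GC=0 in L1."""

    bin_counts: tuple[int, ...]
    n_total: int

    def __post_init__(self) -> None:
        assert len(self.bin_counts) == 10 and sum(self.bin_counts) == self.n_total

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"L{i}" for i in range(1, 11))


@dataclass(frozen=True)
class SetSimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # square, symmetric, entries in [-1, 1]


def gc_histogram(seqs) -> GcHistogram:
    """Decile-bin the GC fractions of a non-empty sequence collection."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("gc_histogram needs at least one sequence")
    counts = [0] * 10
    for s in seqs:
        g = gc_content(s)
        # right-closed bins; round() guards ties like GC=0.10 against float error
        idx = 0 if g == 0 else int(np.ceil(round(g * 10, 9))) - 1
        counts[min(idx, 9)] += 1
    return GcHistogram(tuple(counts), len(seqs))


def cosine_similarity(u, v) -> float:
    """cos of the angle between two equal-dimension nonzero vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _as_matrix(vectors) -> np.ndarray:
    rows = [v.values if isinstance(v, ZVector) else np.asarray(v) for v in vectors]
    return np.asarray(rows, dtype=np.float64)


def mean_set_similarity(sets: dict[str, list]) -> SetSimilarityMatrix:
    """Mean pairwise cosine similarity between and within named vector sets.

    Entry (a, b), a != b: mean over all cross pairs.  Diagonal: mean over all
    unordered distinct pairs within the set (so each set needs >= 2 vectors).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to compare")
    names = tuple(sets)
    mats = {}
    for name, vecs in sets.items():
        m = _as_matrix(vecs)
        if len(m) < 2:
            raise ValueError(f"set {name!r} needs >= 2 vectors for its diagonal entry")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"set {name!r} contains a zero vector")
        mats[name] = m / norms[:, None]
    dims = {m.shape[1] for m in mats.values()}
    if len(dims) > 1:
        raise ValueError(f"sets have mixed dimensions: {sorted(dims)}")
    out = np.empty((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            cos = mats[a] @ mats[b].T
            if i == j:
                n = len(cos)
                val = (cos.sum() - np.trace(cos)) / (n * (n - 1))
            else:
                val = cos.mean()
            out[i, j] = out[j, i] = val
    return SetSimilarityMatrix(names, out)


def embed_2d(vectors, method: str = "lle", seed: int = 0, **kwargs) -> np.ndarray:
    """Project vectors to 2-D for plotting via LLE or t-SNE (scikit-learn)."""
    X = _as_matrix(vectors)
    n = len(X)
    if n < 10:
        raise ValueError("2-D embedding needs at least 10 vectors")
    if method == "lle":
        from sklearn.manifold import LocallyLinearEmbedding

        emb = LocallyLinearEmbedding(
            n_components=2,
            n_neighbors=kwargs.pop("n_neighbors", min(10, n - 1)),
            random_state=seed,
            **kwargs,
        )
    elif method == "tsne":
        from sklearn.manifold import TSNE

        emb = TSNE(
            n_components=2,
            random_state=seed,
            perplexity=kwargs.pop("perplexity", min(30.0, (n - 1) / 3.0)),
            init="pca",
            **kwargs,
        )
    else:
        raise ValueError(f"unknown embedding method {method!r} (use 'lle' or 'tsne')")
    return emb.fit_transform(X)
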