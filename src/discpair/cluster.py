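"""PCA embedding and shared-nearest-neighbor modularity clustering.

The clustering stage mirrors the standard droplet workflow: barcodes are
embedded with PCA on the variable genes, a k-nearest-neighbor graph is
re-weighted by the Jaccard overlap of neighbor lists (shared nearest
neighbors, pruned below 1/15), and communities are found by greedy
modularity optimization (Louvain local moving with aggregation) at a
caller-chosen resolution. The whole stage is deterministic for a fixed
seed: node visit order is the only stochastic ingredient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .normalize import NormMatrix

__all__ = ["Embedding", "ClusterAssignment", "PCAEmbedder", "SNNLouvainClusterer",
           "embed", "cluster", "snn_graph"]

SNN_PRUNE = 1.0 / 15.0
DEFAULT_KNN = 20
DEFAULT_RESOLUTION = 1.0
DEFAULT_PCS = 30


@dataclass
class Embedding:
    """Barcode x k coordinates with per-component variances (descending)."""

    coords: np.ndarray
    variances: np.ndarray
    barcodes: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.coords.shape[0] != len(self.barcodes):
            raise ValueError("embedding rows must match barcodes")


@dataclass
class ClusterAssignment:
    """Per-barcode cluster ids, contiguous from 0, largest cluster first."""

    labels: np.ndarray
    barcodes: list[str]
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        if len(self.labels) != len(self.barcodes):
            raise ValueError("one label per barcode required")
        if ids.size and (ids[0] != 0 or ids[-1] != ids.size - 1):
            raise ValueError("cluster ids must be contiguous from 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


class PCAEmbedder:
    """PCA on gene-centered expression with a deterministic sign convention.

    Signs are fixed so that each component's largest-magnitude gene loading
    is positive, making the embedding reproducible across SVD backends.
    """

    def __init__(self, n_components: int = DEFAULT_PCS):
        if n_components < 2:
            raise ValueError("n_components must be >= 2")
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "PCAEmbedder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """X: barcodes x genes. Returns (coords, variances)."""
        X = np.asarray(X, dtype=float)
        Xc = X - X.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
        k = self.n_components
        if k > rank:
            warnings.warn(
                f"requested {k} components but rank is {rank}; truncating", stacklevel=2
            )
            k = max(rank, 1)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
        flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        coords = U * S * flip
        n = X.shape[0]
        variances = (S ** 2) / max(n - 1, 1)
        self.components_ = Vt * flip[:, None]
        self.explained_variance_ = variances
        return coords, variances


def embed(nm: NormMatrix, hvg: list[str] | pd.Series, k: int = DEFAULT_PCS) -> Embedding:
    """Embed barcodes with PCA on the HVG-restricted normalized matrix."""
    if isinstance(hvg, pd.Series):
        hvg = list(hvg.index)
    present = set(nm.genes)
    missing = [g for g in hvg if g not in present]
    if missing:
        raise ValueError(f"HVG genes absent from matrix: {missing[:5]}")
    sub = nm.subset_genes(list(hvg))
    coords, variances = PCAEmbedder(n_components=k).fit_transform(sub.dense().T)
    return Embedding(coords, variances, nm.barcodes)


def snn_graph(coords: np.ndarray, knn: int = DEFAULT_KNN,
              prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard overlap of knn lists, pruned.

    Neighbor lists include the point itself. Edge weights below ``prune``
    are removed; the result is symmetric with an empty diagonal.
    """
    n = coords.shape[0]
    if knn >= n:
        raise ValueError(f"knn={knn} must be smaller than n_barcodes={n}")
    nn = NearestNeighbors(n_neighbors=knn).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), knn)
    member = sp.csr_matrix(
        (np.ones(n * knn), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (member @ member.T).tocoo()  # |knn(i) & knn(j)|
    inter = shared.data
    jacc = inter / (2.0 * knn - inter)
    keep = (jacc >= prune) & (shared.row != shared.col)
    W = sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return W


def _local_moving(W: sp.csr_matrix, labels: np.ndarray, resolution: float,
                  rng: np.random.Generator) -> bool:
    """Greedy modularity local moving; mutates labels, returns True if any move."""
    n = W.shape[0]
    # row sums already count aggregated self-loops with both directions folded in
    strength = np.asarray(W.sum(axis=1)).ravel()
    two_m = strength.sum()
    if two_m == 0:
        return False
    tot = np.zeros(labels.max() + 1 if n else 0, dtype=float)
    np.add.at(tot, labels, strength)
    indptr, indices, data = W.indptr, W.indices, W.data
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            nbr = indices[indptr[i]:indptr[i + 1]]
            wts = data[indptr[i]:indptr[i + 1]]
            if nbr.size == 0:
                continue
            cand = {}
            for j, w in zip(nbr, wts):
                if j == i:
                    continue
                cand[labels[j]] = cand.get(labels[j], 0.0) + w
            k_i = strength[i]
            base = cand.get(a, 0.0) - resolution * k_i * (tot[a] - k_i) / two_m
            best_c, best_gain = a, 0.0
            for c in sorted(cand):
                if c == a:
                    continue
                gain = (cand[c] - resolution * k_i * tot[c] / two_m) - base
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if best_c != a:
                labels[i] = best_c
                tot[a] -= k_i
                tot[best_c] += k_i
                improved = True
                moved_any = True
    return moved_any


def _aggregate(W: sp.csr_matrix, labels: np.ndarray) -> sp.csr_matrix:
    ids, compact = np.unique(labels, return_inverse=True)
    k = ids.size
    onehot = sp.csr_matrix(
        (np.ones(labels.size), (compact, np.arange(labels.size))), shape=(k, labels.size)
    )
    return sp.csr_matrix(onehot @ W @ onehot.T)


class SNNLouvainClusterer:
    """SNN-graph modularity clustering of an embedding (sklearn-style).

    ``fit_predict(coords)`` returns contiguous labels relabelled by
    decreasing cluster size. Barcodes with no surviving graph edges become
    singleton clusters.
    """

    def __init__(self, knn: int = DEFAULT_KNN, resolution: float = DEFAULT_RESOLUTION,
                 seed: int = 0, prune: float = SNN_PRUNE):
        self.knn = knn
        self.resolution = resolution
        self.seed = seed
        self.prune = prune

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in ("knn", "resolution", "seed", "prune")}

    def set_params(self, **params) -> "SNNLouvainClusterer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_predict(self, coords: np.ndarray) -> np.ndarray:
        W = snn_graph(np.asarray(coords, dtype=float), self.knn, self.prune)
        rng = np.random.default_rng(self.seed)
        labels = np.arange(W.shape[0])
        _local_moving(W, labels, self.resolution, rng)
        # aggregate communities and keep moving until the partition is stable
        while True:
            ids, compact = np.unique(labels, return_inverse=True)
            Wa = _aggregate(W, labels)
            agg_labels = np.arange(Wa.shape[0])
            if not _local_moving(Wa, agg_labels, self.resolution, rng):
                break
            labels = agg_labels[compact]
        self.labels_ = _relabel_by_size(labels)
        return self.labels_


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, compact = np.unique(labels, return_inverse=True)
    sizes = np.bincount(compact)
    # decreasing size; ties broken by first occurrence for determinism
    first = np.full(ids.size, labels.size)
    for pos, c in enumerate(compact):
        if pos < first[c]:
            first[c] = pos
    order = sorted(range(ids.size), key=lambda c: (-sizes[c], first[c]))
    remap = np.empty(ids.size, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[compact]


def cluster(emb: Embedding, knn: int = DEFAULT_KNN,
            resolution: float = DEFAULT_RESOLUTION, seed: int = 0) -> ClusterAssignment:
    """Cluster an embedding with the SNN + greedy-modularity pipeline."""
    model = SNNLouvainClusterer(knn=knn, resolution=resolution, seed=seed)
    labels = model.fit_predict(emb.coords)
    return ClusterAssignment(labels, emb.barcodes, resolution, seed)
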