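"""One-vs-rest marker detection per cluster.

Each gene is tested cluster-vs-rest with a two-sided Wilcoxon rank-sum
test; p-values are Benjamini-Hochberg adjusted per cluster across the
tested genes, and a gene is a significant marker when log2 fold change
> 0.25 and adjusted p < 0.05 (both strict). Only genes detected in at
least ``min_pct`` of the cluster's barcodes are tested. Fold changes are
computed on de-logged means with a pseudocount of 1:

    log2fc = log2((mean(expm1(x_cluster)) + 1) / (mean(expm1(x_rest)) + 1))

For small samples (n + m <= 10) the rank-sum p-value is computed by
exhaustive enumeration over all C(n+m, n) group assignments; larger
samples use the normal approximation with tie and continuity correction.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cluster import ClusterAssignment
from .normalize import NormMatrix

__all__ = ["rank_sum_p", "exact_rank_sum_p", "log2fc", "bh_adjust", "is_marker",
           "find_markers", "top_n", "WilcoxonMarkerFinder"]

LOG2FC_THRESHOLD = 0.25
ALPHA = 0.05
MIN_PCT = 0.10
EXACT_MAX_N = 10
MARKER_COLUMNS = ["cluster", "gene", "log2fc", "p", "p_adj", "significant"]


def exact_rank_sum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments.

    Handles ties via midranks; p = fraction of assignments whose rank-sum
    deviates from its null mean at least as much as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mu = n * (n + m + 1) / 2.0
    w_obs = ranks[:n].sum()
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for comb in combinations(range(n + m), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
    return count / total


def _normal_rank_sum_p(w: float, n: int, m: int, tie_term: float) -> float:
    """Two-sided normal approximation with tie and continuity correction."""
    N = n + m
    mu = n * (N + 1) / 2.0
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    d = abs(w - mu) - 0.5
    if d < 0:
        d = 0.0
    z = d / math.sqrt(var)
    return math.erfc(z / math.sqrt(2.0))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t ** 3 - t))


def rank_sum_p(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``method``: "exact" (enumeration), "normal" (tie/continuity-corrected
    approximation) or "auto" (exact when n + m <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= EXACT_MAX_N else "normal"
    if method == "exact":
        return exact_rank_sum_p(x, y)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = ranks[: len(x)].sum()
    return min(1.0, _normal_rank_sum_p(w, len(x), len(y), _tie_term(pooled)))


def is_marker(lfc: float, p_adj: float, log2fc_threshold: float = LOG2FC_THRESHOLD,
              alpha: float = ALPHA) -> bool:
    """Significance rule: log2 fold change strictly above the threshold AND
    adjusted p strictly below alpha; a gene sitting exactly on either bound
    is not a marker."""
    return lfc > log2fc_threshold and p_adj < alpha


def log2fc(cluster_vals, rest_vals) -> float:
    """log2 fold change of de-logged means with pseudocount 1.

    Inputs are natural-log normalized values (ln(1 + scaled count)).
    """
    a = float(np.mean(np.expm1(cluster_vals)))
    b = float(np.mean(np.expm1(rest_vals)))
    return math.log2((a + 1.0) / (b + 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class WilcoxonMarkerFinder:
    """Per-cluster one-vs-rest Wilcoxon marker detection (sklearn-style).

    ``fit(nm, assignment)`` computes ``markers_``, a long-form table with
    columns cluster, gene, log2fc, p, p_adj, significant. Clusters smaller
    than ``min_cluster_size`` are skipped with a warning; BH adjustment is
    applied per cluster across its tested genes.
    """

    def __init__(self, min_pct: float = MIN_PCT, log2fc_threshold: float = LOG2FC_THRESHOLD,
                 alpha: float = ALPHA, min_cluster_size: int = 3):
        self.min_pct = min_pct
        self.log2fc_threshold = log2fc_threshold
        self.alpha = alpha
        self.min_cluster_size = min_cluster_size

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("min_pct", "log2fc_threshold", "alpha", "min_cluster_size")}

    def set_params(self, **params) -> "WilcoxonMarkerFinder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, nm: NormMatrix, assignment) -> "WilcoxonMarkerFinder":
        labels = (
            assignment.as_series().to_numpy()
            if isinstance(assignment, ClusterAssignment)
            else np.asarray(assignment)
        )
        X = nm.dense()  # genes x barcodes
        n_genes, N = X.shape
        if N != len(labels):
            raise ValueError("assignment length must match barcodes")
        cluster_ids = np.unique(labels)
        if cluster_ids.size < 2:
            raise ValueError("need at least 2 clusters for one-vs-rest tests")

        # global ranks per gene are reused for every cluster's rank sum
        ranks = rankdata(X, axis=1)
        tie_terms = np.array([_tie_term(X[g]) for g in range(n_genes)])
        detected = X > 0
        expm1_sum = np.expm1(X).sum(axis=1)

        rows = []
        for cid in cluster_ids:
            in_c = labels == cid
            n1 = int(in_c.sum())
            n2 = N - n1
            if n1 < self.min_cluster_size:
                warnings.warn(f"cluster {cid} has {n1} < {self.min_cluster_size} "
                              "barcodes; skipped", stacklevel=2)
                continue
            pct = detected[:, in_c].mean(axis=1)
            tested = np.flatnonzero(pct >= self.min_pct)
            if tested.size == 0:
                continue
            w = ranks[np.ix_(tested, np.flatnonzero(in_c))].sum(axis=1)
            pvals = np.array([
                _normal_rank_sum_p(w[k], n1, n2, tie_terms[g])
                for k, g in enumerate(tested)
            ])
            pvals = np.minimum(pvals, 1.0)
            padj = bh_adjust(pvals)
            mean_c = np.expm1(X[np.ix_(tested, np.flatnonzero(in_c))]).mean(axis=1)
            mean_r = (expm1_sum[tested] - mean_c * n1) / n2
            lfc = np.log2((mean_c + 1.0) / (mean_r + 1.0))
            sig = (lfc > self.log2fc_threshold) & (padj < self.alpha)
            for k, g in enumerate(tested):
                rows.append((int(cid), nm.genes[g], float(lfc[k]), float(pvals[k]),
                             float(padj[k]), bool(sig[k])))
        self.markers_ = pd.DataFrame(rows, columns=MARKER_COLUMNS)
        return self

    def fit_transform(self, nm: NormMatrix, assignment) -> pd.DataFrame:
        return self.fit(nm, assignment).markers_


def find_markers(nm: NormMatrix, assignment, min_pct: float = MIN_PCT) -> pd.DataFrame:
    """One-vs-rest marker table for every cluster (see WilcoxonMarkerFinder)."""
    return WilcoxonMarkerFinder(min_pct=min_pct).fit_transform(nm, assignment)


def significant_sets(mt: pd.DataFrame) -> dict:
    """Per-cluster sets of significantly overexpressed genes."""
    sig = mt[mt["significant"]]
    return {c: set(sub["gene"]) for c, sub in sig.groupby("cluster")}


def top_n(mt: pd.DataFrame, n: int = 4) -> dict:
    """Top ``n`` significant genes per cluster, by (p_adj asc, log2fc desc, symbol)."""
    out = {}
    sig = mt[mt["significant"]]
    for c, sub in sig.groupby("cluster"):
        ordered = sub.sort_values(
            by=["p_adj", "log2fc", "gene"], ascending=[True, False, True], kind="stable"
        )
        out[c] = list(ordered["gene"].head(n))
    return out
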