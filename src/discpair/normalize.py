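"""Median-depth log normalization and binned-dispersion variable-gene ranking.

Counts are scaled per barcode to the median sequencing depth and
log-transformed: value(g, b) = ln(1 + count(g, b) * M / depth(b)) with
M the median barcode depth. Variable genes are ranked by the variance of
standardized values, where the expected standard deviation is estimated
per mean-expression bin (20 equal-occupancy bins) and per-gene z-values
are clipped at sqrt(n_barcodes) — the usual vst-style guard against
single-barcode outliers dominating the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tenx_io import CountMatrix

__all__ = ["NormMatrix", "MedianDepthNormalizer", "DispersionHVGSelector",
           "normalize", "select_hvg"]

DEFAULT_N_HVG = 3000
DEFAULT_N_BINS = 20


@dataclass
class NormMatrix:
    """Normalized expression (genes x barcodes, natural-log scale, zero-preserving)."""

    values: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]
    size_factors: np.ndarray
    modality: str = "cells"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("NormMatrix dims do not match gene/barcode labels")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("NormMatrix values must be finite")
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size_factors must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_genes(self, genes: list[str]) -> "NormMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = np.array([pos[g] for g in genes])
        return NormMatrix(self.values[idx, :], list(genes), self.barcodes,
                          self.size_factors, self.modality)


class MedianDepthNormalizer:
    """Scale each barcode to the median depth, then log1p (sklearn-style transformer)."""

    def fit(self, cm: CountMatrix) -> "MedianDepthNormalizer":
        depths = cm.depths().astype(float)
        if np.any(depths <= 0):
            bad = cm.barcodes[int(np.argmin(depths))]
            raise ValueError(f"barcode with zero depth: {bad!r} (run QC first)")
        self.median_depth_ = float(np.median(depths))
        return self

    def transform(self, cm: CountMatrix) -> NormMatrix:
        depths = cm.depths().astype(float)
        if np.any(depths <= 0):
            bad = cm.barcodes[int(np.argmin(depths))]
            raise ValueError(f"barcode with zero depth: {bad!r} (run QC first)")
        scale = self.median_depth_ / depths
        X = sp.csr_matrix(cm.counts.astype(float).multiply(scale[None, :]))
        np.log1p(X.data, out=X.data)
        return NormMatrix(X, cm.genes, cm.barcodes, depths / self.median_depth_, cm.modality)

    def fit_transform(self, cm: CountMatrix) -> NormMatrix:
        return self.fit(cm).transform(cm)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self) -> "MedianDepthNormalizer":
        return self


def normalize(cm: CountMatrix) -> NormMatrix:
    """Median-depth log normalization of a filtered count matrix."""
    return MedianDepthNormalizer().fit_transform(cm)


class DispersionHVGSelector:
    """Rank genes by mean-corrected dispersion of normalized expression.

    Fitted attributes: ``scores_`` (pd.Series indexed by gene, the ranked
    dispersion scores, descending) and ``hvg_`` (the top ``n_top`` symbols).
    Deterministic and invariant to barcode order; ties break
    lexicographically by gene symbol.
    """

    def __init__(self, n_top: int = DEFAULT_N_HVG, n_bins: int = DEFAULT_N_BINS):
        if n_top < 1:
            raise ValueError("n_top must be >= 1")
        self.n_top = n_top
        self.n_bins = n_bins

    def get_params(self, deep: bool = True) -> dict:
        return {"n_top": self.n_top, "n_bins": self.n_bins}

    def set_params(self, **params) -> "DispersionHVGSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, nm: NormMatrix) -> "DispersionHVGSelector":
        X = nm.dense()
        n_genes, n_barcodes = X.shape
        means = X.mean(axis=1)
        sds = X.std(axis=1, ddof=1) if n_barcodes > 1 else np.zeros(n_genes)

        n_bins = self.n_bins if n_genes >= self.n_bins else 1
        order = np.argsort(means, kind="stable")
        expected_sd = np.empty(n_genes)
        for chunk in np.array_split(order, n_bins):
            expected_sd[chunk] = sds[chunk].mean()

        clip = np.sqrt(n_barcodes)
        scores = np.zeros(n_genes)
        ok = expected_sd > 0
        if ok.any():
            Z = (X[ok] - means[ok][:, None]) / expected_sd[ok][:, None]
            np.clip(Z, -clip, clip, out=Z)
            scores[ok] = Z.var(axis=1, ddof=1) if n_barcodes > 1 else 0.0

        # descending score, ties lexicographic by symbol
        ranked = sorted(zip(nm.genes, scores), key=lambda gs: (-gs[1], gs[0]))
        self.scores_ = pd.Series(
            [s for _, s in ranked], index=[g for g, _ in ranked], name="dispersion"
        )
        self.hvg_ = list(self.scores_.index[: self.n_top])
        return self

    def transform(self, nm: NormMatrix) -> NormMatrix:
        return nm.subset_genes([g for g in self.hvg_ if g in set(nm.genes)])

    def fit_transform(self, nm: NormMatrix) -> NormMatrix:
        return self.fit(nm).transform(nm)


def select_hvg(nm: NormMatrix, n: int = DEFAULT_N_HVG) -> pd.Series:
    """Top-``n`` variable genes with dispersion scores (descending).

    Returns all genes when ``n`` exceeds the gene count.
    """
    sel = DispersionHVGSelector(n_top=n).fit(nm)
    return sel.scores_.iloc[: min(n, len(sel.scores_))]
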