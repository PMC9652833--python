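"""Per-barcode QC metrics and modality-specific barcode/gene filters.

Quality rules follow the common Drosophila droplet workflow: barcodes are
dropped when they detect too few genes (< 300; empty droplets, debris),
too many genes (cells: > 3000; nuclei: strictly above the pre-filter
99th-percentile of detected genes — a doublet proxy), or when more than
10% of their reads come from mitochondrial genes (damaged/dying cells).
All bounds are strict: 300, 3000 and exactly 10.0% are kept. Genes are
kept when detected in at least 5 cell barcodes or 3 nuclei barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tenx_io import MODALITIES, CountMatrix

__all__ = [
    "GeneClassRules",
    "compute_qc",
    "filter_barcodes",
    "filter_genes",
    "apply_barcode_filter",
    "BarcodeFilter",
]

QC_COLUMNS = ["n_genes_detected", "pct_mito", "pct_ribo", "pct_hsp", "keep", "drop_reason"]
DROP_REASONS = ("none", "too_few_genes", "too_many_genes", "top1pct_genes", "high_mito")

MIN_GENES = 300
MAX_GENES_CELLS = 3000
NUCLEI_TOP_PERCENTILE = 99.0
MAX_PCT_MITO = 10.0
MIN_BARCODES_PER_GENE = {"cells": 5, "nuclei": 3}


@dataclass
class GeneClassRules:
    """Gene-symbol prefixes defining the mitochondrial/ribosomal/heat-shock classes."""

    mito_prefixes: list[str] = field(default_factory=lambda: ["mt:"])
    ribo_prefixes: list[str] = field(default_factory=lambda: ["RpS", "RpL"])
    hsp_prefixes: list[str] = field(default_factory=lambda: ["Hsp"])

    def __post_init__(self) -> None:
        for name in ("mito_prefixes", "ribo_prefixes", "hsp_prefixes"):
            ps = getattr(self, name)
            if not ps or any(not isinstance(p, str) or not p for p in ps):
                raise ValueError(f"{name} must be a non-empty list of non-empty strings")

    def class_mask(self, genes: list[str], which: str) -> np.ndarray:
        prefixes = {"mito": self.mito_prefixes, "ribo": self.ribo_prefixes,
                    "hsp": self.hsp_prefixes}[which]
        return np.array([any(g.startswith(p) for p in prefixes) for g in genes])


def compute_qc(cm: CountMatrix, rules: GeneClassRules | None = None) -> pd.DataFrame:
    """Per-barcode detected-gene counts and class read percentages.

    Returns a QC table (one row per barcode, index = barcode) with ``keep``
    initialised to True; percentages are 100 * class reads / total reads,
    and all-zero barcodes get 0 for every metric.
    """
    if cm.n_barcodes == 0:
        raise ValueError("empty matrix")
    rules = rules or GeneClassRules()
    X = cm.counts.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    safe = np.where(totals > 0, totals, 1.0)
    pct = {}
    for which in ("mito", "ribo", "hsp"):
        mask = rules.class_mask(cm.genes, which)
        class_sum = np.asarray(X[mask, :].sum(axis=0)).ravel().astype(float)
        pct[which] = np.where(totals > 0, 100.0 * class_sum / safe, 0.0)
    qct = pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "pct_mito": pct["mito"],
            "pct_ribo": pct["ribo"],
            "pct_hsp": pct["hsp"],
            "keep": True,
            "drop_reason": "none",
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )
    qct.attrs["modality"] = cm.modality
    return qct


class BarcodeFilter:
    """Modality-specific barcode filter (scikit-learn style).

    ``fit`` freezes any data-dependent threshold (the nuclei top-1%
    detected-genes cutoff, computed on the pre-filter distribution with
    linear interpolation); ``transform`` flags each barcode with its first
    matching drop reason, in the order too_few_genes -> too_many_genes /
    top1pct_genes -> high_mito.
    """

    def __init__(self, modality: str = "cells", min_genes: int = MIN_GENES,
                 max_genes: int = MAX_GENES_CELLS, max_pct_mito: float = MAX_PCT_MITO,
                 top_percentile: float = NUCLEI_TOP_PERCENTILE):
        self.modality = modality
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_pct_mito = max_pct_mito
        self.top_percentile = top_percentile

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("modality", "min_genes", "max_genes", "max_pct_mito", "top_percentile")}

    def set_params(self, **params) -> "BarcodeFilter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, qct: pd.DataFrame) -> "BarcodeFilter":
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == "nuclei":
            # frozen from the first (pre-filter) pass so filtering is idempotent
            frozen = qct.attrs.get("nuclei_top1pct_threshold")
            self.upper_threshold_ = (
                float(frozen)
                if frozen is not None
                else float(np.percentile(qct["n_genes_detected"], self.top_percentile))
            )
        else:
            self.upper_threshold_ = float(self.max_genes)
        return self

    def transform(self, qct: pd.DataFrame) -> pd.DataFrame:
        out = qct.copy()
        n = out["n_genes_detected"].to_numpy()
        reasons = np.full(len(out), "none", dtype=object)
        too_few = n < self.min_genes
        reasons[too_few] = "too_few_genes"
        upper_reason = "too_many_genes" if self.modality == "cells" else "top1pct_genes"
        too_many = (n > self.upper_threshold_) & ~too_few
        reasons[too_many] = upper_reason
        high_mito = (out["pct_mito"].to_numpy() > self.max_pct_mito) & ~too_few & ~too_many
        reasons[high_mito] = "high_mito"
        out["drop_reason"] = reasons
        out["keep"] = reasons == "none"
        out.attrs = dict(qct.attrs)
        if self.modality == "nuclei":
            out.attrs["nuclei_top1pct_threshold"] = self.upper_threshold_
        return out

    def fit_transform(self, qct: pd.DataFrame) -> pd.DataFrame:
        return self.fit(qct).transform(qct)


def filter_barcodes(qct: pd.DataFrame, modality: str) -> pd.DataFrame:
    """Apply the modality's barcode-quality rules; returns the flagged QC table."""
    return BarcodeFilter(modality=modality).fit_transform(qct)


def apply_barcode_filter(cm: CountMatrix, qct: pd.DataFrame) -> CountMatrix:
    """Subset ``cm`` to the barcodes flagged keep=True in ``qct``."""
    keep = qct["keep"].reindex(cm.barcodes).to_numpy()
    return cm.subset(barcode_idx=np.flatnonzero(keep))


def filter_genes(cm: CountMatrix, modality: str | None = None,
                 min_barcodes: int | None = None) -> CountMatrix:
    """Keep genes detected (count > 0) in at least 5 cells / 3 nuclei.

    Support is counted on the barcodes present in ``cm`` (apply the barcode
    filter first). A result with zero genes is a hard error.
    """
    modality = modality or cm.modality
    if min_barcodes is None:
        if modality not in MIN_BARCODES_PER_GENE:
            raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
        min_barcodes = MIN_BARCODES_PER_GENE[modality]
    support = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    keep = support >= min_barcodes
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    if keep.all():
        return cm
    return cm.subset(gene_idx=np.flatnonzero(keep))
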