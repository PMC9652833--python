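"""Readers and writers for 10x-style count-matrix triplets and tabular references.

A dataset directory holds the conventional triplet ``matrix.mtx[.gz]``,
``features.tsv[.gz]`` and ``barcodes.tsv[.gz]``; counts are UMI counts
(genes x barcodes). The tabular inputs are a marker matrix (curated
identity -> marker-gene table used for cluster annotation) and a merge map
(fine cluster label -> combined cell-type label).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "MarkerMatrix",
    "MergeMap",
    "read_10x",
    "write_10x",
    "read_marker_matrix",
    "read_merge_map",
]

MODALITIES = ("cells", "nuclei")


@dataclass
class CountMatrix:
    """Sparse UMI count matrix (genes x barcodes) with a modality tag.

    Invariants enforced at construction: counts are non-negative integers,
    gene symbols and barcodes are unique, and dimensions match the labels.
    """

    counts: sp.spmatrix
    genes: list[str]
    barcodes: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        n_genes, n_barcodes = self.counts.shape
        if n_genes != len(self.genes):
            raise ValueError(f"matrix has {n_genes} rows but {len(self.genes)} gene symbols")
        if n_barcodes != len(self.barcodes):
            raise ValueError(f"matrix has {n_barcodes} columns but {len(self.barcodes)} barcodes")
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        dup = _first_duplicate(self.barcodes)
        if dup is not None:
            raise ValueError(f"duplicate barcode: {dup!r}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> np.ndarray:
        """Total UMI count per barcode."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset(self, gene_idx=None, barcode_idx=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given index arrays (order preserving)."""
        m = self.counts
        genes, barcodes = self.genes, self.barcodes
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            m = m[gene_idx, :]
            genes = [genes[i] for i in gene_idx]
        if barcode_idx is not None:
            barcode_idx = np.asarray(barcode_idx)
            m = m[:, barcode_idx]
            barcodes = [barcodes[i] for i in barcode_idx]
        return CountMatrix(m, genes, barcodes, self.modality)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.modality == other.modality
            and self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class MarkerMatrix:
    """Reference marker genes per cell identity, with optional positive weights."""

    markers: dict[str, dict[str, float]]
    identities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.identities:
            self.identities = list(self.markers)
        for ident in self.identities:
            genes = self.markers.get(ident, {})
            if not genes:
                raise ValueError(f"identity {ident!r} has no marker genes")
            for g, w in genes.items():
                if not w > 0:
                    raise ValueError(f"marker weight must be > 0 ({ident!r}, {g!r}: {w})")

    def genes(self, identity: str) -> set[str]:
        return set(self.markers[identity])

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.markers.values():
            out.update(genes)
        return out


@dataclass
class MergeMap:
    """Total mapping from fine cluster labels to combined cell-type labels."""

    mapping: dict[str, str]

    def __getitem__(self, label: str) -> str:
        if label not in self.mapping:
            raise KeyError(f"label {label!r} missing from merge map")
        return self.mapping[label]

    def __contains__(self, label: str) -> bool:
        return label in self.mapping

    def extended(self, labels) -> "MergeMap":
        """Return a merge map where unmapped labels map to themselves."""
        mapping = dict(self.mapping)
        for lab in labels:
            mapping.setdefault(lab, lab)
        return MergeMap(mapping)


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Make gene symbols unique by suffixing '.1', '.2', ... in stable order."""
    counts: dict[str, int] = {}
    out = []
    taken = set(symbols)
    for s in symbols:
        if s not in counts:
            counts[s] = 0
            out.append(s)
            continue
        counts[s] += 1
        cand = f"{s}.{counts[s]}"
        while cand in taken:
            counts[s] += 1
            cand = f"{s}.{counts[s]}"
        taken.add(cand)
        out.append(cand)
    return out


def _open_maybe_gz(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_triplet_file(dir_path: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        p = os.path.join(dir_path, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {dir_path}")


def read_10x(dir_path: str, modality: str = "cells") -> CountMatrix:
    """Read a 10x triplet directory into a :class:`CountMatrix`.

    ``features.tsv`` uses column 2 as the gene symbol when present (10x
    convention; column 1 is the gene id), otherwise column 1. Duplicate
    symbols are de-duplicated with '.1', '.2' suffixes. Malformed MTX
    content, dimension mismatches against the tsv files, duplicate
    barcodes and negative or fractional counts are hard errors.
    """
    mtx_path = _find_triplet_file(dir_path, "matrix.mtx")
    feat_path = _find_triplet_file(dir_path, "features.tsv")
    bc_path = _find_triplet_file(dir_path, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed header or body
            raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    symbols = (feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]).tolist()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()

    if mat.shape[0] != len(symbols):
        raise ValueError(
            f"dimension mismatch: matrix declares {mat.shape[0]} genes "
            f"but features.tsv has {len(symbols)} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix declares {mat.shape[1]} barcodes "
            f"but barcodes.tsv has {len(barcodes)} rows"
        )
    dup = _first_duplicate(barcodes)
    if dup is not None:
        raise ValueError(f"duplicate barcode in {bc_path}: {dup!r}")
    symbols = _dedupe_symbols(symbols)
    return CountMatrix(mat, symbols, barcodes, modality)


def write_10x(cm: CountMatrix, dir_path: str, gzip_files: bool = False) -> None:
    """Write ``cm`` as a 10x triplet (coordinate integer general MTX, 1-based)."""
    os.makedirs(dir_path, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(cm.counts), field="integer")
    payload = buf.getvalue()
    # counts are integral by invariant; pin the header even for nnz == 0,
    # where the writer falls back to "real"
    head, rest = payload.split(b"\n", 1)
    head = head.replace(b" real ", b" integer ")
    _write_bytes(os.path.join(dir_path, "matrix.mtx" + suffix), head + b"\n" + rest,
                 gzip_files)

    feats = "".join(f"{g}\t{g}\tGene Expression\n" for g in cm.genes).encode()
    _write_bytes(os.path.join(dir_path, "features.tsv" + suffix), feats, gzip_files)
    bcs = "".join(b + "\n" for b in cm.barcodes).encode()
    _write_bytes(os.path.join(dir_path, "barcodes.tsv" + suffix), bcs, gzip_files)


def _write_bytes(path: str, payload: bytes, gz: bool) -> None:
    if gz:
        # mtime=0 keeps output byte-identical across runs
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


def read_marker_matrix(path: str) -> MarkerMatrix:
    """Read an identity/gene[/weight] TSV into a :class:`MarkerMatrix`.

    Duplicate (identity, gene) rows collapse to the maximum weight.
    """
    df = pd.read_csv(path, sep="\t", dtype={"identity": str, "gene": str})
    missing = {"identity", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"marker matrix {path} missing columns: {sorted(missing)}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    markers: dict[str, dict[str, float]] = {}
    identities: list[str] = []
    for _, row in df.iterrows():
        ident, gene, w = row["identity"], row["gene"], float(row["weight"])
        if not isinstance(ident, str) or not ident:
            raise ValueError(f"empty identity in marker matrix {path}")
        if ident not in markers:
            markers[ident] = {}
            identities.append(ident)
        prev = markers[ident].get(gene)
        markers[ident][gene] = w if prev is None else max(prev, w)
    return MarkerMatrix(markers, identities)


def write_marker_matrix(mm: MarkerMatrix, path: str) -> None:
    rows = [
        {"identity": ident, "gene": g, "weight": w}
        for ident in mm.identities
        for g, w in sorted(mm.markers[ident].items())
    ]
    pd.DataFrame(rows, columns=["identity", "gene", "weight"]).to_csv(path, sep="\t", index=False)


def read_merge_map(path: str) -> MergeMap:
    """Read a fine_label/combined_label TSV; conflicting duplicates are errors."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"fine_label", "combined_label"} - set(df.columns)
    if missing:
        raise ValueError(f"merge map {path} missing columns: {sorted(missing)}")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        fine, combined = row["fine_label"], row["combined_label"]
        if fine in mapping and mapping[fine] != combined:
            raise ValueError(
                f"conflicting merge-map entries for {fine!r}: "
                f"{mapping[fine]!r} vs {combined!r}"
            )
        mapping[fine] = combined
    return MergeMap(mapping)


def write_merge_map(mm: MergeMap, path: str) -> None:
    rows = [{"fine_label": k, "combined_label": v} for k, v in mm.mapping.items()]
    pd.DataFrame(rows, columns=["fine_label", "combined_label"]).to_csv(path, sep="\t", index=False)
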