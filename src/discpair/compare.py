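"""Joint cells+nuclei analysis and cross-modality comparison statistics.

Integration here is deliberately simple and fully specified: both
datasets are restricted to the union of their top variable genes
(intersected with the shared gene universe), each gene is centered and
unit-scaled within its own dataset to absorb modality shift, and the
concatenated barcodes are embedded and clustered with the standard graph
pipeline. The comparison statistics quantify how the two modalities
relate: per-cluster contribution proportions corrected for unequal
filtered dataset sizes, the variable-gene Venn partition, per-cell-type
overlap of differentially expressed genes, and barcode-tracked label
transitions between the individual and the joint analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cluster import (DEFAULT_KNN, DEFAULT_PCS, DEFAULT_RESOLUTION,
                      PCAEmbedder, SNNLouvainClusterer)
from .annotate import assign_identities, merge_labels, score_clusters
from .markers import find_markers
from .normalize import NormMatrix, select_hvg
from .tenx_io import MarkerMatrix, MergeMap

logger = logging.getLogger(__name__)

__all__ = ["JointAssignment", "VennCounts", "integrate", "contribution", "venn_counts",
           "de_overlap", "transitions", "relabel_marker_table", "sequencing_run_summary"]


@dataclass
class JointAssignment:
    """Per-barcode joint cluster and combined label for both datasets."""

    table: pd.DataFrame  # columns: dataset, barcode, joint_cluster, joint_label
    scores: pd.DataFrame | None = None
    markers: pd.DataFrame | None = None
    resolution: float = field(default=DEFAULT_RESOLUTION)
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"dataset", "barcode", "joint_cluster", "joint_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"joint table missing columns: {sorted(missing)}")
        dup = self.table.duplicated(subset=["dataset", "barcode"])
        if dup.any():
            bad = self.table.loc[dup.idxmax()]
            raise ValueError(f"duplicate barcode within dataset: {bad['barcode']!r}")

    def subset(self, dataset: str) -> pd.DataFrame:
        return self.table[self.table["dataset"] == dataset]


class VennCounts(NamedTuple):
    unique_a: int
    shared: int
    unique_b: int


def integrate(nmA: NormMatrix, nmB: NormMatrix, hvg_features: int = 3000,
              n_pcs: int = DEFAULT_PCS, knn: int = DEFAULT_KNN,
              resolution: float = DEFAULT_RESOLUTION, seed: int = 0,
              marker_matrix: MarkerMatrix | None = None,
              merge_map: MergeMap | None = None) -> JointAssignment:
    """Jointly embed, cluster and (optionally) annotate two normalized datasets.

    Features are the union of each dataset's top ``hvg_features`` variable
    genes intersected with the shared gene universe; each feature is
    z-scored within its dataset before the joint embedding. When a marker
    matrix is given, joint clusters are annotated from a joint one-vs-rest
    marker table; a merge map (extended with identity mappings for labels
    it does not cover) collapses fine labels into combined cell types.
    """
    shared = [g for g in nmA.genes if g in set(nmB.genes)]
    if not shared:
        raise ValueError("shared-gene intersection is empty")
    shared_set = set(shared)
    hvgA = set(select_hvg(nmA, hvg_features).index)
    hvgB = set(select_hvg(nmB, hvg_features).index)
    features = [g for g in shared if g in hvgA or g in hvgB]
    if not features:
        raise ValueError("no shared variable genes to integrate on")

    blocks = []
    for nm in (nmA, nmB):
        X = nm.subset_genes(features).dense().T  # barcodes x features
        mu = X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        blocks.append((X - mu) / sd)
    joint = np.vstack(blocks)

    coords, _ = PCAEmbedder(n_components=min(n_pcs, joint.shape[1])).fit_transform(joint)
    labels = SNNLouvainClusterer(knn=knn, resolution=resolution,
                                          seed=seed).fit_predict(coords)

    datasets = [nmA.modality] * len(nmA.barcodes) + [nmB.modality] * len(nmB.barcodes)
    if nmA.modality == nmB.modality:
        datasets = (["A"] * len(nmA.barcodes)) + (["B"] * len(nmB.barcodes))
    table = pd.DataFrame({
        "dataset": datasets,
        "barcode": list(nmA.barcodes) + list(nmB.barcodes),
        "joint_cluster": labels,
        "joint_label": [str(c) for c in labels],
    })

    scores = markers_table = None
    if marker_matrix is not None:
        jnm = _concat_norm(nmA, nmB, shared)
        markers_table = find_markers(jnm, labels)
        scores = score_clusters(markers_table, marker_matrix, gene_universe=shared_set)
        annotation = assign_identities(scores)
        if merge_map is not None:
            observed = set(annotation.labels.values())
            uncovered = sorted(lab for lab in observed if lab not in merge_map)
            if uncovered:
                logger.info("merge map extended with identity mappings for %s", uncovered)
            annotation = merge_labels(annotation, merge_map.extended(observed))
        lab_map = annotation.labels
        table["joint_label"] = [lab_map[c] for c in labels]

    return JointAssignment(table, scores, markers_table, resolution, seed)


def _concat_norm(nmA: NormMatrix, nmB: NormMatrix, genes: list[str]) -> NormMatrix:
    import scipy.sparse as sp

    a = nmA.subset_genes(genes)
    b = nmB.subset_genes(genes)
    values = sp.hstack([a.values, b.values]).tocsr()
    barcodes = [f"{nmA.modality}:{bc}" for bc in a.barcodes] + [
        f"{nmB.modality}:{bc}" for bc in b.barcodes
    ]
    return NormMatrix(values, genes, barcodes,
                      np.concatenate([a.size_factors, b.size_factors]), nmA.modality)


def contribution(ja: JointAssignment | pd.DataFrame, n_filtered_A: int,
                 n_filtered_B: int) -> pd.DataFrame:
    """Corrected per-label contribution proportions of the two datasets.

    The correction factor r = n_filtered_B / n_filtered_A rescales dataset
    A's raw count so that equal *rates* of contribution give equal shares
    regardless of dataset size: share_A = count_A * r / (count_A * r +
    count_B). Shares are percentages and sum to 100 per label.
    """
    if n_filtered_A <= 0 or n_filtered_B <= 0:
        raise ValueError("filtered dataset sizes must be positive")
    table = ja.table if isinstance(ja, JointAssignment) else ja
    datasets = list(pd.unique(table["dataset"]))
    if len(datasets) != 2:
        raise ValueError(f"expected exactly 2 datasets, got {datasets}")
    dsA, dsB = datasets
    r = n_filtered_B / n_filtered_A
    rows = []
    for label, sub in table.groupby("joint_label"):
        count_a = int((sub["dataset"] == dsA).sum())
        count_b = int((sub["dataset"] == dsB).sum())
        if count_a + count_b == 0:
            continue
        denom = count_a * r + count_b
        share_a = 100.0 * count_a * r / denom
        rows.append({
            "joint_label": label,
            f"count_{dsA}": count_a,
            f"count_{dsB}": count_b,
            f"corrected_pct_{dsA}": share_a,
            f"corrected_pct_{dsB}": 100.0 - share_a,
        })
    out = pd.DataFrame(rows).set_index("joint_label")
    out.attrs["correction_factor"] = r
    return out


def venn_counts(listA, listB) -> VennCounts:
    """Partition counts (unique to A, shared, unique to B) of two gene sets."""
    a, b = set(listA), set(listB)
    shared = len(a & b)
    return VennCounts(len(a) - shared, shared, len(b) - shared)


def relabel_marker_table(mt: pd.DataFrame, labels) -> pd.DataFrame:
    """Replace cluster ids by (merged) labels so DE sets can be pooled per cell type."""
    lab = dict(labels)
    missing = sorted(set(mt["cluster"]) - set(lab))
    if missing:
        raise KeyError(f"clusters without labels: {missing}")
    out = mt.copy()
    out["cluster"] = [lab[c] for c in mt["cluster"]]
    return out


def de_overlap(mtA: pd.DataFrame, mtB: pd.DataFrame, label: str):
    """Percent unique-to-A / unique-to-B / shared DE genes for one cell type.

    Marker tables must carry cell-type labels in their ``cluster`` column
    (see :func:`relabel_marker_table`); significant rows for ``label`` are
    pooled per table and compared on the union. Returns
    (pct_unique_A, pct_unique_B, pct_shared, total) or None if the union
    is empty.
    """
    for mt, name in ((mtA, "A"), (mtB, "B")):
        if label not in set(mt["cluster"]):
            raise KeyError(f"label {label!r} absent from marker table {name}")
    setA = set(mtA[(mtA["cluster"] == label) & mtA["significant"]]["gene"])
    setB = set(mtB[(mtB["cluster"] == label) & mtB["significant"]]["gene"])
    union = setA | setB
    total = len(union)
    if total == 0:
        return None
    shared = len(setA & setB)
    pct_unique_a = 100.0 * len(setA - setB) / total
    pct_unique_b = 100.0 * len(setB - setA) / total
    pct_shared = 100.0 * shared / total
    return (pct_unique_a, pct_unique_b, pct_shared, total)


def transitions(individual_labels: pd.Series, ja: JointAssignment,
                dataset: str) -> pd.DataFrame:
    """Source-label x joint-label barcode count matrix for one dataset.

    ``individual_labels`` maps barcode -> label from the individually
    analyzed dataset. Every individual barcode must be present in the
    joint assignment (identity tracking would otherwise be broken).
    """
    sub = ja.subset(dataset).set_index("barcode")["joint_label"]
    missing = [bc for bc in individual_labels.index if bc not in sub.index]
    if missing:
        raise ValueError(f"barcodes missing from joint assignment: {missing[:5]}")
    df = pd.DataFrame({
        "source_label": individual_labels,
        "joint_label": sub.reindex(individual_labels.index),
    })
    mat = df.groupby(["source_label", "joint_label"]).size().unstack(fill_value=0)
    return mat


def transitions_long(mat: pd.DataFrame) -> pd.DataFrame:
    """Long-form (source_label, joint_label, count) table for alluvial plotting."""
    long = mat.stack().rename("count").reset_index()
    return long[long["count"] > 0].reset_index(drop=True)


def sequencing_run_summary(n_barcodes: int, n_discs: int, total_reads: int,
                           expected_cells_per_disc: int = 44000) -> dict:
    """Derived per-run summary metrics at the precision summary tables print.

    * barcodes per disc, rounded to the nearest whole cell;
    * percent of the expected cells per disc, truncated to one decimal
      (computed on the unrounded per-disc yield);
    * mean reads per barcode as integer division, matching how sequencing
      summary tables truncate this metric.
    """
    per_disc = n_barcodes / n_discs
    pct = 100.0 * per_disc / expected_cells_per_disc
    return {
        "barcodes_per_disc": int(math.floor(per_disc + 0.5)),
        "pct_of_expected": math.floor(pct * 10 + 1e-9) / 10.0,
        "mean_reads_per_barcode": total_reads // n_barcodes,
    }
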