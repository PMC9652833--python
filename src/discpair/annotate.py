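"""Marker-matrix cluster annotation with dual-identity and "Other" tie rules.

Each cluster is scored against every candidate identity: the score is the
(weighted) count of that identity's reference markers among the cluster's
significantly overexpressed genes. A cluster is labelled with the highest
scoring identity; when exactly two identities tie for the top score the
cluster gets the dual label "A|B" (alphabetical); with three or more tied
identities, or no marker evidence at all, it is labelled "Other". Fine
labels can then be merged into combined cell types via a merge map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import significant_sets
from .tenx_io import MarkerMatrix, MergeMap

__all__ = ["ScoreHeatmap", "AnnotationResult", "score_clusters", "assign_identities",
           "merge_labels", "MarkerScoreAnnotator", "OTHER_LABEL"]

logger = logging.getLogger(__name__)

OTHER_LABEL = "Other"
TIE_TOL = 1e-9


@dataclass
class AnnotationResult:
    """Cluster labels plus the full score heatmap and per-cluster runner-ups."""

    labels: dict[int, str]
    scores: pd.DataFrame  # identity x cluster
    runners_up: dict[int, list[str]] = field(default_factory=dict)

    def merged(self, mm: MergeMap) -> "AnnotationResult":
        return merge_labels(self, mm)

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, name="label").sort_index()


def score_clusters(mt: pd.DataFrame, mm: MarkerMatrix,
                   gene_universe: set[str] | None = None,
                   normalize_by_size: bool = False) -> pd.DataFrame:
    """Identity x cluster score heatmap.

    score(identity, cluster) = sum of weights of the identity's markers
    found in the cluster's significant gene set. With unit weights this is
    a plain marker count. Markers absent from ``gene_universe`` (when
    given) are noted in the log and contribute nothing. With
    ``normalize_by_size`` scores are divided by each identity's marker
    count, trading raw evidence for comparability across identities.
    """
    sig = significant_sets(mt)
    clusters = sorted(pd.unique(mt["cluster"]))
    if gene_universe is not None:
        for ident in mm.identities:
            absent = sorted(set(mm.markers[ident]) - gene_universe)
            if absent:
                logger.info("markers absent from gene universe for %s: %s", ident, absent)
    heat = pd.DataFrame(0.0, index=list(mm.identities), columns=clusters)
    for c in clusters:
        genes = sig.get(c, set())
        for ident in mm.identities:
            heat.loc[ident, c] = sum(
                w for g, w in mm.markers[ident].items() if g in genes
            )
    if normalize_by_size:
        sizes = np.array([len(mm.markers[i]) for i in mm.identities], dtype=float)
        heat = heat.div(sizes, axis=0)
    return heat


def assign_identities(sh: pd.DataFrame, tie_tol: float = TIE_TOL) -> AnnotationResult:
    """Label clusters from a score heatmap using the max-score tie rules."""
    labels: dict[int, str] = {}
    runners: dict[int, list[str]] = {}
    for c in sh.columns:
        col = sh[c]
        order = sorted(col.index, key=lambda i: (-col[i], i))
        runners[c] = order
        top = float(col.max())
        if top <= 0:
            labels[c] = OTHER_LABEL
            continue
        tied = sorted(i for i in col.index if abs(float(col[i]) - top) <= tie_tol)
        if len(tied) == 1:
            labels[c] = tied[0]
        elif len(tied) == 2:
            labels[c] = "|".join(tied)
        else:
            labels[c] = OTHER_LABEL
    return AnnotationResult(labels, sh.copy(), runners)


def merge_labels(ar: AnnotationResult, mm: MergeMap) -> AnnotationResult:
    """Replace fine labels by combined labels; unmapped labels are hard errors."""
    unmapped = sorted({lab for lab in ar.labels.values() if lab not in mm})
    if unmapped:
        raise KeyError(f"labels missing from merge map: {unmapped}")
    merged = {c: mm[lab] for c, lab in ar.labels.items()}
    return AnnotationResult(merged, ar.scores.copy(), dict(ar.runners_up))


class MarkerScoreAnnotator:
    """Score-and-assign annotation as one estimator.

    ``fit(marker_table)`` computes ``scores_``, ``labels_`` and, when a
    merge map is supplied, ``merged_labels_``.
    """

    def __init__(self, marker_matrix: MarkerMatrix, merge_map: MergeMap | None = None,
                 normalize_by_size: bool = False):
        self.marker_matrix = marker_matrix
        self.merge_map = merge_map
        self.normalize_by_size = normalize_by_size

    def get_params(self, deep: bool = True) -> dict:
        return {"marker_matrix": self.marker_matrix, "merge_map": self.merge_map,
                "normalize_by_size": self.normalize_by_size}

    def set_params(self, **params) -> "MarkerScoreAnnotator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, marker_table: pd.DataFrame,
            gene_universe: set[str] | None = None) -> "MarkerScoreAnnotator":
        self.scores_ = score_clusters(marker_table, self.marker_matrix, gene_universe,
                                      self.normalize_by_size)
        self.annotation_ = assign_identities(self.scores_)
        self.labels_ = dict(self.annotation_.labels)
        if self.merge_map is not None:
            self.merged_ = merge_labels(self.annotation_, self.merge_map)
            self.merged_labels_ = dict(self.merged_.labels)
        return self
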