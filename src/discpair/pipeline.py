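"""Config-driven orchestration of the full paired cells/nuclei analysis.

One YAML config drives simulate -> QC -> normalize -> HVG -> embed ->
cluster -> markers -> annotate per modality, then the joint integration
and every comparison statistic. All stage parameters carry defaults
(the QC thresholds, marker cutoffs and feature counts of the standard
workflow); unknown keys are rejected. Randomness flows from one root
seed, split deterministically per stage. Outputs are plain TSV/JSON and
are byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import compare as C
from . import qc as Q
from .annotate import MarkerScoreAnnotator
from .cluster import cluster as run_cluster
from .cluster import embed
from .markers import find_markers, top_n
from .normalize import normalize, select_hvg
from .synthetic import SimParams, generate_pair, summarize_truth, truth_marker_matrix
from .tenx_io import (MergeMap, read_10x, read_marker_matrix, read_merge_map,
                      write_10x, write_marker_matrix, write_merge_map)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]

FLOAT_FORMAT = "%.10g"

_QC_DEFAULTS = {
    "min_genes": 300,
    "max_genes_cells": 3000,
    "nuclei_top_percentile": 99.0,
    "max_pct_mito": 10.0,
    "min_barcodes_per_gene_cells": 5,
    "min_barcodes_per_gene_nuclei": 3,
}
_HVG_DEFAULTS = {"n_top": 3000, "n_bins": 20}
_CLUSTER_DEFAULTS = {"n_pcs": 30, "knn": 20, "resolution": 1.0}
_MARKER_DEFAULTS = {"min_pct": 0.10, "log2fc_threshold": 0.25, "alpha": 0.05, "top_n": 4}
_INTEGRATION_DEFAULTS = {"hvg_features": 3000}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    mode: str = "simulate"
    sim: SimParams = field(default_factory=SimParams)
    cells_dir: str | None = None
    nuclei_dir: str | None = None
    marker_matrix: str | None = None
    merge_map: str | None = None
    qc: dict = field(default_factory=lambda: dict(_QC_DEFAULTS))
    hvg: dict = field(default_factory=lambda: dict(_HVG_DEFAULTS))
    cluster: dict = field(default_factory=lambda: dict(_CLUSTER_DEFAULTS))
    markers: dict = field(default_factory=lambda: dict(_MARKER_DEFAULTS))
    integration: dict = field(default_factory=lambda: dict(_INTEGRATION_DEFAULTS))
    seed: int = 0
    out_dir: str = "discpair_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["sim"]["identities"] = list(self.sim.identities)
        return d


def _merge_section(name: str, defaults: dict, given: dict | None) -> dict:
    out = dict(defaults)
    if given is None:
        return out
    if not isinstance(given, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    unknown = sorted(set(given) - set(defaults))
    if unknown:
        raise ValueError(f"unknown key in config section {name!r}: {unknown[0]!r}")
    for k, v in given.items():
        expected = type(defaults[k])
        if expected in (int, float):
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise ValueError(f"config {name}.{k} must be numeric, got {v!r}")
            v = expected(v)
        out[k] = v
    return out


def validate_config(cfg: dict | None) -> PipelineConfig:
    """Normalize a raw config mapping: fill defaults, reject unknown keys."""
    cfg = dict(cfg or {})
    known = {"mode", "sim", "cells_dir", "nuclei_dir", "marker_matrix", "merge_map",
             "qc", "hvg", "cluster", "markers", "integration", "seed", "out_dir"}
    unknown = sorted(set(cfg) - known)
    if unknown:
        raise ValueError(f"unknown config key: {unknown[0]!r}")
    mode = cfg.get("mode", "simulate")
    if mode not in ("simulate", "matrices"):
        raise ValueError(f"mode must be 'simulate' or 'matrices', got {mode!r}")
    seed = cfg.get("seed", 0)
    if isinstance(seed, bool) or not isinstance(seed, int):
        raise ValueError(f"seed must be an integer, got {seed!r}")

    sim_cfg = cfg.get("sim") or {}
    if not isinstance(sim_cfg, dict):
        raise ValueError("config section 'sim' must be a mapping")
    sim_cfg = dict(sim_cfg)  # never mutate the caller's mapping
    sim_fields = {f.name for f in dataclasses.fields(SimParams)}
    unknown = sorted(set(sim_cfg) - sim_fields)
    if unknown:
        raise ValueError(f"unknown key in config section 'sim': {unknown[0]!r}")
    sim_cfg.setdefault("seed", seed)
    if "identities" in sim_cfg and sim_cfg["identities"] is not None:
        sim_cfg["identities"] = tuple(sim_cfg["identities"])
    sim = SimParams(**sim_cfg)

    qc = _merge_section("qc", _QC_DEFAULTS, cfg.get("qc"))
    hvg = _merge_section("hvg", _HVG_DEFAULTS, cfg.get("hvg"))
    clu = _merge_section("cluster", _CLUSTER_DEFAULTS, cfg.get("cluster"))
    mk = _merge_section("markers", _MARKER_DEFAULTS, cfg.get("markers"))
    integ = _merge_section("integration", _INTEGRATION_DEFAULTS, cfg.get("integration"))

    if hvg["n_top"] < 1:
        raise ValueError("hvg.n_top must be >= 1")
    if qc["min_genes"] < 0 or qc["max_genes_cells"] <= qc["min_genes"]:
        raise ValueError("qc gene bounds must satisfy 0 <= min_genes < max_genes_cells")
    if not 0 < qc["nuclei_top_percentile"] <= 100:
        raise ValueError("qc.nuclei_top_percentile must be in (0, 100]")
    if clu["resolution"] <= 0 or clu["knn"] < 1 or clu["n_pcs"] < 2:
        raise ValueError("cluster parameters out of range")
    if not 0 <= mk["min_pct"] <= 1 or not 0 < mk["alpha"] < 1:
        raise ValueError("marker parameters out of range")
    if integ["hvg_features"] < 1:
        raise ValueError("integration.hvg_features must be >= 1")

    if mode == "matrices":
        for key in ("cells_dir", "nuclei_dir"):
            if not cfg.get(key):
                raise ValueError(f"mode 'matrices' requires {key}")
        if not cfg.get("marker_matrix"):
            raise ValueError("mode 'matrices' requires marker_matrix")

    return PipelineConfig(
        mode=mode, sim=sim,
        cells_dir=cfg.get("cells_dir"), nuclei_dir=cfg.get("nuclei_dir"),
        marker_matrix=cfg.get("marker_matrix"), merge_map=cfg.get("merge_map"),
        qc=qc, hvg=hvg, cluster=clu, markers=mk, integration=integ,
        seed=seed, out_dir=cfg.get("out_dir", "discpair_out"),
    )


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def stage_seed(root: int, name: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    return (int(root) ^ zlib.crc32(name.encode())) & 0x7FFFFFFF


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full paired analysis; returns the run manifest (also written).

    Any stage failure aborts with :class:`PipelineError` carrying the
    stage name; the partial manifest is preserved on disk.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }
    current_stage = "setup"

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    def save(df: pd.DataFrame, name: str, index: bool = True) -> str:
        path = os.path.join(out, name)
        _write_tsv(df, path, index=index)
        manifest["outputs"][name] = _sha256(path)
        return path

    try:
        current_stage = "inputs"
        if cfg.mode == "simulate":
            cells, nuclei, truth = generate_pair(
                dataclasses.replace(cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
            )
            marker_matrix = (
                read_marker_matrix(cfg.marker_matrix)
                if cfg.marker_matrix
                else truth_marker_matrix(truth)
            )
            merge_map = (
                read_merge_map(cfg.merge_map)
                if cfg.merge_map
                else MergeMap({i: i for i in truth.params.identities})
            )
            save(truth.barcodes, "truth_barcodes.tsv", index=False)
            save(summarize_truth(truth)["barcodes"], "truth_summary.tsv", index=False)
        else:
            cells = read_10x(cfg.cells_dir, "cells")
            nuclei = read_10x(cfg.nuclei_dir, "nuclei")
            truth = None
            marker_matrix = read_marker_matrix(cfg.marker_matrix)
            merge_map = read_merge_map(cfg.merge_map) if cfg.merge_map else MergeMap({})
        record("inputs", cells_barcodes=cells.n_barcodes, nuclei_barcodes=nuclei.n_barcodes,
               genes=cells.n_genes)

        per_modality: dict[str, dict] = {}
        for cm in (cells, nuclei):
            mod = cm.modality
            current_stage = f"qc:{mod}"
            qct = Q.compute_qc(cm)
            bf = Q.BarcodeFilter(
                modality=mod, min_genes=cfg.qc["min_genes"],
                max_genes=cfg.qc["max_genes_cells"], max_pct_mito=cfg.qc["max_pct_mito"],
                top_percentile=cfg.qc["nuclei_top_percentile"],
            )
            qct = bf.fit_transform(qct)
            save(qct, f"qc_{mod}.tsv")
            filt = Q.apply_barcode_filter(cm, qct)
            min_support = cfg.qc[f"min_barcodes_per_gene_{mod}"]
            genes_in = filt.n_genes
            filt = Q.filter_genes(filt, mod, min_support)
            record(f"qc:{mod}", barcodes_in=cm.n_barcodes, barcodes_out=filt.n_barcodes,
                   genes_in=genes_in, genes_out=filt.n_genes)

            current_stage = f"normalize:{mod}"
            nm = normalize(filt)
            current_stage = f"hvg:{mod}"
            hvg = select_hvg(nm, cfg.hvg["n_top"])
            save(hvg.rename("score").rename_axis("gene").reset_index(), f"hvg_{mod}.tsv",
                 index=False)

            current_stage = f"cluster:{mod}"
            emb = embed(nm, hvg, cfg.cluster["n_pcs"])
            ca = run_cluster(emb, cfg.cluster["knn"], cfg.cluster["resolution"],
                             stage_seed(cfg.seed, f"cluster:{mod}"))
            save(ca.as_series().rename_axis("barcode").reset_index(), f"clusters_{mod}.tsv",
                 index=False)
            record(f"cluster:{mod}", n_clusters=ca.n_clusters)

            current_stage = f"markers:{mod}"
            mt = find_markers(nm, ca, cfg.markers["min_pct"])
            save(mt, f"markers_{mod}.tsv", index=False)
            tops = top_n(mt, cfg.markers["top_n"])
            save(pd.DataFrame(
                [(c, i + 1, g) for c, gs in tops.items() for i, g in enumerate(gs)],
                columns=["cluster", "rank", "gene"],
            ), f"top_markers_{mod}.tsv", index=False)

            current_stage = f"annotate:{mod}"
            ann = MarkerScoreAnnotator(marker_matrix).fit(mt, gene_universe=set(nm.genes))
            observed = set(ann.annotation_.labels.values())
            extended = merge_map.extended(observed)
            added = sorted(set(extended.mapping) - set(merge_map.mapping))
            if added:
                record(f"annotate:{mod}", merge_map_extended_with=added)
            merged = ann.annotation_.merged(extended)
            save(ann.scores_.rename_axis("identity"), f"scores_{mod}.tsv")
            save(pd.DataFrame({
                "cluster": sorted(ann.labels_),
                "label": [ann.labels_[c] for c in sorted(ann.labels_)],
                "combined_label": [merged.labels[c] for c in sorted(ann.labels_)],
            }), f"annotation_{mod}.tsv", index=False)

            per_modality[mod] = {"filtered": filt, "norm": nm, "clusters": ca,
                                 "markers": mt, "annotation": ann.annotation_,
                                 "merged": merged}

        current_stage = "integrate"
        ja = C.integrate(
            per_modality["cells"]["norm"], per_modality["nuclei"]["norm"],
            hvg_features=cfg.integration["hvg_features"], n_pcs=cfg.cluster["n_pcs"],
            knn=cfg.cluster["knn"], resolution=cfg.cluster["resolution"],
            seed=stage_seed(cfg.seed, "integrate"),
            marker_matrix=marker_matrix, merge_map=merge_map,
        )
        save(ja.table, "joint_assignment.tsv", index=False)
        if ja.scores is not None:
            save(ja.scores.rename_axis("identity"), "scores_joint.tsv")

        current_stage = "compare"
        nA = per_modality["cells"]["filtered"].n_barcodes
        nB = per_modality["nuclei"]["filtered"].n_barcodes
        contrib = C.contribution(ja, nA, nB)
        save(contrib, "contribution.tsv")

        hvg_sets = {m: set(pd.read_csv(os.path.join(out, f"hvg_{m}.tsv"), sep="\t")["gene"])
                    for m in ("cells", "nuclei")}
        venn = C.venn_counts(hvg_sets["cells"], hvg_sets["nuclei"])
        save(pd.DataFrame([venn._asdict()]), "venn.tsv", index=False)

        relabeled = {
            m: C.relabel_marker_table(per_modality[m]["markers"],
                                      per_modality[m]["merged"].labels)
            for m in ("cells", "nuclei")
        }
        shared_labels = sorted(
            set(relabeled["cells"]["cluster"]) & set(relabeled["nuclei"]["cluster"])
        )
        de_rows = []
        for lab in shared_labels:
            res = C.de_overlap(relabeled["cells"], relabeled["nuclei"], lab)
            if res is None:
                continue
            pa, pb, ps, tot = res
            de_rows.append({"label": lab, "pct_unique_cells": pa, "pct_unique_nuclei": pb,
                            "pct_shared": ps, "total_genes": tot})
        save(pd.DataFrame(de_rows), "de_overlap.tsv", index=False)

        trans_tables = {}
        for mod in ("cells", "nuclei"):
            ind = per_modality[mod]["merged"].labels
            bc_labels = pd.Series(
                [ind[c] for c in per_modality[mod]["clusters"].labels],
                index=per_modality[mod]["clusters"].barcodes, name="label",
            )
            mat = C.transitions(bc_labels, ja, mod)
            trans_tables[mod] = mat
            save(C.transitions_long(mat), f"transitions_{mod}.tsv", index=False)

        record("compare", correction_factor=contrib.attrs["correction_factor"],
               n_filtered_cells=nA, n_filtered_nuclei=nB,
               joint_clusters=int(ja.table["joint_cluster"].max()) + 1)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineError(current_stage, manifest, exc) from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def simulate_to_dir(params: SimParams, out_dir: str) -> None:
    """Write the synthetic pair as two 10x triplets plus truth tables."""
    cells, nuclei, truth = generate_pair(params)
    write_10x(cells, os.path.join(out_dir, "cells"))
    write_10x(nuclei, os.path.join(out_dir, "nuclei"))
    truth.barcodes.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    truth.gene_classes.rename_axis("gene").reset_index().to_csv(
        os.path.join(out_dir, "gene_classes.tsv"), sep="\t", index=False
    )
    write_marker_matrix(truth_marker_matrix(truth), os.path.join(out_dir, "marker_matrix.tsv"))
    write_merge_map(MergeMap({i: i for i in params.identities}),
                    os.path.join(out_dir, "merge_map.tsv"))
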