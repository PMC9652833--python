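import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from discpair import qc as Q
from discpair.annotate import MarkerScoreAnnotator
from discpair.cluster import cluster as run_cluster
from discpair.cluster import embed
from discpair.compare import integrate
from discpair.markers import find_markers
from discpair.normalize import normalize, select_hvg
from discpair.synthetic import SimParams, generate_pair, truth_marker_matrix
from discpair.tenx_io import CountMatrix, MergeMap

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_count_matrix(counts, genes=None, barcodes=None, modality="cells"):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"bc{i}" for i in range(counts.shape[1])]
    return CountMatrix(counts, genes, barcodes, modality)


@pytest.fixture(scope="session")
def small_pair():
    """Quick planted pair: 5 types x 80 barcodes per modality."""
    params = SimParams(n_types=5, cells_per_type=80, seed=11)
    cells, nuclei, truth = generate_pair(params)
    return cells, nuclei, truth


def _process(cm, truth, seed):
    qct = Q.filter_barcodes(Q.compute_qc(cm), cm.modality)
    filt = Q.filter_genes(Q.apply_barcode_filter(cm, qct), cm.modality)
    nm = normalize(filt)
    hvg = select_hvg(nm, 3000)
    emb = embed(nm, hvg, 30)
    ca = run_cluster(emb, 20, 1.0, seed=seed)
    mt = find_markers(nm, ca)
    return {"qc": qct, "filtered": filt, "norm": nm, "hvg": hvg, "embedding": emb,
            "clusters": ca, "markers": mt}


@pytest.fixture(scope="session")
def default_run():
    """Full-scale planted run (11 types x 200 per modality) through the whole
    per-modality pipeline plus joint integration; shared across tests because
    it is the expensive fixture."""
    params = SimParams(seed=5)
    cells, nuclei, truth = generate_pair(params)
    mm = truth_marker_matrix(truth)
    merge_map = MergeMap({i: i for i in params.identities})
    out = {"params": params, "truth": mm and truth, "marker_matrix": mm,
           "merge_map": merge_map}
    for cm in (cells, nuclei):
        mod = cm.modality
        res = _process(cm, truth, seed=5)
        ann = MarkerScoreAnnotator(mm).fit(res["markers"],
                                           gene_universe=set(res["norm"].genes))
        extended = merge_map.extended(set(ann.annotation_.labels.values()))
        res["annotation"] = ann.annotation_
        res["merged"] = ann.annotation_.merged(extended)
        res["raw"] = cm
        out[mod] = res
    out["joint"] = integrate(
        out["cells"]["norm"], out["nuclei"]["norm"],
        seed=5, marker_matrix=mm, merge_map=merge_map,
    )
    return out


def majority_truth_label(run, modality):
    """Cluster -> majority planted identity among its singlet barcodes."""
    truth = run["truth"].labels(modality)
    ca = run[modality]["clusters"]
    lab = truth.reindex(ca.barcodes)
    singlet = ~(lab.str.startswith("doublet:") | (lab == "lowq"))
    out = {}
    for c in range(ca.n_clusters):
        sub = lab[(ca.labels == c) & singlet.to_numpy()]
        if len(sub):
            out[c] = sub.mode().iloc[0]
    return out
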