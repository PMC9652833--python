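"""Synthetic paired cells/nuclei UMI count generator with planted ground truth.

Emulates the modality contrasts seen when the same tissue is profiled by
droplet scRNA-seq (dissociated cells) and snRNA-seq (isolated nuclei):

* cells carry an elevated ribosomal read fraction, a heat-shock (stress)
  read burden from harsh dissociation, and a sizeable subset of barcodes
  whose mitochondrial read fraction exceeds 10% (dying/damaged cells);
* nuclei carry almost no mitochondrial excess, a ~28% lower ribosomal
  fraction, and detect more genes per barcode (flatter expression
  profile, standing in for nascent-transcript capture);
* both share one gene universe and one set of planted cell identities,
  each with exclusive marker genes, plus doublets and low-quality
  barcodes.

Counts are drawn per barcode as a multinomial over a type-specific
probability vector (Dirichlet-perturbed per barcode) with depth drawn
from a negative binomial around ``base_depth``. Gene symbols follow the
Drosophila prefix conventions used for QC gene classes: mitochondrial
genes are prefixed ``mt:``, ribosomal proteins ``RpS``/``RpL`` and heat
shock proteins ``Hsp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tenx_io import CountMatrix, MarkerMatrix

__all__ = ["SimParams", "SyntheticTruth", "generate_pair", "summarize_truth", "truth_marker_matrix"]

DEFAULT_IDENTITIES = (
    "Antenna",
    "EAB",
    "PhR",
    "MFurrow",
    "SMW",
    "PPN",
    "Interom",
    "Ventral PE",
    "Dorsal|Ocelli",
    "Hemocytes",
    "Other-background",
)

_MITO_GENES = (
    "mt:CoI", "mt:CoII", "mt:CoIII", "mt:ATPase6",
    "mt:Cyt-b", "mt:ND1", "mt:ND4", "mt:ND5",
)
_HSP_GENES = ("Hsp22", "Hsp23", "Hsp26", "Hsp27", "Hsp60", "Hsp68", "Hsp70", "Hsp83")


@dataclass
class SimParams:
    """Generator parameters; defaults are the study conditions the pipeline targets."""

    n_types: int = 11
    cells_per_type: int = 200
    n_marker_genes_per_type: int = 6
    n_background_genes: int = 1000
    marker_fold: float = 10.0
    base_depth: float = 3000.0
    depth_dispersion: float = 10.0
    min_singlet_depth: int = 2000
    mito_fail_fraction_cells: float = 0.14
    mito_fail_fraction_nuclei: float = 0.0002
    mito_baseline_cells: float = 0.02
    mito_baseline_nuclei: float = 0.002
    ribo_fraction_cells: float = 0.20
    ribo_reduction_nuclei: float = 0.28
    hsp_fraction_cells: float = 0.05
    hsp_fraction_nuclei: float = 0.002
    doublet_rate: float = 0.05
    lowq_rate: float = 0.03
    # lognormal sigma of the body-gene expression profile; steeper (cells)
    # concentrates reads on fewer genes => fewer detected genes per barcode
    expression_sigma_cells: float = 0.8
    expression_sigma_nuclei: float = 0.4
    dirichlet_concentration: float = 600.0
    seed: int = 0
    identities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if not self.marker_fold > 1:
            raise ValueError("marker_fold must be > 1")
        for name in (
            "mito_fail_fraction_cells", "mito_fail_fraction_nuclei",
            "mito_baseline_cells", "mito_baseline_nuclei",
            "ribo_fraction_cells", "ribo_reduction_nuclei",
            "hsp_fraction_cells", "hsp_fraction_nuclei",
            "doublet_rate", "lowq_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("base_depth and depth_dispersion must be positive")
        if self.cells_per_type < 1 or self.n_marker_genes_per_type < 1:
            raise ValueError("cells_per_type and n_marker_genes_per_type must be >= 1")
        if not self.identities:
            base = list(DEFAULT_IDENTITIES)
            while len(base) < self.n_types:
                base.append(f"Type{len(base) + 1}")
            self.identities = tuple(base[: self.n_types])
        elif len(self.identities) != self.n_types:
            raise ValueError("identities length must equal n_types")


@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per emitted barcode, one class per gene."""

    barcodes: pd.DataFrame  # columns: modality, barcode, label, mito_fail
    gene_classes: pd.Series  # index gene symbol -> class string
    params: SimParams = field(repr=False, default=None)

    def labels(self, modality: str) -> pd.Series:
        sub = self.barcodes[self.barcodes["modality"] == modality]
        return sub.set_index("barcode")["label"]


def _gene_universe(params: SimParams) -> tuple[list[str], pd.Series, dict[str, list[int]]]:
    genes: list[str] = []
    classes: list[str] = []
    marker_idx: dict[str, list[int]] = {}
    for t, ident in enumerate(params.identities):
        idxs = []
        for j in range(params.n_marker_genes_per_type):
            idxs.append(len(genes))
            genes.append(f"mk{t:02d}g{j + 1}")
            classes.append(f"marker:{ident}")
        marker_idx[ident] = idxs
    for j in range(params.n_background_genes):
        genes.append(f"bg{j:04d}")
        classes.append("background")
    mito = list(_MITO_GENES)
    ribo = [f"RpS{j}" for j in range(2, 17)] + [f"RpL{j}" for j in range(3, 18)]
    hsp = list(_HSP_GENES)
    for name, cls in ((mito, "mito"), (ribo, "ribo"), (hsp, "hsp")):
        for g in name:
            genes.append(g)
            classes.append(cls)
    return genes, pd.Series(classes, index=genes, name="class"), marker_idx


def _class_masks(classes: pd.Series) -> dict[str, np.ndarray]:
    vals = classes.to_numpy()
    return {
        "body": np.array([c.startswith("marker:") or c == "background" for c in vals]),
        "mito": vals == "mito",
        "ribo": vals == "ribo",
        "hsp": vals == "hsp",
    }


def _nb_depths(rng: np.random.Generator, n: int, mean: float, r: float, floor: int) -> np.ndarray:
    p = r / (r + mean)
    d = rng.negative_binomial(r, p, size=n)
    return np.maximum(d, floor)


def generate_pair(params: SimParams) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Generate paired (cells, nuclei) count matrices plus planted truth.

    Fully deterministic for a given :class:`SimParams` (including seed).
    """
    rng = np.random.default_rng(params.seed)
    genes, classes, marker_idx = _gene_universe(params)
    masks = _class_masks(classes)
    n_genes = len(genes)
    body_ix = np.flatnonzero(masks["body"])

    # within-class gene weights shared across modalities
    class_w = {
        name: rng.lognormal(0.0, 1.0, size=int(masks[name].sum()))
        for name in ("mito", "ribo", "hsp")
    }
    for name in class_w:
        class_w[name] /= class_w[name].sum()

    results = {}
    truth_rows: list[dict] = []
    for modality in ("cells", "nuclei"):
        sub_rng = np.random.default_rng([params.seed, 0 if modality == "cells" else 1])
        sigma = (
            params.expression_sigma_cells
            if modality == "cells"
            else params.expression_sigma_nuclei
        )
        base_body = sub_rng.lognormal(0.0, sigma, size=body_ix.size)
        base_body /= base_body.sum()

        type_body = {}
        for ident in params.identities:
            w = base_body.copy()
            local = [np.searchsorted(body_ix, i) for i in marker_idx[ident]]
            w[local] *= params.marker_fold
            type_body[ident] = w / w.sum()

        mito_base = (
            params.mito_baseline_cells if modality == "cells" else params.mito_baseline_nuclei
        )
        mito_fail_frac = (
            params.mito_fail_fraction_cells
            if modality == "cells"
            else params.mito_fail_fraction_nuclei
        )
        ribo_frac = params.ribo_fraction_cells
        if modality == "nuclei":
            ribo_frac *= 1.0 - params.ribo_reduction_nuclei
        hsp_frac = (
            params.hsp_fraction_cells if modality == "cells" else params.hsp_fraction_nuclei
        )

        n_singlets = params.n_types * params.cells_per_type
        n_doublets = int(sub_rng.binomial(n_singlets, params.doublet_rate))
        n_lowq = int(sub_rng.binomial(n_singlets, params.lowq_rate))
        n_total = n_singlets + n_doublets + n_lowq

        labels: list[str] = []
        body_profiles = np.empty((n_total, body_ix.size))
        depths = np.empty(n_total, dtype=np.int64)

        singlet_depths = _nb_depths(
            sub_rng, n_singlets, params.base_depth, params.depth_dispersion,
            params.min_singlet_depth,
        )
        k = 0
        for t, ident in enumerate(params.identities):
            for _ in range(params.cells_per_type):
                labels.append(ident)
                body_profiles[k] = type_body[ident]
                depths[k] = singlet_depths[k]
                k += 1
        for _ in range(n_doublets):
            a, b = sub_rng.choice(params.n_types, size=2, replace=False)
            ia, ib = sorted((params.identities[a], params.identities[b]))
            labels.append(f"doublet:{ia}+{ib}")
            body_profiles[k] = 0.5 * (type_body[ia] + type_body[ib])
            d2 = _nb_depths(sub_rng, 2, params.base_depth, params.depth_dispersion,
                            params.min_singlet_depth)
            depths[k] = int(d2.sum())
            k += 1
        for _ in range(n_lowq):
            ident = params.identities[int(sub_rng.integers(params.n_types))]
            labels.append("lowq")
            body_profiles[k] = type_body[ident]
            # depth < 300 guarantees detected genes < 300
            depths[k] = int(sub_rng.integers(30, 250))
            k += 1

        is_lowq = np.array([lab == "lowq" for lab in labels])
        mito_fail = np.zeros(n_total, dtype=bool)
        eligible = ~is_lowq
        mito_fail[eligible] = sub_rng.random(int(eligible.sum())) < mito_fail_frac
        mito_targets = np.full(n_total, mito_base)
        mito_targets[mito_fail] = sub_rng.uniform(0.13, 0.30, size=int(mito_fail.sum()))

        prefix = "C" if modality == "cells" else "N"
        barcodes = [f"{prefix}{i:05d}-1" for i in range(n_total)]

        rows_i: list[np.ndarray] = []
        rows_j: list[np.ndarray] = []
        rows_v: list[np.ndarray] = []
        conc = params.dirichlet_concentration
        for i in range(n_total):
            body_p = body_profiles[i]
            if conc > 0:
                alpha = np.maximum(conc * body_p, 1e-8)
                body_p = sub_rng.dirichlet(alpha)
            class_mass = mito_targets[i] + ribo_frac + hsp_frac
            p = np.zeros(n_genes)
            p[body_ix] = body_p * (1.0 - class_mass)
            p[masks["mito"]] = class_w["mito"] * mito_targets[i]
            p[masks["ribo"]] = class_w["ribo"] * ribo_frac
            p[masks["hsp"]] = class_w["hsp"] * hsp_frac
            draw = sub_rng.multinomial(depths[i], p)
            nz = np.flatnonzero(draw)
            rows_i.append(nz)
            rows_j.append(np.full(nz.size, i, dtype=np.int64))
            rows_v.append(draw[nz])

        mat = sp.coo_matrix(
            (np.concatenate(rows_v), (np.concatenate(rows_i), np.concatenate(rows_j))),
            shape=(n_genes, n_total),
        )
        results[modality] = CountMatrix(mat, genes, barcodes, modality)
        for bc, lab, mf in zip(barcodes, labels, mito_fail):
            truth_rows.append(
                {"modality": modality, "barcode": bc, "label": lab, "mito_fail": bool(mf)}
            )

    truth = SyntheticTruth(pd.DataFrame(truth_rows), classes, params)
    return results["cells"], results["nuclei"], truth


def summarize_truth(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Per-identity barcode counts (by modality) and per-class gene counts."""
    bc = (
        truth.barcodes.groupby(["modality", "label"]).size().rename("n_barcodes").reset_index()
    )
    gene = truth.gene_classes.value_counts().rename("n_genes").rename_axis("class").reset_index()
    return {"barcodes": bc, "genes": gene}


def truth_marker_matrix(truth: SyntheticTruth) -> MarkerMatrix:
    """MarkerMatrix built from the generator's planted marker genes (unit weights)."""
    markers: dict[str, dict[str, float]] = {}
    identities = list(truth.params.identities)
    for gene, cls in truth.gene_classes.items():
        if cls.startswith("marker:"):
            ident = cls.split(":", 1)[1]
            markers.setdefault(ident, {})[gene] = 1.0
    return MarkerMatrix(markers, identities)
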