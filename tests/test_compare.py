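import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from discpair.compare import (JointAssignment, contribution, de_overlap, integrate,
                              relabel_marker_table, sequencing_run_summary,
                              transitions, transitions_long, venn_counts)
from discpair.normalize import normalize
from discpair.synthetic import SimParams, generate_pair


def joint_table(rows):
    return JointAssignment(pd.DataFrame(rows, columns=["dataset", "barcode",
                                                       "joint_cluster", "joint_label"]))


def counts_to_table(label_counts):
    rows = []
    i = 0
    for label, (a, b) in label_counts.items():
        for _ in range(a):
            rows.append(("cells", f"c{i}", 0, label)); i += 1
        for _ in range(b):
            rows.append(("nuclei", f"n{i}", 0, label)); i += 1
    return joint_table(rows)


class TestContribution:
    def test_worked_example_100_cells_74_nuclei(self):
        ja = counts_to_table({"PhR": (100, 74)})
        out = contribution(ja, n_filtered_A=100, n_filtered_B=74)
        assert out.attrs["correction_factor"] == pytest.approx(0.74)
        assert out.loc["PhR", "corrected_pct_cells"] == pytest.approx(50.0)
        assert out.loc["PhR", "corrected_pct_nuclei"] == pytest.approx(50.0)

    def test_factor_one_gives_raw_proportions(self):
        ja = counts_to_table({"A": (30, 10)})
        out = contribution(ja, 100, 100)
        assert out.loc["A", "corrected_pct_cells"] == pytest.approx(75.0)

    def test_equal_counts_with_074_factor(self):
        ja = counts_to_table({"A": (100, 100)})
        out = contribution(ja, 100, 74)
        assert out.loc["A", "corrected_pct_cells"] == pytest.approx(100 * 74 / 174)

    def test_invariant_to_common_count_rescaling(self):
        base = counts_to_table({"A": (40, 25), "B": (10, 30)})
        scaled = counts_to_table({"A": (120, 75), "B": (30, 90)})
        out1 = contribution(base, 50, 55)
        out2 = contribution(scaled, 150, 165)
        for lab in ("A", "B"):
            assert out1.loc[lab, "corrected_pct_cells"] == pytest.approx(
                out2.loc[lab, "corrected_pct_cells"])

    def test_shares_sum_to_100(self):
        ja = counts_to_table({"A": (13, 7), "B": (3, 29)})
        out = contribution(ja, 16, 36)
        total = out["corrected_pct_cells"] + out["corrected_pct_nuclei"]
        assert np.allclose(total, 100.0, atol=1e-9)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            contribution(counts_to_table({"A": (1, 1)}), 0, 10)


class TestVennCounts:
    def test_published_overlap_arithmetic(self):
        a = {f"gA{i}" for i in range(1520)} | {f"s{i}" for i in range(1480)}
        b = {f"gB{i}" for i in range(1520)} | {f"s{i}" for i in range(1480)}
        assert venn_counts(a, b) == (1520, 1480, 1520)

    def test_identical_sets(self):
        s = {"a", "b"}
        assert venn_counts(s, s) == (0, 2, 0)

    def test_disjoint_sets(self):
        assert venn_counts({"a"}, {"b", "c"}) == (1, 0, 2)

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_partition_identity(self, a, b):
        ua, shared, ub = venn_counts(a, b)
        assert ua + shared == len(a)
        assert ub + shared == len(b)


class TestDEOverlap:
    def _mt(self, label, genes):
        rows = [(label, g, 1.0, 1e-6, 1e-5, True) for g in genes]
        rows.append((label, "ns", 0.0, 0.9, 0.9, False))
        return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "p",
                                           "p_adj", "significant"])

    def test_set_arithmetic_example(self):
        res = de_overlap(self._mt("PhR", ["g1", "g2", "g3", "g4"]),
                         self._mt("PhR", ["g3", "g4", "g5"]), "PhR")
        pa, pb, ps, total = res
        assert (pa, pb, ps, total) == (40.0, 20.0, 40.0, 5)
        assert pa + pb + ps == 100.0

    def test_identical_sets_fully_shared(self):
        mt = self._mt("A", ["x", "y"])
        assert de_overlap(mt, mt, "A")[2] == 100.0

    def test_empty_union_reported_missing(self):
        res = de_overlap(self._mt("A", []), self._mt("A", []), "A")
        assert res is None

    def test_missing_label_rejected(self):
        with pytest.raises(KeyError, match="absent"):
            de_overlap(self._mt("A", ["x"]), self._mt("B", ["x"]), "A")

    def test_percentages_sum_to_100_on_synthetic_run(self, default_run):
        relabeled = {}
        for mod in ("cells", "nuclei"):
            relabeled[mod] = relabel_marker_table(
                default_run[mod]["markers"], default_run[mod]["merged"].labels)
        shared = set(relabeled["cells"]["cluster"]) & set(relabeled["nuclei"]["cluster"])
        assert shared
        for lab in shared:
            res = de_overlap(relabeled["cells"], relabeled["nuclei"], lab)
            if res is not None:
                assert sum(res[:3]) == pytest.approx(100.0)


class TestRelabel:
    def test_unlabelled_cluster_rejected(self):
        mt = pd.DataFrame([(0, "g", 1.0, 0.1, 0.2, False)],
                          columns=["cluster", "gene", "log2fc", "p", "p_adj",
                                   "significant"])
        with pytest.raises(KeyError):
            relabel_marker_table(mt, {1: "A"})


class TestTransitions:
    def test_identical_labelings_are_diagonal(self):
        ja = joint_table([("cells", f"b{i}", i % 2, ["A", "B"][i % 2])
                          for i in range(10)])
        ind = pd.Series({f"b{i}": ["A", "B"][i % 2] for i in range(10)})
        mat = transitions(ind, ja, "cells")
        assert mat.loc["A", "A"] == 5 and mat.loc["B", "B"] == 5
        assert mat.to_numpy().sum() == 10

    def test_row_sums_equal_source_sizes(self, default_run):
        ja = default_run["joint"]
        for mod in ("cells", "nuclei"):
            merged = default_run[mod]["merged"].labels
            ca = default_run[mod]["clusters"]
            ind = pd.Series([merged[c] for c in ca.labels], index=ca.barcodes)
            mat = transitions(ind, ja, mod)
            expected = ind.value_counts()
            assert mat.sum(axis=1).sort_index().equals(expected.sort_index())
            assert mat.to_numpy().sum() == len(ind)

    def test_missing_barcode_is_hard_error(self):
        ja = joint_table([("cells", "b0", 0, "A")])
        with pytest.raises(ValueError, match="missing"):
            transitions(pd.Series({"b0": "A", "zz": "A"}), ja, "cells")

    def test_long_form_drops_zero_cells(self):
        mat = pd.DataFrame([[3, 0], [1, 2]], index=["A", "B"], columns=["A", "B"])
        mat = mat.rename_axis(index="source_label", columns="joint_label")
        long = transitions_long(mat)
        assert set(long.columns) == {"source_label", "joint_label", "count"}
        assert (long["count"] > 0).all() and long["count"].sum() == 6


class TestIntegrate:
    def test_no_batch_case_mixes_datasets(self):
        # no doublets/lowq/mito-failures: QC is skipped here, so planted
        # quality-failure subpopulations would form extra (real) clusters
        params = SimParams(n_types=3, cells_per_type=60, doublet_rate=0,
                           lowq_rate=0, mito_fail_fraction_cells=0, seed=31)
        cells, _, truth = generate_pair(params)
        # disjoint interleaved halves of one matrix: same composition, no batch
        idx = np.arange(cells.n_barcodes)
        nmA = normalize(cells.subset(barcode_idx=idx[idx % 2 == 0]))
        nmB = normalize(cells.subset(barcode_idx=idx[idx % 2 == 1]))
        ja = integrate(nmA, nmB, hvg_features=100, seed=1)
        lab = truth.labels("cells")
        joint = ja.table.set_index("barcode")["joint_cluster"]
        ari = adjusted_rand_score(lab.reindex(joint.index), joint)
        assert ari >= 0.95
        # every joint cluster contains barcodes from both halves
        tags = ja.table.groupby("joint_cluster")["dataset"].nunique()
        assert (tags == 2).all()

    def test_planted_identities_mix_across_modalities(self, default_run):
        ja = default_run["joint"]
        truth = default_run["truth"]
        merged = ja.table.copy()
        labels = pd.concat([truth.labels("cells"), truth.labels("nuclei")])
        merged["truth"] = labels.reindex(merged["barcode"]).to_numpy()
        singlets = merged[~(merged["truth"].str.startswith("doublet:")
                            | (merged["truth"] == "lowq"))]
        for ident, sub in singlets.groupby("truth"):
            top_cluster = sub["joint_cluster"].mode().iloc[0]
            members = merged[merged["joint_cluster"] == top_cluster]
            assert set(members["dataset"]) == {"cells", "nuclei"}

    def test_deterministic_under_seed(self, small_pair):
        cells, nuclei, _ = small_pair
        nmA, nmB = normalize(cells), normalize(nuclei)
        a = integrate(nmA, nmB, seed=3).table
        b = integrate(nmA, nmB, seed=3).table
        pd.testing.assert_frame_equal(a, b)

    def test_empty_shared_universe_rejected(self, small_pair):
        cells, _, _ = small_pair
        nmA = normalize(cells.subset(gene_idx=range(0, 40), barcode_idx=range(80)))
        nmB = normalize(cells.subset(gene_idx=range(40, 80), barcode_idx=range(80)))
        with pytest.raises(ValueError, match="shared-gene"):
            integrate(nmA, nmB)


class TestRunSummary:
    def test_derived_metrics_printed_precision(self):
        cells = sequencing_run_summary(14487, 28, 192731871)
        assert cells == {"barcodes_per_disc": 517, "pct_of_expected": 1.1,
                         "mean_reads_per_barcode": 13303}
        nuclei = sequencing_run_summary(9048, 41, 120649741)
        assert nuclei == {"barcodes_per_disc": 221, "pct_of_expected": 0.5,
                          "mean_reads_per_barcode": 13334}
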