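import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from discpair.markers import (WilcoxonMarkerFinder, bh_adjust, exact_rank_sum_p,
                              find_markers, is_marker, log2fc, rank_sum_p, top_n)
from discpair.normalize import NormMatrix, normalize
from discpair.synthetic import SimParams, generate_pair, truth_marker_matrix
from discpair.cluster import cluster, embed
from discpair.normalize import select_hvg

from conftest import make_count_matrix


def enumeration_oracle(x, y):
    """Test-local brute force: two-sided rank-sum p over all assignments."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    mu = n * (len(pooled) + 1) / 2
    d_obs = abs(ranks[:n].sum() - mu)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_textbook_separated_groups(self):
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        x = [2.0, 2.0, 2.0, 2.0]
        assert rank_sum_p(x, x, method="normal") == pytest.approx(1.0, abs=1e-6)
        assert rank_sum_p(x, x, method="exact") == 1.0

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=5),
           st.lists(st.integers(0, 5), min_size=2, max_size=5))
    def test_symmetry(self, x, y):
        assert rank_sum_p(x, y) == pytest.approx(rank_sum_p(y, x))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_p([], [1.0])

    def test_normal_approximation_tracks_exact_at_moderate_sizes(self):
        # tie-free draws: with heavy discrete ties the small-sample normal
        # approximation can legitimately drift further from the exact law
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(3, 6))
            m = int(rng.integers(3, 11 - n))
            vals = rng.normal(size=n + m)
            p_norm = rank_sum_p(vals[:n], vals[n:], method="normal")
            p_exact = enumeration_oracle(vals[:n], vals[n:])
            worst = max(worst, abs(p_norm - p_exact))
        # the continuity-corrected approximation sits within a few percent of
        # the exact law at these sizes; rank_sum_p itself switches to the
        # exact path below n+m=10, where agreement is perfect
        assert worst <= 0.05


class TestLog2FC:
    def test_arithmetic(self):
        cl = np.log1p([3.0, 3.0])
        rest = np.log1p([1.0, 1.0])
        assert log2fc(cl, rest) == pytest.approx(1.0)

    def test_identical_distributions_zero(self):
        v = np.log1p([2.0, 5.0, 1.0])
        assert log2fc(v, v) == 0.0

    def test_monotone_in_cluster_expression(self):
        rest = np.log1p([1.0] * 10)
        values = [log2fc(np.log1p([c] * 10), rest) for c in (1, 2, 4, 8, 16)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_bounds_and_sorted_monotonicity(self, pvals):
        adj = bh_adjust(pvals)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 30)))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=0, rtol=1e-12)


class TestSignificanceRule:
    def test_thresholds_are_strict(self):
        assert not is_marker(0.25, 1e-4)
        assert is_marker(0.2500001, 1e-4)
        assert not is_marker(1.0, 0.05)
        assert is_marker(1.0, 0.049999)


@pytest.fixture(scope="module")
def planted():
    params = SimParams(n_types=4, cells_per_type=60, doublet_rate=0,
                       lowq_rate=0, seed=21)
    cells, _, truth = generate_pair(params)
    nm = normalize(cells)
    labels = truth.labels("cells").reindex(cells.barcodes)
    ids = {ident: i for i, ident in enumerate(params.identities)}
    assignment = np.array([ids[l] for l in labels])
    mt = find_markers(nm, assignment)
    return params, truth, nm, assignment, mt, ids


class TestFindMarkers:
    def test_planted_markers_significant_only_in_own_cluster(self, planted):
        params, truth, nm, assignment, mt, ids = planted
        mm = truth_marker_matrix(truth)
        sig = mt[mt["significant"]]
        for ident in params.identities:
            own = set(sig[sig["cluster"] == ids[ident]]["gene"])
            assert mm.genes(ident) <= own
            for other in params.identities:
                if other != ident:
                    other_sig = set(sig[sig["cluster"] == ids[other]]["gene"])
                    assert not (mm.genes(ident) & other_sig)

    def test_shuffled_labels_yield_almost_no_markers(self, planted):
        _, _, nm, assignment, _, _ = planted
        rng = np.random.default_rng(3)
        perm = rng.permutation(assignment)
        mt = find_markers(nm, perm)
        frac = mt["significant"].mean()
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(mt))

    def test_small_cluster_skipped_with_warning(self):
        counts = np.random.default_rng(0).poisson(5, (20, 30))
        nm = normalize(make_count_matrix(counts))
        labels = np.zeros(30, dtype=int)
        labels[:2] = 1  # too small to test
        with pytest.warns(UserWarning, match="skipped"):
            mt = find_markers(nm, labels)
        assert set(mt["cluster"]) == {0}

    def test_single_cluster_rejected(self):
        counts = np.random.default_rng(0).poisson(5, (10, 12))
        nm = normalize(make_count_matrix(counts))
        with pytest.raises(ValueError, match="2 clusters"):
            find_markers(nm, np.zeros(12, dtype=int))

    def test_min_pct_gate_excludes_rare_genes(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5, (10, 60))
        counts[0, :] = 0
        counts[0, 0] = 50  # detected in 1/30 of its cluster
        nm = normalize(make_count_matrix(counts))
        labels = np.repeat([0, 1], 30)
        mt = find_markers(nm, labels)
        assert "g0" not in set(mt[mt["cluster"] == 0]["gene"])


class TestTopN:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "p",
                                           "p_adj", "significant"])

    def test_tie_break_by_fold_change_then_symbol(self):
        mt = self._table([
            (0, "a_low", 1.0, 1e-12, 1e-10, True),
            (0, "b_high", 2.0, 1e-12, 1e-10, True),
            (0, "c_mid", 2.0, 1e-12, 1e-10, True),
            (0, "later", 3.0, 1e-4, 1e-3, True),
        ])
        assert top_n(mt, 3)[0] == ["b_high", "c_mid", "a_low"]

    def test_short_clusters_return_what_they_have(self):
        mt = self._table([
            (0, "x", 1.0, 1e-4, 1e-3, True),
            (0, "y", 1.0, 1e-4, 2e-3, True),
            (0, "z", 0.1, 0.5, 0.9, False),
        ])
        res = top_n(mt, 4)[0]
        assert res == ["x", "y"]
        assert set(res) <= set(mt[mt["significant"]]["gene"])
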