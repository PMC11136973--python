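"""Metacell core: downsampling, feature statistics, balanced KNN graph,
bootstrap co-clustering, and partition derivation."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from conftest import majority_labels
from mcatlas import metacell, synth
from mcatlas.matrix import UMICountMatrix


def _matrix_from_dense(dense):
    dense = np.asarray(dense)
    genes = np.array([f"g{i}" for i in range(dense.shape[0])], dtype=object)
    cells = np.array([f"c{j}" for j in range(dense.shape[1])], dtype=object)
    return UMICountMatrix(sp.csc_matrix(dense), genes, cells)


class TestDownsample:
    def test_cells_above_target_hit_it_exactly(self, small_matrix):
        matrix, _ = small_matrix
        ds = metacell.downsample_cells(matrix, 600, seed=0)
        assert np.all(ds.cell_totals() == 600)
        assert (ds.counts > matrix.counts).nnz == 0  # no gene gains counts

    def test_cells_at_or_below_target_unchanged(self):
        m = _matrix_from_dense([[5, 1], [5, 1]])
        ds = metacell.downsample_cells(m, 10, seed=0)
        assert (ds.counts != m.counts).nnz == 0

    def test_deterministic_given_seed(self, small_matrix):
        matrix, _ = small_matrix
        a = metacell.downsample_cells(matrix, 500, seed=4)
        b = metacell.downsample_cells(matrix, 500, seed=4)
        assert (a.counts != b.counts).nnz == 0

    def test_auto_target_is_fifth_percentile(self, small_matrix):
        matrix, _ = small_matrix
        ds = metacell.downsample_cells(matrix, "auto", seed=0)
        target = int(np.percentile(matrix.cell_totals(), 5))
        assert ds.cell_totals().max() <= target


class TestSelectFeatures:
    def test_total_umi_threshold_is_strict(self):
        # one gene at exactly 30 total, one just above; spread so the
        # prevalence filter passes both.
        dense = np.zeros((2, 10), dtype=int)
        dense[0, :10] = 3  # total 30
        dense[1, :10] = 3
        dense[1, 0] += 1  # total 31
        m = _matrix_from_dense(dense)
        fs = metacell.select_features(
            m, downsampled=m, use_szcor=False, use_niche=False
        )
        assert not fs.stats.loc["g0", "selected"]
        assert fs.stats.loc["g1", "selected"]

    def test_prevalence_requires_gt2_umi_in_3_cells(self):
        dense = np.zeros((2, 8), dtype=int)
        dense[0, :3] = 3   # 3 UMIs in exactly 3 cells
        dense[0, 3] = 31 - 9
        dense[1, :8] = 2   # never exceeds 2 UMIs -> prevalence 0
        dense[1, 0] += 30
        m = _matrix_from_dense(dense)
        fs = metacell.select_features(m, downsampled=m, use_szcor=False, use_niche=False)
        assert fs.stats.loc["g0", "prevalence"] >= 3
        assert fs.stats.loc["g0", "selected"]
        assert not fs.stats.loc["g1", "selected"]

    def test_homogeneous_gene_has_minimum_niche_score(self):
        # 10x10 toy: gene 0 identical everywhere; brute-force check that
        # its top-5% concentration equals the uniform floor exactly.
        rng = np.random.default_rng(0)
        dense = rng.integers(1, 6, size=(10, 10))
        dense[0, :] = 4
        m = _matrix_from_dense(dense * 10)  # scale so totals pass t_tot
        fs = metacell.select_features(m, downsampled=m, use_szcor=False)
        counts = np.asarray(m.counts.todense())[0].astype(float)
        k = int(np.ceil(0.05 * 10))
        expected = np.sort(counts)[-k:].sum() / counts.sum() - k / 10
        assert fs.stats.loc["g0", "niche_score"] == pytest.approx(expected)
        assert fs.stats.loc["g0", "niche_score"] == pytest.approx(0.0)
        assert not fs.stats.loc["g0", "selected"]

    def test_stats_reported_for_all_genes(self, small_matrix):
        matrix, _ = small_matrix
        fs = metacell.select_features(matrix, seed=0)
        assert len(fs.stats) == matrix.n_genes
        assert set(fs.stats.columns) >= {
            "total_umi", "prevalence", "size_correlation", "niche_score", "selected"
        }

    def test_szcor_filter_is_literal_and_restrictive(self, small_matrix):
        matrix, _ = small_matrix
        strict = metacell.select_features(matrix, use_szcor=True, seed=0)
        loose = metacell.select_features(matrix, use_szcor=False, seed=0)
        assert set(strict.gene_ids) <= set(loose.gene_ids)


class TestBalancedKnn:
    def test_identical_cells_get_weight_half_edge(self):
        rng = np.random.default_rng(1)
        dense = rng.integers(0, 20, size=(10, 6))
        dense[:, 1] = dense[:, 0]  # cells 0 and 1 identical
        m = _matrix_from_dense(dense)
        g = metacell.build_balanced_knn(m, m.gene_ids, K=2)
        pairs = {tuple(e): w for e, w in zip(map(tuple, g.edges), g.weights)}
        assert pairs.get((0, 1)) == pytest.approx(0.5)

    def test_degree_capped_at_2K(self, small_matrix):
        matrix, _ = small_matrix
        ds = metacell.downsample_cells(matrix, "auto", seed=0)
        fs = metacell.select_features(matrix, downsampled=ds, use_szcor=False, seed=0)
        g = metacell.build_balanced_knn(ds, fs, K=5)
        assert g.degrees().max() <= 10

    def test_graph_is_simple_and_positive(self, small_matrix):
        matrix, _ = small_matrix
        ds = metacell.downsample_cells(matrix, "auto", seed=0)
        fs = metacell.select_features(matrix, downsampled=ds, use_szcor=False, seed=0)
        g = metacell.build_balanced_knn(ds, fs, K=10)
        assert np.all(g.edges[:, 0] < g.edges[:, 1])  # no self loops, no dups
        assert len({tuple(e) for e in map(tuple, g.edges)}) == len(g.edges)
        assert np.all(g.weights > 0)

    def test_too_few_cells_raises_with_guidance(self):
        m = _matrix_from_dense(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError, match="lower K"):
            metacell.build_balanced_knn(m, m.gene_ids, K=10)

    def test_tie_break_on_equidistant_cells_keeps_graph_symmetric(self):
        # 3 mutually identical cells: all similarities tie at 1.
        dense = np.tile(np.array([[3], [5], [2], [7]]), (1, 3))
        m = _matrix_from_dense(dense)
        g = metacell.build_balanced_knn(m, m.gene_ids, K=1)
        assert len(g.edges) >= 1
        assert np.all(g.weights > 0)


def _clique_graph(sizes, seed=0):
    """Cell graph of disjoint cliques with unit weights."""
    n = sum(sizes)
    edges = []
    start = 0
    for s in sizes:
        for i in range(start, start + s):
            for j in range(i + 1, start + s):
                edges.append((i, j))
        start += s
    cells = np.array([f"c{i}" for i in range(n)], dtype=object)
    return metacell.CellGraph(cells, np.array(edges), np.ones(len(edges)), K=3)


class TestBootstrapCocluster:
    def test_count_invariants(self):
        g = _clique_graph([8, 8])
        cc = metacell.bootstrap_cocluster(g, n_iter=20, fraction=0.75, seed=0)
        assert np.all(cc.co_count <= cc.co_sample)
        assert np.all(cc.co_sample <= 20)
        assert np.array_equal(cc.co_count, cc.co_count.T)
        assert np.array_equal(cc.co_sample, cc.co_sample.T)

    def test_full_fraction_is_deterministic_per_iteration(self):
        g = _clique_graph([8, 8])
        cc = metacell.bootstrap_cocluster(g, n_iter=2, fraction=1.0, seed=0)
        freq = cc.frequency()
        off_diag = freq[np.triu_indices_from(freq, 1)]
        assert set(np.round(off_diag, 9)) <= {0.0, 1.0}

    def test_co_sample_matches_binomial_expectation(self):
        g = _clique_graph([10, 10])
        n_iter, frac = 400, 0.75
        cc = metacell.bootstrap_cocluster(g, n_iter=n_iter, fraction=frac, seed=1)
        m = int(np.ceil(frac * 20))
        p_pair = (m / 20) * ((m - 1) / 19)
        expect = n_iter * p_pair
        sigma = np.sqrt(n_iter * p_pair * (1 - p_pair))
        off = cc.co_sample[np.triu_indices_from(cc.co_sample, 1)]
        assert np.all(np.abs(off - expect) <= 4 * sigma)

    def test_disconnected_components_never_cocluster(self):
        g = _clique_graph([10, 10])
        cc = metacell.bootstrap_cocluster(g, n_iter=30, fraction=0.8, seed=2)
        assert cc.co_count[:10, 10:].sum() == 0

    def test_bad_fraction_raises(self):
        g = _clique_graph([8])
        with pytest.raises(ValueError):
            metacell.bootstrap_cocluster(g, n_iter=2, fraction=1.5, seed=0)


def _clique_cocluster(sizes, n_iter=10):
    """Hand-built co-clustering: within-clique frequency 1, between 0."""
    n = sum(sizes)
    co = np.zeros((n, n), dtype=np.int32)
    start = 0
    for s in sizes:
        co[start : start + s, start : start + s] = n_iter
        start += s
    samp = np.full((n, n), n_iter, dtype=np.int32)
    cells = np.array([f"c{i}" for i in range(n)], dtype=object)
    return metacell.CoClustering(cells, co, samp, n_iter, 1.0)


class TestDeriveMetacells:
    def test_two_planted_cliques_recovered_exactly(self):
        cc = _clique_cocluster([20, 20])
        part = metacell.derive_metacells(cc, K_cc=30, alpha=2, min_size=15)
        assert part.n_metacells == 2
        assert len(set(part.assignment[:20])) == 1
        assert len(set(part.assignment[20:])) == 1
        assert part.assignment[0] != part.assignment[20]

    def test_undersized_isolated_clique_becomes_outliers(self):
        cc = _clique_cocluster([10])
        with pytest.warns(UserWarning):
            part = metacell.derive_metacells(cc, min_size=15)
        assert np.all(part.assignment == -1)

    def test_infinite_alpha_disables_edge_removal(self):
        cc = _clique_cocluster([20, 20])
        a = metacell.derive_metacells(cc, alpha=np.inf, min_size=15)
        b = metacell.derive_metacells(cc, alpha=2, min_size=15)
        assert np.array_equal(a.assignment, b.assignment)

    def test_partition_is_total(self):
        cc = _clique_cocluster([18, 25, 16])
        part = metacell.derive_metacells(cc, min_size=15)
        assert len(part.assignment) == len(cc.cell_ids)
        assert np.all((part.assignment >= -1))

    def test_increasing_min_size_never_increases_metacell_count(self):
        cc = _clique_cocluster([16, 20, 30])
        counts = [
            metacell.derive_metacells(cc, min_size=s).n_metacells for s in (10, 17, 25, 40)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLowQualityFilter:
    def _partition_and_matrix(self, n_cells, depth):
        dense = np.zeros((3, n_cells), dtype=int)
        dense[0] = depth
        m = _matrix_from_dense(dense)
        part = metacell.MetacellPartition(
            m.cell_ids, np.zeros(n_cells, dtype=int), min_size=15
        )
        return part, m

    def test_large_low_umi_metacell_removed(self):
        part, m = self._partition_and_matrix(60, 400)
        out = metacell.filter_low_quality_metacells(part, m)
        assert np.all(out.assignment == -1)

    def test_small_low_umi_metacell_kept(self):
        part, m = self._partition_and_matrix(40, 400)
        out = metacell.filter_low_quality_metacells(part, m)
        assert np.all(out.assignment == 0)

    def test_median_at_threshold_kept(self):
        part, m = self._partition_and_matrix(60, 500)
        out = metacell.filter_low_quality_metacells(part, m)
        assert np.all(out.assignment == 0)


class TestLayout:
    def test_single_metacell_at_origin(self):
        cc = _clique_cocluster([20])
        part = metacell.derive_metacells(cc, min_size=15)
        mc_coords, cell_coords = metacell.layout_2d(cc, part, seed=0)
        assert np.allclose(mc_coords[["x", "y"]].to_numpy(), 0.0)
        assert np.isfinite(cell_coords[["x", "y"]].to_numpy()).all()

    def test_layout_deterministic_given_seed(self):
        cc = _clique_cocluster([20, 20, 20])
        part = metacell.derive_metacells(cc, min_size=15)
        a = metacell.layout_2d(cc, part, seed=3)[0]
        b = metacell.layout_2d(cc, part, seed=3)[0]
        assert np.allclose(a[["x", "y"]], b[["x", "y"]])

    def test_disconnected_metacells_do_not_coincide(self):
        cc = _clique_cocluster([20, 20])
        part = metacell.derive_metacells(cc, min_size=15)
        mc_coords, _ = metacell.layout_2d(cc, part, seed=1)
        xy = mc_coords[["x", "y"]].to_numpy()
        assert np.linalg.norm(xy[0] - xy[1]) > 1e-3


def test_recovery_on_small_planted_dataset():
    """End-to-end clustering separates 4 planted types at fold 8."""
    truth = synth.make_expression_truth(4, 500, 15, [8.0], seed=21)
    matrix, labels = synth.sample_umi_matrix(truth, 80, None, seed=21)
    part, _, _ = metacell.cluster_cells(matrix, K=40, n_boot=15, seed=21)
    maj = majority_labels(part, labels)
    assert adjusted_rand_score(labels, maj) >= 0.8
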