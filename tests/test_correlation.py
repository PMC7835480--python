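import numpy as np
import pandas as pd
import pytest

from histmod_dex.correlation import (
    change_expression_profile,
    cluster_and_network,
    edges_to_networkx,
    pairwise_hm_correlation,
    spearman,
)


class TestSpearman:
    def test_identity_gives_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, x) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_worked_rank_example(self):
        # d = (-1, 1, -1, 1, 0), d^2 sum = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        assert spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(out)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestChangeExpressionProfile:
    def test_expression_equal_to_one_column_gives_rho_one(self, small_perbin_matrix):
        m = small_perbin_matrix
        col = m.columns_for_hm(m.hm_names[0])[0]
        expr = m.X[col]
        profile = change_expression_profile(m, expr, "up")
        assert profile.loc[m.hm_names[0], m.bin_labels[0]] == pytest.approx(1.0)
        assert profile.shape == (len(m.hm_names), len(m.bin_labels))
        assert ((profile >= -1) & (profile <= 1)).all().all()

    def test_independent_noise_has_small_rho(self):
        """Null bound: with n genes, |rho| stays below ~3/sqrt(n)."""
        from histmod_dex.features import RatioMatrix

        rng = np.random.default_rng(1)
        n = 500
        idx = pd.Index([f"G{i:03d}" for i in range(n)], name="gene_id")
        bins = (-1, 1)
        X = pd.DataFrame(
            rng.lognormal(size=(n, 4)),
            index=idx,
            columns=[f"HM{k}:{b}" for k in range(2) for b in bins],
        )
        y = pd.Series(["up"] * 250 + ["down"] * 250, index=idx, name="label")
        m = RatioMatrix(X, y, "per_bin", ("HM0", "HM1"), bins, eps=0.0)
        expr = pd.Series(rng.lognormal(size=n), index=idx)
        profile = change_expression_profile(m, expr, "up")
        assert profile.abs().max().max() < 0.15

    def test_planted_driver_correlates_positively_in_up_class(
        self, small_perbin_matrix, small_dataset, small_config
    ):
        truth = small_dataset.gene_truth.set_index("gene_id")
        driver = small_config.driver_names[0]
        responders = truth[f"responds_{driver}"]
        expr = (2.0 ** truth["log2_fc"]).reindex(small_perbin_matrix.y.index)
        profile = change_expression_profile(small_perbin_matrix, expr, "up")
        # responding up-genes raise driver signal with expression; pooled
        # over responders and non-responders rho stays positive
        assert (profile.loc[driver] > 0).mean() > 0.9
        assert responders.mean() > 0.3  # sanity: regulon non-trivial

    def test_empty_class_rejected(self, small_perbin_matrix):
        expr = pd.Series(1.0, index=small_perbin_matrix.y.index)
        with pytest.raises(ValueError, match="gene_class"):
            change_expression_profile(small_perbin_matrix, expr, "sideways")


def _block_rho():
    """Two blocks of mutually correlated marks, uncorrelated across."""
    names = ["A1", "A2", "A3", "B1", "B2"]
    rho = pd.DataFrame(np.eye(5), index=names, columns=names)
    for a in ("A1", "A2", "A3"):
        for b in ("A1", "A2", "A3"):
            if a != b:
                rho.loc[a, b] = 0.9
    rho.loc["B1", "B2"] = rho.loc["B2", "B1"] = 0.85
    return rho


class TestClusterAndNetwork:
    def test_block_structure_recovered(self):
        rho = _block_rho()
        Z, newick, edges = cluster_and_network(rho, threshold=0.6)
        got = {frozenset((a, b)) for a, b in zip(edges["hm_a"], edges["hm_b"])}
        want = {
            frozenset(p)
            for p in [("A1", "A2"), ("A1", "A3"), ("A2", "A3"), ("B1", "B2")]
        }
        assert got == want
        # dendrogram top split separates the blocks
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(Z, t=2, criterion="maxclust")
        blocks = {}
        for name, c in zip(rho.index, assign):
            blocks.setdefault(c, set()).add(name)
        assert set(map(frozenset, blocks.values())) == {
            frozenset({"A1", "A2", "A3"}),
            frozenset({"B1", "B2"}),
        }
        assert newick.count("(") == 4  # binary tree over 5 leaves

    def test_threshold_one_gives_empty_edge_list(self):
        _, _, edges = cluster_and_network(_block_rho(), threshold=1.0)
        assert edges.empty

    def test_threshold_minus_one_gives_complete_graph(self):
        rho = _block_rho()
        _, _, edges = cluster_and_network(rho, threshold=-1.0)
        m = len(rho)
        assert len(edges) == m * (m - 1) // 2

    def test_edges_monotone_in_threshold(self):
        rho = _block_rho()
        sizes = [
            len(cluster_and_network(rho, threshold=t)[2])
            for t in (-1.0, 0.0, 0.6, 0.88, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_rho_rejected(self):
        rho = _block_rho()
        rho.loc["A1", "B1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cluster_and_network(rho)

    def test_networkx_export(self):
        rho = _block_rho()
        _, _, edges = cluster_and_network(rho, threshold=0.6)
        g = edges_to_networkx(edges, nodes=rho.index)
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == len(edges)
        assert g["A1"]["A2"]["weight"] == pytest.approx(0.9)


class TestPairwise:
    def test_symmetric_unit_diagonal(self, small_region_matrix):
        rho = pairwise_hm_correlation(small_region_matrix, "up")
        np.testing.assert_allclose(rho.values, rho.values.T)
        np.testing.assert_allclose(np.diag(rho.values), 1.0)
        assert ((rho.values >= -1) & (rho.values <= 1)).all()

    def test_perbin_matrix_collapses_to_region_means(
        self, small_perbin_matrix, small_region_matrix
    ):
        a = pairwise_hm_correlation(small_perbin_matrix, "down")
        b = pairwise_hm_correlation(small_region_matrix, "down")
        # same genes and marks; mean-of-bin-ratios vs ratio-of-means agree
        # closely in rank structure
        assert a.shape == b.shape
        np.testing.assert_allclose(a.values, b.values, atol=0.25)


def test_pairwise_raw_signal_mode(small_region_matrix, small_tensors):
    raw = pd.DataFrame(
        small_tensors["cancer"].region_values(),
        index=small_tensors["cancer"].gene_ids,
        columns=small_tensors["cancer"].hm_names,
    )
    rho = pairwise_hm_correlation(small_region_matrix, "up", raw_signals=raw)
    np.testing.assert_allclose(rho.values, rho.values.T)
    np.testing.assert_allclose(np.diag(rho.values), 1.0)
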