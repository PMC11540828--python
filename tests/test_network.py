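"""Network construction, TOM, clustering, eigengenes, merging, hubs."""

import numpy as np
import pandas as pd
import pytest

from fibromod.network import (NetworkParams, cluster_genes, compute_eigengenes,
                              correlation_matrix, cut_static, detect_modules,
                              drop_zero_variance, hub_genes, merge_modules,
                              scale_free_fit, scan_soft_threshold,
                              soft_adjacency, topological_overlap)


class TestCorrelationMatrix:
    def test_duplicate_and_negated_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        m = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
        c = correlation_matrix(m)
        assert c.loc["a", "b"] == pytest.approx(1.0)
        assert c.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(10, 8)))
        c = correlation_matrix(m).to_numpy()
        x = m.to_numpy()
        for i in range(10):
            for j in range(10):
                a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
                ref = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
                assert c[i, j] == pytest.approx(ref, abs=1e-12)

    def test_rejects_few_samples_and_constant_genes(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(pd.DataFrame(np.ones((4, 2))))
        m = pd.DataFrame(np.vstack([np.ones(5), np.arange(5.0)]),
                         index=["flat", "ok"])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(m)

    def test_drop_zero_variance_reports_manifest(self):
        m = pd.DataFrame(np.vstack([np.ones(5), np.arange(5.0)]),
                         index=["flat", "ok"])
        kept, dropped = drop_zero_variance(m)
        assert dropped == ["flat"] and list(kept.index) == ["ok"]


class TestSoftAdjacency:
    @pytest.mark.parametrize("cor,expected", [(0.5, 0.0625), (-1.0, 1.0),
                                              (0.0, 0.0)])
    def test_powers(self, cor, expected):
        c = np.array([[1.0, cor], [cor, 1.0]])
        a = soft_adjacency(c, 4)
        assert a[0, 1] == pytest.approx(expected)
        assert a[0, 0] == 0.0  # diagonal zeroed for connectivity

    def test_rejects_power_below_one(self):
        with pytest.raises(ValueError):
            soft_adjacency(np.eye(2), 0)


class TestScaleFreeFit:
    def test_constructed_power_law_fits_well(self):
        # node degrees drawn from an exact discrete power law; a rank-1
        # adjacency realizes them (up to the zeroed diagonal)
        ks = np.concatenate([np.full(64, 1.0), np.full(16, 2.0),
                             np.full(4, 4.0), np.full(1, 8.0)])
        w = ks / np.sqrt(ks.sum())
        a = np.outer(w, w)
        np.fill_diagonal(a, 0.0)
        r2, mean_k = scale_free_fit(a)
        assert r2 >= 0.99
        assert mean_k == pytest.approx(a.sum(1).mean())

    def test_complete_graph_is_degenerate(self):
        a = np.ones((10, 10)) - np.eye(10)
        with pytest.warns(UserWarning, match="degenerate"):
            r2, _ = scale_free_fit(a)
        assert r2 == 0.0

    def test_scan_returns_one_row_per_power(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(30, 10)))
        table = scan_soft_threshold(correlation_matrix(m), (1, 2, 4, 6))
        assert list(table["power"]) == [1, 2, 4, 6]
        assert {"r_squared", "mean_connectivity"} <= set(table.columns)


class TestTopologicalOverlap:
    def test_three_node_clique(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        # (shared neighbour 1*1 + direct 1) / (min k 2 + 1 - 1) = 1
        assert tom[0, 1] == pytest.approx(1.0)

    def test_isolated_pair(self):
        a = np.zeros((4, 4))
        tom = topological_overlap(a)
        assert tom[0, 1] == 0.0
        assert tom[0, 0] == 1.0

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(3)
        n = 20
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        k = a.sum(1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                ref = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(ref, abs=1e-12)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError, match="non-negative"):
            topological_overlap(np.array([[0.0, -0.1], [-0.1, 0.0]]))
        bad = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(bad)


class TestClusterGenes:
    def test_identical_blocks_merge_at_zero(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        z = cluster_genes(d)
        assert np.allclose(z[:4, 2], 0.0)  # within-block merges first, at 0
        assert z[-1, 2] == pytest.approx(1.0)

    def test_three_point_upgma_by_hand(self):
        d = np.array([[0.0, 0.1, 0.9],
                      [0.1, 0.0, 0.9],
                      [0.9, 0.9, 0.0]])
        z = cluster_genes(d)
        assert z[0, 2] == pytest.approx(0.1)
        assert z[1, 2] == pytest.approx(0.9)  # average of 0.9 and 0.9

    def test_permutation_gives_same_heights(self):
        rng = np.random.default_rng(4)
        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        z1 = cluster_genes(d)
        perm = rng.permutation(12)
        z2 = cluster_genes(d[np.ix_(perm, perm)])
        np.testing.assert_allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))

    def test_rejects_nan(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cluster_genes(d)


class TestModuleDetection:
    def test_planted_blocks_recovered_noise_unassigned(self, planted_blocks):
        matrix, labels, detected = planted_blocks
        found = {m: set(matrix.index[detected.labels == m])
                 for m in detected.module_ids}
        assert len(found) == 2
        for b in (1, 2):
            block = set(matrix.index[labels == b])
            best = max(len(block & genes) / len(block | genes)
                       for genes in found.values())
            assert best >= 0.8
        noise = set(matrix.index[labels == 0])
        assigned_noise = noise & set().union(*found.values())
        assert len(assigned_noise) <= 0.1 * len(noise)

    def test_static_cut_threshold_edge(self):
        # largest real branch below the minimum size -> zero modules
        rng = np.random.default_rng(6)
        d = rng.random((40, 40)) * 0.1 + 0.9
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        z = cluster_genes(d)
        with pytest.warns(UserWarning, match="minimum module size"):
            labels = cut_static(z, 40, min_module_size=41, height_fraction=0.5)
        assert (labels == 0).all()

    def test_duplicating_genes_doubles_modules(self, planted_blocks):
        """Exact duplicates of every gene yield the same modules with the
        duplicates assigned alongside their originals (sizes ~doubled, up to
        rescue of borderline background genes)."""
        matrix, labels, detected = planted_blocks
        doubled = pd.concat([matrix,
                             matrix.set_index(matrix.index + "_copy")])
        det2 = detect_modules(doubled)
        assert len(det2.module_ids) == len(detected.module_ids)
        for m in detected.module_ids:
            genes = set(detected.module_genes(m))
            both = genes | {g + "_copy" for g in genes}
            best = max(
                len(both & set(det2.module_genes(d))) / len(both)
                for d in det2.module_ids)
            assert best >= 0.95


@pytest.fixture(scope="module")
def planted_blocks(request):
    from conftest import planted_block_matrix
    rng = np.random.default_rng(8)
    matrix, labels = planted_block_matrix(rng)
    detected = detect_modules(matrix)
    return matrix, labels, detected


class TestEigengenes:
    def test_identical_genes_explain_everything(self):
        rng = np.random.default_rng(9)
        profile = rng.normal(size=10)
        m = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        labels = pd.Series([1] * 5, index=m.index)
        ms = compute_eigengenes(m, labels)
        assert ms.variance_explained[1] == pytest.approx(1.0)
        e = ms.eigengenes[1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        cos = abs(e @ z) / np.linalg.norm(z)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_sign_tie(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=12)
        m = pd.DataFrame([profile, -profile], index=["a", "b"])
        ms = compute_eigengenes(m, pd.Series([1, 1], index=m.index))
        assert ms.variance_explained[1] == pytest.approx(1.0)
        kme = ms.kme
        assert kme["a"] + kme["b"] == pytest.approx(0.0, abs=1e-12)
        assert kme["a"] > 0  # first-gene-positive tie-break

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(40, 20)))
        ms = compute_eigengenes(m, pd.Series(np.ones(40, int), index=m.index))
        x = m.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        w, v = np.linalg.eigh(xs.T @ xs)
        top = v[:, -1]
        e = ms.eigengenes[1].to_numpy()
        assert abs(e @ top) >= 1 - 1e-10
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_unit_norm_and_nonnegative_mean_kme(self, planted_blocks):
        _, _, detected = planted_blocks
        for m in detected.module_ids:
            assert np.linalg.norm(detected.eigengenes[m]) == pytest.approx(1.0)
            genes = detected.module_genes(m)
            assert detected.kme[genes].mean() >= 0


class TestMergeModules:
    def test_artificially_split_block_remerges(self):
        from conftest import planted_block_matrix
        rng = np.random.default_rng(12)
        matrix, labels = planted_block_matrix(rng, n_blocks=1, n_noise=0)
        split = pd.Series(np.r_[np.ones(25, int), np.full(25, 2)],
                          index=matrix.index)
        merged = merge_modules(matrix, split)
        assert len(merged.module_ids) == 1

    def test_independent_blocks_stay_separate(self):
        from conftest import planted_block_matrix
        rng = np.random.default_rng(13)
        matrix, labels = planted_block_matrix(rng, n_blocks=2, n_noise=0)
        merged = merge_modules(matrix, pd.Series(labels, index=matrix.index))
        assert len(merged.module_ids) == 2
        eg = merged.eigengenes.to_numpy()
        r = np.corrcoef(eg.T)
        assert abs(r[0, 1]) <= 0.75

    def test_postcondition_no_pair_above_threshold(self, planted_blocks):
        _, _, detected = planted_blocks
        if len(detected.module_ids) > 1:
            r = np.abs(np.corrcoef(detected.eigengenes.to_numpy().T))
            np.fill_diagonal(r, 0.0)
            assert r.max() <= 0.75 + 1e-12


class TestHubGenes:
    def test_gene_equal_to_pattern_is_hub(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=15)
        rows = [z] + [0.5 * z + rng.normal(0, 1, 15) for _ in range(6)]
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(7)])
        ms = compute_eigengenes(m, pd.Series(np.ones(7, int), index=m.index))
        assert ms.hub_gene[1] == "g0"
        assert ms.kme["g0"] > 0.9

    def test_strong_loading_wins_across_seeds(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=80)
            rows = [0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=80)]
            rows += [0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=80)
                     for _ in range(5)]
            m = pd.DataFrame(rows, index=["A"] + [f"b{i}" for i in range(5)])
            ms = compute_eigengenes(m, pd.Series(np.ones(6, int), index=m.index))
            wins += ms.hub_gene[1] == "A"
        assert wins >= 45

    def test_exact_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=10)
        m = pd.DataFrame([z, z, 0.3 * z + rng.normal(size=10)],
                         index=["B", "A", "c"])
        ms = compute_eigengenes(m, pd.Series(np.ones(3, int), index=m.index))
        assert ms.hub_gene[1] == "A"
        table = hub_genes(ms)
        assert table.loc[0, "hub_gene"] == "A"


def test_negating_a_gene_preserves_absolute_correlations():
    """Unsigned-network sign invariance: flipping any gene's sign leaves the
    absolute correlation structure (hence adjacency and TOM) unchanged."""
    rng = np.random.default_rng(16)
    m = pd.DataFrame(rng.normal(size=(15, 12)))
    flipped = m.copy()
    flipped.iloc[4] *= -1.0
    a1 = soft_adjacency(correlation_matrix(m), 4)
    a2 = soft_adjacency(correlation_matrix(flipped), 4)
    np.testing.assert_allclose(a1, a2, atol=1e-12)
    np.testing.assert_allclose(topological_overlap(a1),
                               topological_overlap(a2), atol=1e-12)


def test_network_params_validation():
    with pytest.raises(ValueError):
        NetworkParams(power=0)
    with pytest.raises(ValueError):
        NetworkParams(merge_cor_threshold=1.5)
    with pytest.raises(ValueError):
        NetworkParams(cut_method="other")
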