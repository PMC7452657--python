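import numpy as np
import pandas as pd
import pytest

from striatype import fit_pca, hierarchical_cluster, select_components, silhouette_sweep
from striatype.cluster import export_dendrogram, tree_to_newick
from striatype.exceptions import ValidationError


def three_blobs(seed=0, n=30, sep=10.0, dim=3):
    """Three spherical Gaussian blobs with centers ``sep`` SDs apart."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, dim))
    centers[1, 0] = sep
    centers[2, 1] = sep
    x = np.vstack([rng.normal(c, 1.0, size=(n, dim)) for c in centers])
    labels = np.repeat([0, 1, 2], n)
    return x, labels


class TestPCA:
    def test_single_axis_data_loads_on_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=100)
        x = np.column_stack([t, 2 * t + 1, -0.5 * t])
        model = fit_pca(x)
        assert model.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_matches_eigendecomposition_oracle(self):
        """SVD route equals a brute-force covariance eigendecomposition."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 12)) @ rng.normal(size=(12, 12))
        model = fit_pca(x)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(np.cov(z, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            model.variance_explained, evals / evals.sum(), atol=1e-8
        )

    def test_scores_reproduce_projection(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 5))
        model = fit_pca(x)
        z = (x - model.means) / model.sds
        np.testing.assert_allclose(model.scores, z @ model.loadings, atol=1e-8)

    def test_loadings_orthonormal_and_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        model = fit_pca(rng.normal(size=(40, 6)))
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert model.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.variance_explained) <= 1e-12)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 4))
        a, b = fit_pca(x), fit_pca(x.copy())
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(a.loadings.shape[1]):
            imax = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[imax, j] > 0

    def test_nan_cells_rejected_with_policy_pointer(self):
        x = np.ones((5, 3)) + np.arange(15).reshape(5, 3)
        x[2, 1] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            fit_pca(x)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="b"):
            fit_pca(df)


class TestSelectComponents:
    def test_all_components_reach_full_variance(self):
        rng = np.random.default_rng(5)
        model = fit_pca(rng.normal(size=(30, 4)))
        scores, cum = select_components(model, n=4)
        assert scores.shape == (30, 4)
        assert cum == pytest.approx(1.0, abs=1e-10)

    def test_cum_var_picks_smallest_n(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=80)
        x = np.column_stack([t, 3 * t, -t]) + 1e-6 * rng.normal(size=(80, 3))
        model = fit_pca(x)
        scores, cum = select_components(model, cum_var=0.5)
        assert scores.shape[1] == 1
        assert cum >= 0.5

    def test_out_of_range_n_rejected(self):
        rng = np.random.default_rng(7)
        model = fit_pca(rng.normal(size=(20, 3)))
        with pytest.raises(ValidationError):
            select_components(model, n=7)


class TestHierarchical:
    def test_two_far_pairs_separate_at_k2(self):
        x = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        res = hierarchical_cluster(x, k_range=range(2, 3))
        labels = res.labels_for_k[2]
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_merge_heights_match_brute_force_ward_oracle(self):
        """Exhaustive Lance-Williams agglomeration reproduces scipy's tree
        on a small instance (n <= 8, no ties)."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(8, 3))
        res = hierarchical_cluster(x)

        # brute-force Ward via Lance-Williams update on squared distances
        n = len(x)
        d2 = {
            frozenset((i, j)): np.sum((x[i] - x[j]) ** 2)
            for i in range(n)
            for j in range(i + 1, n)
        }
        sizes = {i: 1 for i in range(n)}
        active = set(range(n))
        merges = []
        next_id = n
        while len(active) > 1:
            pair = min(
                (frozenset((i, j)) for i in active for j in active if i < j),
                key=lambda p: d2[p],
            )
            i, j = sorted(pair)
            h = np.sqrt(d2[pair])
            merges.append((i, j, h, sizes[i] + sizes[j]))
            for k in active - {i, j}:
                si, sj, sk = sizes[i], sizes[j], sizes[k]
                tot = si + sj + sk
                d2[frozenset((next_id, k))] = (
                    (si + sk) / tot * d2[frozenset((i, k))]
                    + (sj + sk) / tot * d2[frozenset((j, k))]
                    - sk / tot * d2[pair]
                )
            active -= {i, j}
            sizes[next_id] = sizes[i] + sizes[j]
            active.add(next_id)
            next_id += 1

        for row, (i, j, h, size) in zip(res.linkage_tree, merges):
            assert {int(row[0]), int(row[1])} == {i, j}
            assert row[2] == pytest.approx(h, abs=1e-8)
            assert int(row[3]) == size

    def test_three_blobs_recovered_at_k3(self):
        x, truth = three_blobs(seed=9)
        model = fit_pca(x)
        scores, _ = select_components(model, n=3)
        res = hierarchical_cluster(scores)
        labels = res.labels_for_k[3]
        # agreement up to permutation: each blob maps to one cluster
        for g in range(3):
            assert len(np.unique(labels[truth == g])) == 1
        assert len(np.unique(labels)) == 3

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.zeros((2, 2)))

    def test_feature_rescaling_invariance_via_zscore(self):
        x, _ = three_blobs(seed=10, dim=4)
        scale = np.array([1.0, 100.0, 0.01, 5.0])
        a = hierarchical_cluster(select_components(fit_pca(x), n=3)[0])
        b = hierarchical_cluster(select_components(fit_pca(x * scale + 7.0), n=3)[0])
        np.testing.assert_array_equal(a.labels_for_k[3], b.labels_for_k[3])


class TestSilhouette:
    def test_hand_computed_six_point_instance(self):
        """Mean silhouette at k=2 of {0,1,2} vs {10,11,12} on a line."""
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        res = hierarchical_cluster(x, k_range=range(2, 5))
        res = silhouette_sweep(x, res)
        s0 = (11.0 - 1.5) / 11.0  # point 0: a=1.5, b=11
        s1 = (10.0 - 1.0) / 10.0  # point 1: a=1,   b=10
        s2 = (9.0 - 1.5) / 9.0  # point 2: a=1.5, b=9
        expected = np.mean([s0, s1, s2, s2, s1, s0])
        assert res.silhouette_by_k[2] == pytest.approx(expected, abs=1e-12)
        assert res.optimal_k == 2

    def test_three_blobs_pick_k3(self):
        # clustered in the blobs' own coordinates, where the stated
        # 10-SD separation holds exactly
        x, _ = three_blobs(seed=11)
        res = silhouette_sweep(x, hierarchical_cluster(x))
        assert res.optimal_k == 3

    def test_two_tight_groups_give_k2_near_one(self):
        rng = np.random.default_rng(12)
        x = np.vstack([
            rng.normal(0, 1e-3, size=(10, 2)),
            rng.normal(50, 1e-3, size=(10, 2)),
        ])
        res = silhouette_sweep(x, hierarchical_cluster(x))
        assert res.optimal_k == 2
        assert res.silhouette_by_k[2] > 0.99

    def test_silhouette_values_bounded(self):
        x, _ = three_blobs(seed=13, sep=2.0)
        res = silhouette_sweep(x, hierarchical_cluster(x))
        assert all(-1.0 <= v <= 1.0 for v in res.silhouette_by_k.values())


class TestDendrogramExport:
    def test_two_leaf_newick_form(self, tmp_path):
        x = np.array([[0.0], [3.0], [50.0]])
        res = hierarchical_cluster(x, k_range=range(2, 3))
        nwk = tree_to_newick(res.linkage_tree, ["A", "B", "C"])
        assert nwk.endswith(";")
        assert nwk.count("(") == 2 and "A:" in nwk and "B:" in nwk

    def test_newick_round_trip_topology(self, tmp_path):
        import dendropy

        x, _ = three_blobs(seed=14, n=10)
        res = hierarchical_cluster(x)
        path = tmp_path / "tree.nwk"
        export_dendrogram(res, str(path), leaf_names=[f"c{i}" for i in range(30)])
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        assert len(tree.leaf_nodes()) == 30
        # ultrametric: all leaves equidistant from the root
        depths = [leaf.distance_from_root() for leaf in tree.leaf_nodes()]
        assert max(depths) - min(depths) < 1e-3

    def test_render_creates_image(self, tmp_path):
        x, _ = three_blobs(seed=15, n=5)
        res = hierarchical_cluster(x)
        img = tmp_path / "tree.png"
        export_dendrogram(res, str(tmp_path / "t.nwk"), render=str(img))
        assert img.exists() and img.stat().st_size > 0
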