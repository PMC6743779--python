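import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from paircell.core import ContractError, FeatureTable
from paircell.evaluate import (
    PairDistanceConfig,
    hierarchical_cluster,
    image_pair_distance,
    knn_loo_balanced_accuracy,
    multiloc_score,
    normalized_same_term_distance,
    variability_statistic,
)


def brute_force_knn(X, labels, k):
    """Independent oracle: explicit loops, (distance, index) sorted neighbours,
    vote ties broken by the smallest class in sorted order."""
    classes = sorted(set(labels))
    preds = []
    for i in range(len(X)):
        neigh = sorted(
            (float(np.linalg.norm(X[i] - X[j])), j) for j in range(len(X)) if j != i
        )[: min(k, len(X) - 1)]
        counts = {}
        for _, j in neigh:
            counts[labels[j]] = counts.get(labels[j], 0) + 1
        best = max(counts.values())
        preds.append(min(c for c in classes if counts.get(c, 0) == best))
    return preds


class TestKnn:
    def test_separable_clouds_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        labels = ["a"] * 20 + ["b"] * 20
        report = knn_loo_balanced_accuracy(X, labels, k=1)
        assert report.balanced_accuracy == 1.0
        assert report.per_class == {"a": 1.0, "b": 1.0}

    def test_random_labels_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 4))
            labels = list(rng.permutation(["a"] * 60 + ["b"] * 60))
            accs.append(knn_loo_balanced_accuracy(X, labels, k=11).balanced_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_matches_brute_force_including_ties(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 50))
            # integer coordinates force frequent exact distance ties
            X = rng.integers(0, 3, size=(n, 2)).astype(float)
            labels = [str(l) for l in rng.integers(0, 3, size=n)]
            k = int(rng.choice([1, 3, 5, 11]))
            report = knn_loo_balanced_accuracy(X, labels, k=k)
            assert report.predictions == brute_force_knn(X, labels, k)

    def test_missing_labels_rejected(self):
        with pytest.raises(ContractError):
            knn_loo_balanced_accuracy(np.zeros((3, 2)), ["a", None, "b"], k=1)

    def test_small_class_warns(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        with pytest.warns(UserWarning, match="k\\+1"):
            knn_loo_balanced_accuracy(X, ["a", "a", "b", "b"], k=11)

    def test_group_exclusion_blocks_same_image_neighbours(self):
        # two wells whose cells are tightly clustered by well, labels split
        # across wells: plain LOO matches within the well (perfect), the
        # leave-one-group-out control must look across wells
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = ["a", "a", "b", "b"]
        groups = ["w1", "w1", "w2", "w2"]
        plain = knn_loo_balanced_accuracy(X, labels, k=1)
        assert plain.balanced_accuracy == 1.0
        controlled = knn_loo_balanced_accuracy(X, labels, k=1, exclude_groups=groups)
        assert controlled.balanced_accuracy == 0.0  # nearest other-well cell is class b/a


class TestImagePairDistance:
    def test_three_four_five(self):
        assert image_pair_distance([[0.0, 0.0]], [[3.0, 4.0]]) == pytest.approx(5.0)

    def test_identical_singletons_zero(self):
        assert image_pair_distance([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(6, 3))
        assert image_pair_distance(A, B) == pytest.approx(image_pair_distance(B, A))

    def test_empty_side_rejected(self):
        with pytest.raises(ContractError):
            image_pair_distance(np.zeros((0, 2)), np.zeros((3, 2)))


def _clustered_feature_table(rng, n_terms=3, images_per_term=6, cells=5, spread=0.2):
    ids, cell_ids, rows, terms = [], [], [], {}
    centers = rng.normal(scale=4.0, size=(n_terms, 3))
    for t in range(n_terms):
        for g in range(images_per_term):
            gid = f"t{t}_img{g}"
            terms[gid] = f"term{t}"
            offset = rng.normal(scale=spread, size=3)
            for c in range(cells):
                ids.append(gid)
                cell_ids.append(f"c{c}")
                rows.append(centers[t] + offset + rng.normal(scale=spread, size=3))
    return FeatureTable(ids, cell_ids, "Conv3", np.array(rows)), terms


class TestNormalizedSameTermDistance:
    def test_clustered_features_negative_everywhere(self):
        rng = np.random.default_rng(0)
        table, terms = _clustered_feature_table(rng)
        cfg = PairDistanceConfig(n_same_pairs=200, n_diff_pairs_per_term=200, seed=1)
        report = normalized_same_term_distance(table, terms, cfg)
        assert set(report.per_term) == {"term0", "term1", "term2"}
        assert all(s < 0 for s in report.per_term.values())
        assert report.overall < 0

    def test_shuffled_terms_near_zero(self):
        rng = np.random.default_rng(2)
        table, terms = _clustered_feature_table(rng, images_per_term=8)
        gids = list(terms)
        shuffled = dict(zip(gids, rng.permutation([terms[g] for g in gids])))
        cfg = PairDistanceConfig(n_same_pairs=300, n_diff_pairs_per_term=300, seed=3)
        report = normalized_same_term_distance(table, shuffled, cfg)
        assert abs(report.overall) < 0.15

    def test_equal_means_score_zero(self):
        # all images coincident: mean_same == mean_diff, normalization fixed
        # point -> every score exactly 0
        table = FeatureTable(
            ["a", "a", "b", "b", "c", "c", "d", "d"],
            [f"c{i}" for i in range(8)],
            "Conv3",
            np.tile(np.array([[0.0, 1.0]]), (8, 1)),
        )
        terms = {"a": "t1", "b": "t1", "c": "t2", "d": "t2"}
        report = normalized_same_term_distance(
            table, terms, PairDistanceConfig(n_same_pairs=10, n_diff_pairs_per_term=10)
        )
        assert report.per_term == {"t1": 0.0, "t2": 0.0}
        assert report.overall == 0.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        table, terms = _clustered_feature_table(rng)
        cfg = PairDistanceConfig(n_same_pairs=100, n_diff_pairs_per_term=100, seed=5)
        r1 = normalized_same_term_distance(table, terms, cfg)
        scaled = FeatureTable(
            list(table.image_ids), list(table.cell_ids), "Conv3", table.matrix * 7.5
        )
        r2 = normalized_same_term_distance(scaled, terms, cfg)
        for t in r1.per_term:
            assert r1.per_term[t] == pytest.approx(r2.per_term[t], rel=1e-9)

    def test_single_image_term_skipped(self):
        rng = np.random.default_rng(6)
        table, terms = _clustered_feature_table(rng, n_terms=2, images_per_term=3)
        terms[next(iter(terms))] = "rare"
        with pytest.warns(UserWarning, match="single image"):
            report = normalized_same_term_distance(
                table, terms,
                PairDistanceConfig(n_same_pairs=50, n_diff_pairs_per_term=50),
            )
        assert "rare" not in report.per_term

    def test_cell_line_variant_runs(self):
        rng = np.random.default_rng(7)
        table, terms = _clustered_feature_table(rng)
        lines = {g: ("L1" if i % 2 else "L2") for i, g in enumerate(terms)}
        cfg = PairDistanceConfig(
            variant="cell_line", cell_line_constraint="different",
            n_pairs_unbalanced=100, seed=8,
        )
        report = normalized_same_term_distance(table, terms, cfg, cell_lines=lines)
        assert report.overall < 0


class TestMultilocScore:
    def test_equidistant_zero(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[2.0, 0.0]])
        assert multiloc_score(np.array([1.0, 5.0]), A, B) == pytest.approx(0.0)

    def test_sign_convention(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[10.0, 0.0]])
        assert multiloc_score(np.array([1.0, 0.0]), A, B) < 0  # closer to A
        assert multiloc_score(np.array([9.0, 0.0]), A, B) > 0  # closer to B

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        cell = rng.normal(size=3)
        assert multiloc_score(cell, A, B) == pytest.approx(-multiloc_score(cell, B, A))

    def test_centroid_cell_infinite_with_warning(self):
        A = np.array([[1.0, 1.0]])
        B = np.array([[5.0, 5.0]])
        with pytest.warns(UserWarning, match="centroid"):
            assert multiloc_score(np.array([1.0, 1.0]), A, B) == -np.inf

    def test_empty_reference_rejected(self):
        with pytest.raises(ContractError):
            multiloc_score(np.zeros(2), np.zeros((0, 2)), np.ones((1, 2)))


class TestVariabilityStatistic:
    def test_constant_scores_zero_sd(self):
        df = variability_statistic({"a": [0.3, 0.3, 0.3], "b": [-1.0, 1.0]})
        assert df.loc[df.image_id == "a", "sd"].item() == 0.0

    def test_population_sd(self):
        df = variability_statistic({"a": [-1.0, 1.0], "b": [0.0, 0.0]})
        assert df.loc[df.image_id == "a", "sd"].item() == pytest.approx(1.0)
        assert df.iloc[0]["image_id"] == "a"  # ranked descending

    def test_singleton_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="sd undefined"):
            df = variability_statistic({"a": [1.0], "b": [0.0, 1.0]})
        assert list(df.image_id) == ["b"]


class TestHierarchicalCluster:
    def test_two_rows_single_merge(self):
        result = hierarchical_cluster(np.array([[0.0, 0.0], [3.0, 4.0]]), ["a", "b"])
        assert result.linkage_matrix.shape == (1, 4)
        assert result.linkage_matrix[0, 2] == pytest.approx(5.0)

    def test_coincident_pair_merges_first(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        result = hierarchical_cluster(X, ["a", "b", "c"], n_clusters=2)
        assert result.flat["a"] == result.flat["c"] != result.flat["b"]
        assert result.linkage_matrix[0, 2] == 0.0

    def test_class_recovery(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(m, 0.3, size=(10, 4)) for m in (0.0, 5.0, 10.0)])
        truth = [0] * 10 + [1] * 10 + [2] * 10
        result = hierarchical_cluster(X, [str(i) for i in range(30)], n_clusters=3)
        assign = [result.flat[str(i)] for i in range(30)]
        assert adjusted_rand_score(truth, assign) == 1.0

    def test_newick_well_formed(self):
        rng = np.random.default_rng(1)
        result = hierarchical_cluster(rng.normal(size=(5, 3)), list("abcde"))
        text = result.to_newick()
        assert text.endswith(";")
        for leaf in "abcde":
            assert leaf in text
        # parses as a tree with 5 leaves
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(text), "newick")
        assert tree.count_terminals() == 5

    def test_nonfinite_rejected(self):
        with pytest.raises(ContractError):
            hierarchical_cluster(np.array([[np.nan, 0.0], [1.0, 1.0]]), ["a", "b"])

    def test_unsupported_linkage_rejected(self):
        with pytest.raises(ContractError):
            hierarchical_cluster(np.zeros((3, 2)), ["a", "b", "c"], linkage="single")
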