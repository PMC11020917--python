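import numpy as np
import pytest

from netrf import (
    ForestConfig,
    SamplingPrior,
    best_split,
    fit_forest,
    importance_frame,
    permutation_importance,
    predict,
    sample_candidates,
)
from netrf.forest import Tree


def brute_force_best_split(X, y, idx, candidates):
    """Enumerate every (gene, midpoint threshold) and maximize Gini decrease."""

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        q = np.mean(labels)
        return 1.0 - q**2 - (1.0 - q) ** 2

    yn = y[idx]
    n = len(idx)
    parent = gini(yn)
    best = None
    for g in candidates:
        vals = np.sort(np.unique(X[idx, g]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            mask = X[idx, g] <= thr
            dec = parent - (mask.sum() / n) * gini(yn[mask]) - ((~mask).sum() / n) * gini(yn[~mask])
            if best is None or dec > best[2] + 1e-12:
                best = (g, thr, dec)
    if best is None or best[2] <= 1e-12:
        return None
    return best


class TestSampleCandidates:
    def test_uniform_mtry_p_returns_all(self):
        prior = SamplingPrior.uniform(("a", "b", "c", "d"))
        out = sample_candidates(prior, 4, np.random.default_rng(0))
        assert np.array_equal(out, [0, 1, 2, 3])

    def test_point_mass_always_selected(self):
        prior = SamplingPrior(("a", "b", "c"), np.array([1.0, 0.0, 0.0]))
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert np.array_equal(sample_candidates(prior, 1, rng), [0])

    def test_zero_weight_genes_never_drawn(self):
        prior = SamplingPrior(("a", "b", "c", "d"), np.array([0.5, 0.0, 0.5, 0.0]))
        rng = np.random.default_rng(2)
        for _ in range(200):
            assert set(sample_candidates(prior, 2, rng)) == {0, 2}

    def test_empirical_frequencies_match_prior(self):
        # 3-SE binomial check on 100k single-candidate draws
        probs = np.array([0.7, 0.2, 0.1])
        prior = SamplingPrior(("a", "b", "c"), probs)
        rng = np.random.default_rng(3)
        n = 100_000
        counts = np.zeros(3)
        for _ in range(n):
            counts[sample_candidates(prior, 1, rng)[0]] += 1
        freq = counts / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 3 * se)


class TestBestSplit:
    def test_pure_node_returns_none(self):
        X = np.arange(8.0).reshape(-1, 1)
        y = np.zeros(8, dtype=np.int8)
        assert best_split(X, y, np.arange(8), np.array([0])) is None

    def test_perfect_separator_recovers_parent_gini(self):
        X = np.column_stack([[1.0, 2, 3, 10, 11, 12], [5.0, 5, 5, 5, 5, 5]])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        g, thr, dec = best_split(X, y, np.arange(6), np.array([0, 1]))
        assert g == 0
        assert 3.0 < thr < 10.0
        assert dec == pytest.approx(0.5)  # both children pure

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 4, (6, 2)).astype(float)
        y = rng.integers(0, 2, 6).astype(np.int8)
        idx = np.arange(6)
        cand = np.array([0, 1])
        got = best_split(X, y, idx, cand)
        want = brute_force_best_split(X, y, idx, cand)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got[2] == pytest.approx(want[2])

    def test_tie_broken_by_smallest_gene_index(self):
        col = np.array([0.0, 0, 1, 1])
        X = np.column_stack([col, col])
        y = np.array([0, 0, 1, 1], dtype=np.int8)
        g, thr, _ = best_split(X, y, np.arange(4), np.array([0, 1]))
        assert g == 0
        assert thr == pytest.approx(0.5)


class TestFitPredict:
    def test_min_node_size_n_gives_single_leaf_majority(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 7 + [1] * 3, dtype=np.int8)
        forest = fit_forest(X, y, ForestConfig(ntree=1, min_node_size=10, seed=5))
        tree = forest.trees[0]
        assert tree.n_nodes == 1
        labels, frac = predict(forest, X)
        assert set(labels) <= {0, 1}
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_separable_1d_data_fit_perfectly(self):
        X = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)]).reshape(-1, 1)
        y = np.array([0] * 10 + [1] * 10, dtype=np.int8)
        forest = fit_forest(X, y, ForestConfig(ntree=5, seed=1))
        labels, _ = predict(forest, X)
        assert np.array_equal(labels, y)

    def test_single_class_phenotype_errors(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit_forest(X, np.zeros(6, dtype=int), ForestConfig(ntree=1))

    def test_vote_tie_goes_to_class_zero(self):
        leaf = dict(
            feature=np.array([-1]),
            threshold=np.array([np.nan]),
            left=np.array([-1]),
            right=np.array([-1]),
            bootstrap_indices=np.arange(2),
            oob_indices=np.empty(0, dtype=int),
            used_features=np.empty(0, dtype=int),
        )
        t0 = Tree(counts=np.array([[2, 0]]), pred=np.array([0], dtype=np.int8), **leaf)
        t1 = Tree(counts=np.array([[0, 2]]), pred=np.array([1], dtype=np.int8), **leaf)
        forest = fit_forest(
            np.array([[0.0], [1.0]]), np.array([0, 1]), ForestConfig(ntree=2, seed=0)
        )
        forest.trees = [t0, t1]
        labels, frac = predict(forest, np.array([[0.5]]))
        assert labels[0] == 0
        assert frac[0, 1] == pytest.approx(0.5)

    def test_single_leaf_counts_predict_majority(self):
        X = np.zeros((4, 1))
        y = np.array([0, 0, 0, 1], dtype=np.int8)
        forest = fit_forest(X, y, ForestConfig(ntree=1, min_node_size=4, seed=0))
        labels, _ = predict(forest, np.array([[123.0]]))
        assert labels[0] == 0

    def test_missing_gene_column_errors(self):
        import pandas as pd

        X = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 3)), columns=["a", "b", "c"])
        y = np.array([0, 1] * 6)
        forest = fit_forest(X, y, ForestConfig(ntree=2, seed=0))
        with pytest.raises(ValueError, match="missing gene"):
            predict(forest, X[["a", "b"]])


@pytest.fixture(scope="module")
def noise_data():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(100, 30))
    y = rng.integers(0, 2, 100).astype(np.int8)
    return X, y


class TestForestContracts:
    def test_determinism_bit_identical(self, noise_data):
        X, y = noise_data
        cfg = ForestConfig(ntree=20, seed=99)
        f1, f2 = fit_forest(X, y, cfg), fit_forest(X, y, cfg)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert np.array_equal(t1.feature, t2.feature)
            assert np.array_equal(t1.threshold, t2.threshold, equal_nan=True)
            assert np.array_equal(t1.bootstrap_indices, t2.bootstrap_indices)
        i1 = permutation_importance(f1, X, y, seed=5)
        i2 = permutation_importance(f2, X, y, seed=5)
        assert np.array_equal(i1, i2)

    def test_bootstrap_size_and_oob_fraction(self, noise_data):
        X, y = noise_data
        forest = fit_forest(X, y, ForestConfig(ntree=500, min_node_size=100, seed=7))
        oob_fracs = [t.oob_indices.size / 100 for t in forest.trees]
        for tree in forest.trees:
            assert tree.bootstrap_indices.size == 100
            assert np.intersect1d(tree.bootstrap_indices, tree.oob_indices).size == 0
        assert abs(np.mean(oob_fracs) - np.exp(-1)) < 0.02

    def test_zero_weight_gene_never_splits(self, noise_data):
        X, y = noise_data
        w = np.ones(30)
        w[[3, 17]] = 0.0
        prior = SamplingPrior([f"g{i}" for i in range(30)], w / w.sum())
        forest = fit_forest(X, y, ForestConfig(ntree=30, seed=2, prior=prior))
        used = np.concatenate([t.used_features for t in forest.trees])
        assert 3 not in used and 17 not in used

    def test_uniform_prior_reduces_to_standard_rf(self, noise_data):
        # node-identical forests from the weighted path with a uniform prior
        # and the dedicated unweighted path, at the same seed
        X, y = noise_data
        prior = SamplingPrior.uniform([f"g{i}" for i in range(30)])
        fw = fit_forest(X, y, ForestConfig(ntree=10, seed=123, prior=prior))
        fu = fit_forest(X, y, ForestConfig(ntree=10, seed=123, prior=None))
        for tw, tu in zip(fw.trees, fu.trees):
            assert np.array_equal(tw.feature, tu.feature)
            assert np.array_equal(tw.threshold, tu.threshold, equal_nan=True)
            assert np.array_equal(tw.left, tu.left)
            assert np.array_equal(tw.counts, tu.counts)


class TestPermutationImportance:
    def test_unused_gene_scores_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.repeat([0.0, 1.0], 20), rng.normal(size=40)])
        y = np.repeat([0, 1], 20).astype(np.int8)
        w = np.array([1.0, 0.0])
        prior = SamplingPrior(("sig", "noise"), w)
        forest = fit_forest(X, y, ForestConfig(ntree=10, seed=0, prior=prior))
        imp = permutation_importance(forest, X, y, seed=1)
        assert imp[1] == 0.0
        assert imp[0] > 0.1

    @pytest.mark.parametrize("seed", range(10))
    def test_predictive_gene_ranks_first(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 80, 10
        X = rng.normal(size=(n, p))
        y = (X[:, 4] > 0).astype(np.int8)
        forest = fit_forest(X, y, ForestConfig(ntree=50, seed=seed))
        imp = permutation_importance(forest, X, y, seed=seed)
        assert np.argmax(imp) == 4

    def test_null_importance_centered_at_zero(self):
        # over 20 repetitions, mean importance across genes within 3 SE of 0
        means = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(60, 8))
            y = rng.integers(0, 2, 60).astype(np.int8)
            forest = fit_forest(X, y, ForestConfig(ntree=30, seed=rep))
            means.append(permutation_importance(forest, X, y, seed=rep).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_importance_frame_ranks(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = (X[:, 1] > 0).astype(np.int8)
        forest = fit_forest(X, y, ForestConfig(ntree=20, seed=0), gene_ids=("a", "b", "c"))
        frame = importance_frame(forest, permutation_importance(forest, X, y, seed=0))
        assert list(frame.columns) == ["gene_id", "importance", "rank"]
        assert frame.loc[frame["rank"] == 1, "gene_id"].item() == "b"
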