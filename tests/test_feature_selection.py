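import itertools

import numpy as np
import pytest

from gradepanel.feature_selection import (
    DiscretizationScheme,
    MRMRState,
    SelectionConfig,
    conditional_entropy,
    entropy,
    information_gain,
    mrmr_score,
    mrmr_wrapper_select,
    mutual_information,
    rank_by_ig,
)


def contingency_entropy(counts):
    """Oracle: −Σ p log2 p from raw counts."""
    c = np.asarray(counts, float).ravel()
    p = c[c > 0] / c.sum()
    return float(-(p * np.log2(p)).sum())


def oracle_conditional_entropy(labels, bins):
    labels = np.asarray(labels)
    bins = np.asarray(bins)
    h = 0.0
    for x in np.unique(bins):
        mask = bins == x
        counts = [np.sum(labels[mask] == a) for a in np.unique(labels)]
        h += mask.mean() * contingency_entropy(counts)
    return h


def oracle_mi(u, v):
    u, v = np.asarray(u), np.asarray(v)
    joint = np.zeros((len(np.unique(u)), len(np.unique(v))))
    for i, uu in enumerate(np.unique(u)):
        for j, vv in enumerate(np.unique(v)):
            joint[i, j] = np.sum((u == uu) & (v == vv))
    return (
        contingency_entropy(joint.sum(1))
        + contingency_entropy(joint.sum(0))
        - contingency_entropy(joint)
    )


class TestEntropies:
    def test_entropy_known_values(self):
        assert entropy([0, 1]) == pytest.approx(1.0)
        assert entropy([3, 3, 3]) == pytest.approx(0.0)
        assert entropy([0, 0, 0, 1]) == pytest.approx(0.811278, abs=1e-6)

    def test_entropy_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([])

    def test_conditional_entropy_known_values(self):
        y = [0, 0, 1, 1]
        assert conditional_entropy(y, y) == pytest.approx(0.0)
        assert conditional_entropy(y, [7, 7, 7, 7]) == pytest.approx(entropy(y))
        # 2x2 contingency {(x1: 2a,1b), (x2: 1a,2b)}
        labels = ["a", "a", "b", "a", "b", "b"]
        bins = ["x1", "x1", "x1", "x2", "x2", "x2"]
        assert conditional_entropy(labels, bins) == pytest.approx(0.918296, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            conditional_entropy([0, 1], [0, 1, 2])
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information([0, 1], [0])

    def test_mutual_information_known_values(self):
        u = [0, 0, 1, 1]
        v = [2, 3, 2, 3]  # independent product table
        assert mutual_information(u, v) == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(u, u) == pytest.approx(entropy(u))
        # joint counts {(0,0):5, (0,1):1, (1,0):1, (1,1):5}
        uu = [0] * 6 + [1] * 6
        vv = [0] * 5 + [1] + [0] + [1] * 5
        assert mutual_information(uu, vv) == pytest.approx(0.349978, abs=1e-6)

    def test_agreement_with_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 3, n)
            bins = rng.integers(0, 5, n)
            assert conditional_entropy(labels, bins) == pytest.approx(
                oracle_conditional_entropy(labels, bins), abs=1e-9
            )
            assert mutual_information(labels, bins) == pytest.approx(
                oracle_mi(labels, bins), abs=1e-9
            )
            assert abs(
                mutual_information(labels, bins) - mutual_information(bins, labels)
            ) < 1e-12

    def test_ig_bounded_by_class_and_feature_entropy(self, rng):
        scheme = DiscretizationScheme(n_bins=4, min_bin_count=2)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, n)
            x = rng.normal(size=n)
            ig = information_gain(y, x, DiscretizationScheme(n_bins=4, min_bin_count=2))
            bins = DiscretizationScheme(n_bins=4, min_bin_count=2).fit_transform(
                x.reshape(-1, 1)
            )[:, 0]
            assert -1e-12 <= ig <= min(entropy(y), entropy(bins)) + 1e-9
        assert scheme is not None


class TestInformationGain:
    def test_perfect_separator_on_balanced_labels(self):
        y = np.array([0] * 50 + [1] * 50)
        x = np.array([0.0] * 50 + [10.0] * 50)
        assert information_gain(y, x) == pytest.approx(1.0, abs=1e-9)

    def test_constant_feature_is_uninformative(self):
        y = np.array([0, 1] * 20)
        assert information_gain(y, np.full(40, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_gaussian_feature_matches_contingency_oracle(self, rng):
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        scheme = DiscretizationScheme(n_bins=10).fit(x.reshape(-1, 1))
        bins = scheme.transform(x.reshape(-1, 1))[:, 0]
        oracle = entropy(y) - oracle_conditional_entropy(y, bins)
        assert information_gain(y, x, scheme) == pytest.approx(oracle, abs=0.05)
        assert n == len(x)


class TestRanking:
    def test_label_identical_feature_ranked_first(self, rng):
        y = rng.integers(0, 2, 60)
        X = rng.normal(size=(60, 6))
        X[:, 0] = y * 10.0
        ranking = rank_by_ig(X, y, [f"f{i}" for i in range(6)])
        assert ranking.feature_ids[0] == "f0"
        assert ranking.scores[0] <= ranking.h_class + 1e-9

    def test_all_constant_features_tie_broken_lexicographically(self):
        y = np.array([0, 1] * 10)
        X = np.ones((20, 4))
        ranking = rank_by_ig(X, y, ["fd", "fb", "fa", "fc"])
        assert ranking.feature_ids == ["fa", "fb", "fc", "fd"]
        assert np.all(ranking.scores == 0.0)

    def test_permutation_invariance_to_sample_order(self, rng):
        y = rng.integers(0, 2, 50)
        X = rng.normal(size=(50, 8))
        perm = rng.permutation(50)
        r1 = rank_by_ig(X, y, [f"f{i}" for i in range(8)])
        r2 = rank_by_ig(X[perm], y[perm], [f"f{i}" for i in range(8)])
        assert r1.feature_ids == r2.feature_ids
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-12)

    def test_top_k_larger_than_feature_count_warns(self, rng):
        y = rng.integers(0, 2, 30)
        X = rng.normal(size=(30, 3))
        with pytest.warns(UserWarning, match="top_k"):
            ranking = rank_by_ig(X, y, ["a", "b", "c"], top_k=10)
        assert len(ranking.feature_ids) == 3


def oracle_vw(bins, y, subset, include_diagonal):
    """Direct evaluation of set-mean relevance and redundancy."""
    m = len(subset)
    v = sum(oracle_mi(y, bins[:, i]) for i in subset) / m
    w = sum(
        oracle_mi(bins[:, i], bins[:, j])
        for i in subset
        for j in subset
        if include_diagonal or i != j
    ) / (m * m)
    return v, w


class TestMRMR:
    @pytest.mark.parametrize("include_diagonal", [True, False])
    def test_score_matches_exhaustive_oracle_small_system(self, rng, include_diagonal):
        n, p = 40, 4
        y = rng.integers(0, 2, n)
        bins = rng.integers(0, 3, size=(n, p))
        for subset in itertools.chain.from_iterable(
            itertools.combinations(range(p), r) for r in range(1, p + 1)
        ):
            *prefix, cand = subset
            state = MRMRState(bins, y, [f"f{i}" for i in range(p)], include_diagonal)
            for f in prefix:
                state.add(f)
            v, w = oracle_vw(bins, y, list(subset), include_diagonal)
            assert mrmr_score(state, cand) == pytest.approx(v - w, abs=1e-9)

    def test_singleton_score_with_diagonal_is_relevance_minus_self_entropy(self, rng):
        y = rng.integers(0, 2, 50)
        bins = rng.integers(0, 4, size=(50, 1))
        state = MRMRState(bins, y, ["f0"], include_diagonal=True)
        expected = oracle_mi(y, bins[:, 0]) - entropy(bins[:, 0])
        assert mrmr_score(state, 0) == pytest.approx(expected, abs=1e-9)

    def test_duplicate_candidate_scores_below_independent_equal_relevance(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        # two equally noisy views of the class: a duplicate is maximally
        # redundant with its original, an independent view is not
        f0 = y ^ (rng.random(n) < 0.2)
        dup = f0.copy()
        indep = y ^ (rng.random(n) < 0.2)
        bins = np.column_stack([f0, dup, indep])
        state = MRMRState(bins, y, ["f0", "dup", "indep"])
        state.add(0)
        assert mrmr_score(state, 1) < mrmr_score(state, 2) + 1e-12

    def test_incremental_sums_equal_recomputation(self, rng):
        y = rng.integers(0, 2, 50)
        bins = rng.integers(0, 4, size=(50, 6))
        state = MRMRState(bins, y, [f"f{i}" for i in range(6)])
        for f in (2, 0, 5, 3):
            state.add(f)
            v, w = state.recompute_sums()
            assert state.relevance_sum == pytest.approx(v, abs=1e-9)
            assert state.redundancy_sum == pytest.approx(w, abs=1e-9)


class TestWrapper:
    def test_perfect_feature_found_and_selection_stops(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = rng.normal(size=(n, 20))
        X[:, 7] = y * 8.0 + rng.normal(0, 0.05, n)
        result = mrmr_wrapper_select(
            X, y, [f"f{i}" for i in range(20)],
            SelectionConfig(top_k=20, inner_cv_repeats=1, seed=0),
        )
        assert result.selected_feature_ids == ["f7"]
        assert result.wrapper_accuracy == pytest.approx(1.0)

    def test_subset_size_capped_and_acceptances_strictly_improve(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 30))
        cfg = SelectionConfig(top_k=30, max_features=4, inner_cv_repeats=1, seed=1)
        result = mrmr_wrapper_select(X, y, [f"f{i}" for i in range(30)], cfg)
        assert 1 <= len(result.selected_feature_ids) <= 4
        accepted = [t["wrapper_accuracy"] for t in result.trace if t["accepted"]]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))

    def test_trace_records_rejections(self, rng):
        n = 50
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 10))
        result = mrmr_wrapper_select(
            X, y, [f"f{i}" for i in range(10)],
            SelectionConfig(top_k=10, inner_cv_repeats=1, seed=0),
        )
        assert any(not t["accepted"] for t in result.trace) or len(
            result.selected_feature_ids
        ) >= 1
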