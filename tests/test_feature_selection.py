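import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heartpcg.feature_selection import (
    NCAParams,
    ReliefFParams,
    nca_objective,
    nca_weights,
    nrbmi_select,
    relieff_weights,
    top_indices,
)


# ---------------------------------------------------------------- oracles
def naive_relieff(X, y, k):
    """Independent O(N^2 D) re-implementation with explicit loops."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)

    def diff(a, i, j):
        if rng_range[a] < 1e-12:
            return 0.0
        return abs(X[i, a] - X[j, a]) / rng_range[a]

    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    W = np.zeros(d)
    m = n
    for i in range(n):
        dists = [
            (sum(diff(a, i, j) for a in range(d)), j) for j in range(n)
        ]
        for c in classes:
            pool = sorted(
                (dd, j) for dd, j in dists if y[j] == c and j != i
            )
            neigh = [j for _, j in pool[:k]]
            for a in range(d):
                contrib = sum(diff(a, i, j) for j in neigh) / (m * k)
                if c == y[i]:
                    W[a] -= contrib
                else:
                    W[a] += priors[c] / (1 - priors[y[i]]) * contrib
    return W


def naive_nca_objective(w, X, y, lam):
    """Nested-loop evaluation of the leave-one-out soft-NN objective."""
    n, d = X.shape
    f = 0.0
    for i in range(n):
        denom = 0.0
        for k in range(n):
            if k == i:
                continue
            dist = sum(w[r] ** 2 * (X[i, r] - X[k, r]) ** 2 for r in range(d))
            denom += np.exp(-dist)
        for j in range(n):
            if j == i or y[j] != y[i]:
                continue
            dist = sum(w[r] ** 2 * (X[i, r] - X[j, r]) ** 2 for r in range(d))
            f += np.exp(-dist) / denom
    return f - lam * float(np.dot(w, w))


def _standardized(X):
    return (X - X.mean(axis=0)) / X.std(axis=0)


# -------------------------------------------------------------------- NCA
class TestNCA:
    def test_duplicated_features_tie_exactly(self, separable_features):
        X, y = separable_features
        Xdup = np.column_stack([X, X[:, 0]])
        w = nca_weights(Xdup, y, NCAParams(max_iters=25))
        assert abs(w[0] - w[-1]) < 1e-6

    def test_separating_feature_outweighs_noise(self):
        """Oracle: grid search over diagonal weights confirms the
        class-separating feature carries the objective."""
        rng = np.random.default_rng(3)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = np.column_stack([y * 2.0 + 0.05 * rng.normal(size=n), rng.normal(size=n)])
        Xs = _standardized(X)
        lam = 1.0 / n
        grid = [(a, b) for a in (0.0, 0.5, 1.0, 1.5, 2.0) for b in (0.0, 0.5, 1.0, 1.5, 2.0)]
        best = max(grid, key=lambda w: naive_nca_objective(np.array(w), Xs, y, lam))
        assert best[0] > best[1]  # the oracle agrees feature 0 matters more
        w = nca_weights(X, y, NCAParams(max_iters=60))
        assert w[0] > w[1]

    def test_objective_beats_uniform_on_four_points(self):
        X = np.array([[0.0, 0.2], [0.1, 0.8], [1.0, 0.1], [1.1, 0.9]])
        y = np.array([0, 0, 1, 1])
        Xs = _standardized(X)
        lam = 0.0
        params = NCAParams(max_iters=50, regularization=0.0)
        w_sq = nca_weights(X, y, params)
        w = np.sqrt(w_sq)
        f_fit = naive_nca_objective(w, Xs, y, lam)
        f_uniform = naive_nca_objective(np.ones(2), Xs, y, lam)
        assert f_fit >= f_uniform
        # fast path and nested-loop oracle agree on the objective itself
        assert abs(nca_objective(w, Xs, y, lam) - f_fit) < 1e-9

    def test_objective_nondecreasing_over_iterations(self, separable_features):
        X, y = separable_features
        Xs = _standardized(X)
        lam = 1.0 / len(y)
        prev = -np.inf
        for iters in (1, 3, 6, 12, 25):
            w = np.sqrt(nca_weights(X, y, NCAParams(max_iters=iters)))
            f = nca_objective(w, Xs, y, lam)
            assert f >= prev - 1e-12
            prev = f

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="two classes"):
            nca_weights(np.random.default_rng(0).normal(size=(6, 2)), np.zeros(6))

    def test_zero_variance_feature_guarded(self, caplog, separable_features):
        X, y = separable_features
        X = np.column_stack([X, np.full(len(y), 7.0)])
        with caplog.at_level("WARNING"):
            w = nca_weights(X, y, NCAParams(max_iters=5))
        assert np.all(np.isfinite(w))
        assert any("zero-variance" in r.message for r in caplog.records)


# ----------------------------------------------------------------- ReliefF
class TestReliefF:
    def test_constant_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(12, 3.0), rng.normal(size=12)])
        y = np.array([0] * 6 + [1] * 6)
        w = relieff_weights(X, y, ReliefFParams(k=2))
        assert w[0] == 0.0

    def test_hand_executed_four_point_instance(self):
        """Frozen values from executing the update rule by hand over all
        four instances (k=1, equal priors, range scaling)."""
        X = np.array([[0.0, 0.3], [0.1, 0.9], [1.0, 0.1], [0.9, 0.8]])
        y = np.array([0, 0, 1, 1])
        w = relieff_weights(X, y, ReliefFParams(k=1))
        np.testing.assert_allclose(w, [0.8, -0.625], atol=1e-12)
        assert w[0] > w[1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5 * (seed + 2)
        X = rng.normal(size=(2 * n, 4))
        y = np.array([0] * n + [1] * n)
        k = min(3, n - 1)
        fast = relieff_weights(X, y, ReliefFParams(k=k))
        np.testing.assert_allclose(fast, naive_relieff(X, y, k), atol=1e-12)

    def test_duplicating_samples_keeps_ordering(self):
        """Oracle: recomputation on the doubled dataset preserves the
        ranking of features with clearly graded relevance."""
        rng = np.random.default_rng(5)
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        strengths = (3.0, 1.5, 0.0)
        X = np.column_stack([
            s * y + 0.3 * rng.normal(size=n) for s in strengths
        ])
        w1 = relieff_weights(X, y, ReliefFParams(k=3))
        w2 = relieff_weights(np.vstack([X, X]), np.concatenate([y, y]),
                             ReliefFParams(k=3))
        assert list(np.argsort(-w1)) == [0, 1, 2]
        assert list(np.argsort(-w2)) == [0, 1, 2]

    def test_k_too_large_names_class(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([0] * 6 + [1] * 2)
        with pytest.raises(ValueError, match="class 1"):
            relieff_weights(X, y, ReliefFParams(k=3))

    def test_weights_within_bounds(self, separable_features):
        X, y = separable_features
        w = relieff_weights(X, y, ReliefFParams(k=5))
        assert np.all(w >= -1.0) and np.all(w <= 1.0)


# ------------------------------------------------------------------ NRBMI
class TestNRBMI:
    def test_intersection_example(self):
        w_nca = np.zeros(10)
        w_rel = np.zeros(10)
        w_nca[[5, 2, 9]] = [3, 2, 1]
        w_rel[[2, 9, 7]] = [3, 2, 1]
        res = nrbmi_select(w_nca, w_rel, top_x=3)
        assert set(res.matched_indices.tolist()) == {2, 9}
        # ordered by descending NCA weight
        assert res.matched_indices.tolist() == [2, 9]

    def test_identical_vectors_match_everything(self):
        w = np.arange(10, dtype=float)
        res = nrbmi_select(w, w.copy(), top_x=4)
        assert len(res.matched_indices) == 4

    def test_disjoint_sets_warn_not_error(self, caplog):
        w_nca = np.array([1.0, 1.0, 0.0, 0.0])
        w_rel = np.array([0.0, 0.0, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            res = nrbmi_select(w_nca, w_rel, top_x=2)
        assert res.matched_indices.size == 0
        assert any("disjoint" in r.message for r in caplog.records)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError, match="differ in length"):
            nrbmi_select(np.ones(3), np.ones(4), top_x=2)

    def test_boundary_ties_go_to_lowest_index(self):
        w = np.array([1.0, 2.0, 2.0, 2.0])
        assert sorted(top_indices(w, 2).tolist()) == [1, 2]

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.data(),
        d=st.integers(min_value=2, max_value=30),
    )
    def test_subset_property(self, data, d):
        """The matched set is always a subset of each method's top-x set."""
        w_nca = np.array(data.draw(st.lists(
            st.floats(min_value=-5, max_value=5), min_size=d, max_size=d)))
        w_rel = np.array(data.draw(st.lists(
            st.floats(min_value=-5, max_value=5), min_size=d, max_size=d)))
        top_x = data.draw(st.integers(min_value=1, max_value=d))
        res = nrbmi_select(w_nca, w_rel, top_x)
        assert len(res.matched_indices) <= top_x
        assert set(res.matched_indices) <= set(top_indices(w_nca, top_x))
        assert set(res.matched_indices) <= set(top_indices(w_rel, top_x))


def test_feature_permutation_consistency(separable_features):
    """Permuting feature columns permutes all three outputs consistently."""
    X, y = separable_features
    perm = np.array([4, 0, 5, 2, 1, 3])
    w_nca = nca_weights(X, y, NCAParams(max_iters=15))
    w_rel = relieff_weights(X, y, ReliefFParams(k=3))
    w_nca_p = nca_weights(X[:, perm], y, NCAParams(max_iters=15))
    w_rel_p = relieff_weights(X[:, perm], y, ReliefFParams(k=3))
    np.testing.assert_allclose(w_nca_p, w_nca[perm], atol=1e-10)
    np.testing.assert_allclose(w_rel_p, w_rel[perm], atol=1e-12)
    sel = nrbmi_select(w_nca, w_rel, top_x=3)
    sel_p = nrbmi_select(w_nca_p, w_rel_p, top_x=3)
    assert [perm.tolist().index(i) for i in sel.matched_indices] == list(sel_p.matched_indices)
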