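"""Rank statistics vs enumeration oracles, FDR control, classifier behavior."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromafactor as cf
from chromafactor.io_preproc import DistanceTensor


# --- independent oracles -----------------------------------------------------

def mwu_null_distribution(n1, n2):
    """All C(n1+n2, n1) values of U1 under the exchangeable null (no ties)."""
    total = n1 + n2
    us = []
    for ranks in combinations(range(1, total + 1), n1):
        us.append(sum(ranks) - n1 * (n1 + 1) / 2)
    return np.array(us)


def mwu_exact_p(u1, n1, n2, null=None):
    """Two-sided exact p by exhaustive enumeration of rank assignments."""
    if null is None:
        null = mwu_null_distribution(n1, n2)
    u_big = max(u1, n1 * n2 - u1)
    return min(1.0, 2.0 * np.mean(null >= u_big))


def bh_stepup_oracle(p):
    """Direct step-up evaluation: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# --- Mann-Whitney U ----------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_worked_example(self):
        u, p = cf.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = cf.mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cf.mann_whitney_u([1.0], [])

    def test_matches_enumeration_for_all_small_tie_free_inputs(self):
        """Complete sweep: every rank configuration with n1, n2 <= 6."""
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                total = n1 + n2
                null = mwu_null_distribution(n1, n2)
                values = np.arange(1.0, total + 1.0)
                for chosen in combinations(range(total), n1):
                    x = values[list(chosen)]
                    y = np.delete(values, list(chosen))
                    u, p = cf.mann_whitney_u(x, y)
                    expected = mwu_exact_p(u, n1, n2, null)
                    assert p == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_group_swap_flips_u_and_preserves_p(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(2, 30)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(2, 30)).astype(float)
        u_xy, p_xy = cf.mann_whitney_u(x, y)
        u_yx, p_yx = cf.mann_whitney_u(y, x)
        center = x.size * y.size / 2
        assert (u_xy - center) == pytest.approx(-(u_yx - center))
        assert p_xy == pytest.approx(p_yx, abs=1e-12)


# --- Benjamini-Hochberg ------------------------------------------------------

class TestBHFDR:
    def test_worked_example(self):
        q = cf.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert cf.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_order_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.allclose(cf.bh_fdr(p)[perm], cf.bh_fdr(p[perm]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cf.bh_fdr([0.1, 1.2])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = rng.integers(1, 51)
            p = rng.random(m)
            if rng.random() < 0.2:
                p = np.round(p, 1)  # exercise ties
            assert np.allclose(cf.bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_q_dominates_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(30)
        assert (cf.bh_fdr(p) >= p - 1e-15).all()


# --- differential testing ----------------------------------------------------

def _shifted_block_tensor(seed, n=400, b=6, shifted=True):
    """Random symmetric maps; transcribing cells get +0.3 on block (1,2)x(4,5)."""
    rng = np.random.default_rng(seed)
    data = rng.uniform(0.3, 0.8, size=(b, b, n))
    data = 0.5 * (data + data.transpose(1, 0, 2))
    data[np.arange(b), np.arange(b), :] = 0
    labels = (np.arange(n) < n // 2).astype(int)
    if shifted:
        for i in (1, 2):
            for j in (4, 5):
                data[i, j, labels == 1] += 0.3
                data[j, i, labels == 1] += 0.3
    return DistanceTensor(data), labels


class TestPositionwise:
    def test_planted_block_detected_with_high_sensitivity(self):
        hits = []
        for seed in range(20):
            tensor, labels = _shifted_block_tensor(seed)
            result = cf.positionwise_differential(tensor, labels, threshold=0.05)
            block = [(1, 4), (1, 5), (2, 4), (2, 5)]
            hits.append(np.mean([result.significant[i, j] for i, j in block]))
        assert np.mean(hits) >= 0.9

    def test_null_fdr_controlled(self):
        fracs = []
        iu = np.triu_indices(6, 1)
        for seed in range(20):
            tensor, labels = _shifted_block_tensor(seed + 100, shifted=False)
            result = cf.positionwise_differential(tensor, labels, threshold=0.05)
            fracs.append(result.significant[iu].mean())
        assert np.mean(fracs) <= 0.05

    def test_result_symmetric_with_nan_diagonal(self):
        tensor, labels = _shifted_block_tensor(0, n=60)
        result = cf.positionwise_differential(tensor, labels)
        assert np.isnan(np.diagonal(result.q_fdr)).all()
        iu = np.triu_indices(6, 1)
        assert np.array_equal(result.q_fdr[iu], result.q_fdr.T[iu])

    def test_single_class_rejected(self):
        tensor, _ = _shifted_block_tensor(0, n=20)
        with pytest.raises(ValueError):
            cf.positionwise_differential(tensor, np.ones(20, dtype=int))


class TestComponentwise:
    def test_single_component_reduces_to_raw_p(self):
        rng = np.random.default_rng(1)
        H = rng.gamma(2, 0.5, size=(1, 200))
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        result = cf.componentwise_differential(H, labels)
        _, p = cf.mann_whitney_u(H[0, labels == 1], H[0, labels == 0])
        assert result.q_fdr[0] == pytest.approx(p)

    def test_driving_component_flagged(self):
        config = cf.SyntheticConfig(b=8, k_true=3, n=2000,
                                    label_components=(2,), label_effect=2.0,
                                    seed=300)
        H = cf.sample_weight_matrix(config)
        labels = cf.generate_transcription_labels(H, (2,), 2.0, seed=300)
        result = cf.componentwise_differential(H, labels, threshold=0.1)
        assert result.significant[2]


class TestBalancedSubset:
    def test_majority_downsampled(self):
        labels = np.array([1] * 30 + [0] * 70)
        idx = cf.balanced_subset(labels, seed=0)
        assert idx.size == 60
        assert labels[idx].sum() == 30

    def test_balanced_input_returned_whole(self):
        labels = np.tile([0, 1], 25)
        assert cf.balanced_subset(labels, seed=0).size == 50

    def test_single_class_rejected_and_deterministic(self):
        with pytest.raises(ValueError):
            cf.balanced_subset(np.zeros(10, dtype=int))
        labels = np.array([1] * 10 + [0] * 40)
        assert np.array_equal(cf.balanced_subset(labels, seed=3),
                              cf.balanced_subset(labels, seed=3))


def _separable_features(seed=0, n=400, d=5, informative=True):
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n // 2)
    X = rng.normal(0, 1, size=(n, d))
    if informative:
        X[:, 0] = labels + rng.normal(0, 0.1, n)
    return X, labels


class TestRandomForest:
    def test_informative_feature_found(self):
        X, y = _separable_features()
        report = cf.fit_rf_classifier(X, y, seed=0)
        assert report.accuracy >= 0.95
        assert report.feature_importances.argmax() == 0
        assert report.feature_importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_labels_give_chance_accuracy(self):
        X, y = _separable_features(seed=2)
        rng = np.random.default_rng(5)
        accs = [cf.fit_rf_classifier(X, y[rng.permutation(y.size)],
                                     seed=s).accuracy for s in range(5)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_deterministic_reports(self):
        X, y = _separable_features(seed=3)
        a = cf.fit_rf_classifier(X, y, seed=1)
        b = cf.fit_rf_classifier(X, y, seed=1)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.feature_importances, b.feature_importances)

    def test_unbalanced_labels_rejected(self):
        X, y = _separable_features()
        with pytest.raises(ValueError, match="balanced"):
            cf.fit_rf_classifier(X[:-1], y[:-1], seed=0)


class TestPermutation:
    def test_signal_beats_every_null(self):
        X, y = _separable_features()
        null = cf.permutation_test(X, y, n_perm=10, seed=0)
        assert null.p_value == pytest.approx(1 / 11)
        assert null.observed > max(null.null_accuracies)

    def test_null_features_center_at_chance(self):
        X, y = _separable_features(seed=7, informative=False)
        null = cf.permutation_test(X, y, n_perm=19, seed=1)
        assert null.mean == pytest.approx(0.5, abs=0.05)

    def test_zero_permutations_rejected(self):
        X, y = _separable_features()
        with pytest.raises(ValueError):
            cf.permutation_test(X, y, n_perm=0)
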