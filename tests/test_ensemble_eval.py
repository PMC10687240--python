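"""Soft voting, stratified folds and metric computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progself.ensemble_eval import (
    PAIR_FAMILY_COMBINATIONS,
    TABLE3_COMBINATIONS,
    compute_metrics,
    default_nonprogressive_subsets,
    soft_vote,
    stratified_kfold,
)


class TestSoftVote:
    def test_idempotent_on_identical_members(self):
        p = np.array([0.1, 0.5, 0.9])
        assert np.allclose(soft_vote([p, p, p]), p)

    def test_arithmetic_mean(self):
        out = soft_vote([np.array([0.2, 0.8]), np.array([0.4, 0.6])])
        assert np.allclose(out, [0.3, 0.7])

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(0)
        members = [rng.uniform(size=50) for _ in range(6)]
        got = soft_vote(members)
        expected = [
            sum(m[i] for m in members) / len(members) for i in range(50)
        ]
        assert np.allclose(got, expected, atol=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(
        st.integers(1, 5),
        st.integers(1, 30),
        st.integers(0, 10_000),
    )
    def test_bounds_between_member_extremes(self, k, n, seed):
        rng = np.random.default_rng(seed)
        members = [rng.uniform(size=n) for _ in range(k)]
        out = soft_vote(members)
        stack = np.stack(members)
        assert (out >= stack.min(axis=0) - 1e-15).all()
        assert (out <= stack.max(axis=0) + 1e-15).all()

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([np.zeros(3), np.zeros(4)])


class TestStratifiedKFold:
    def test_counting_example(self):
        """100 participants, 16% positive, k=5: 3-4 positives per fold."""
        y = np.zeros(100, dtype=int)
        y[:16] = 1
        folds = stratified_kfold(y, k=5, seed=0)
        for f in range(5):
            pos = int(y[folds == f].sum())
            assert pos in (3, 4)

    def test_partition_exact(self):
        y = np.random.default_rng(0).integers(0, 2, 97)
        folds = stratified_kfold(y, k=5, seed=1)
        assert folds.shape == (97,)
        assert set(np.unique(folds)) == set(range(5))
        # every participant in exactly one fold is implied by the assignment
        # vector; check per-fold class proportions within 1 participant
        n_pos = y.sum()
        for f in range(5):
            size = (folds == f).sum()
            pos = y[folds == f].sum()
            expected = n_pos * size / len(y)
            assert abs(pos - expected) <= 1

    def test_deterministic_per_seed(self):
        y = np.random.default_rng(2).integers(0, 2, 60)
        assert np.array_equal(
            stratified_kfold(y, 5, seed=7), stratified_kfold(y, 5, seed=7)
        )

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 1, 0, 1]), k=1)

    def test_small_class_rejected(self):
        y = np.zeros(50, dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError):
            stratified_kfold(y, k=5)


class TestComputeMetrics:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(y, p)
        assert m["auc"] == 100.0
        assert m["accuracy"] == 100.0
        assert m["recall"] == m["precision"] == m["f1"] == 100.0

    def test_no_information(self):
        y = np.array([0, 1] * 10)
        p = np.full(20, 0.5)
        assert compute_metrics(y, p)["auc"] == 50.0

    def test_auc_matches_pairwise_concordance_oracle(self):
        """Rank AUC equals the O(n^2) concordance count with midrank ties."""
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = np.round(rng.uniform(size=200), 2)  # coarse grid forces ties
        auc = compute_metrics(y, p)["auc"] / 100.0
        pos = p[y == 1]
        neg = p[y == 0]
        total = 0.0
        for a in pos:
            for b in neg:
                if a > b:
                    total += 1.0
                elif a == b:
                    total += 0.5
        assert np.isclose(auc, total / (len(pos) * len(neg)), atol=1e-12)

    def test_invariant_to_participant_reordering(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        a = compute_metrics(y, p)
        b = compute_metrics(y[perm], p[perm])
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(10), np.linspace(0, 1, 10))


def test_combination_sweep_sizes():
    """2 pairs + 4 triples + 1 quadruple; pair family adds (1,4), (2,4)."""
    assert len(TABLE3_COMBINATIONS) == 7
    sizes = sorted(len(c) for c in TABLE3_COMBINATIONS)
    assert sizes == [2, 2, 3, 3, 3, 3, 4]
    assert PAIR_FAMILY_COMBINATIONS == ((1, 4), (2, 4))


def test_default_nonprogressive_subsets_at_seven_steps():
    subsets = default_nonprogressive_subsets(7)
    assert subsets["all_steps"] == (1, 2, 3, 4, 5, 6)
    assert subsets["recent_three"] == (4, 5, 6)
    assert subsets["every_other"] == (2, 4, 6)
    assert subsets["two_steps"] == (3, 6)
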