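"""Majority vote, Pearson redundancy filtering, and the fused OBEFS run."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obefs import (
    FeatureTable,
    ObefsConfig,
    SyntheticSpec,
    generate_synthetic,
    majority_vote,
    pearson,
    redundancy_filter,
    run_obefs,
)


class TestPearson:
    def test_exact_positive_relation(self):
        assert pearson(np.array([1, 2, 3]), np.array([2, 4, 6])) == pytest.approx(1.0)

    def test_exact_negative_relation(self):
        assert pearson(np.array([1, 2, 3]), np.array([3, 2, 1])) == pytest.approx(-1.0)

    def test_worked_zero_numerator(self):
        # N*sum(xy) - sum(x)*sum(y) = 12 - 12 = 0
        assert pearson(np.array([1, 2, 3]), np.array([1, 0, 1])) == pytest.approx(0.0)

    def test_constant_vector_flagged_nan(self):
        assert np.isnan(pearson(np.array([1.0, 1.0, 1.0]), np.array([1, 2, 3])))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson(np.zeros(3), np.zeros(4))

    def test_agrees_with_covariance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            expected = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
            assert pearson(x, y) == pytest.approx(expected, abs=1e-10)


class TestMajorityVote:
    def test_counting(self):
        counts, consensus = majority_vote(
            [np.array([1, 1, 0]), np.array([1, 0, 1]), np.array([0, 1, 1])]
        )
        np.testing.assert_array_equal(counts, [2, 2, 2])
        np.testing.assert_array_equal(consensus, [1, 1, 1])

    def test_worked_column_example(self):
        counts, consensus = majority_vote(
            [np.array([1, 1, 0]), np.array([1, 0, 0]), np.array([0, 1, 1])]
        )
        np.testing.assert_array_equal(counts, [2, 2, 1])
        np.testing.assert_array_equal(consensus, [1, 1, 0])

    def test_unanimity(self):
        m = np.array([1, 0, 1])
        _, consensus = majority_vote([m, m.copy(), m.copy()])
        np.testing.assert_array_equal(consensus, m)

    def test_disjoint_masks_empty_consensus(self):
        counts, consensus = majority_vote(
            [np.array([1, 0, 0]), np.array([0, 1, 0]), np.array([0, 0, 1])]
        )
        assert consensus.sum() == 0

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([np.zeros(2), np.zeros(2)])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=5, max_size=5), min_size=3, max_size=3))
    def test_consensus_iff_two_votes(self, masks):
        counts, consensus = majority_vote([np.array(m) for m in masks])
        np.testing.assert_array_equal(consensus, counts >= 2)


def _table_with_columns(cols: np.ndarray, label: np.ndarray) -> FeatureTable:
    n = len(label)
    return FeatureTable(
        values=cols,
        subject_id=np.arange(n),
        label=label,
        feature_names=[f"c{i}" for i in range(cols.shape[1])],
        feature_family=["synthetic"] * cols.shape[1],
    )


class TestRedundancyFilter:
    def test_exact_copies_drop_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        label = (x > 0).astype(int)
        cols = np.column_stack([x, x.copy(), rng.standard_normal(40)])
        table = _table_with_columns(cols, label)
        final, dropped, _ = redundancy_filter(table, np.array([1, 1, 1]), 0.9)
        assert final.sum() == 2
        assert len(dropped) == 1
        kept, drop, r = dropped[0]
        assert {kept, drop} == {0, 1}
        assert abs(r) == pytest.approx(1.0)
        assert drop == 1  # tie on label correlation -> higher index dropped

    def test_below_threshold_is_noop(self):
        rng = np.random.default_rng(2)
        cols = rng.standard_normal((50, 4))
        table = _table_with_columns(cols, (cols[:, 0] > 0).astype(int))
        consensus = np.array([1, 1, 1, 1])
        final, dropped, _ = redundancy_filter(table, consensus, 0.9)
        np.testing.assert_array_equal(final, consensus)
        assert dropped == []

    def test_redundant_copy_with_lower_label_correlation_dropped(self):
        table, truth = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=100,
                n_informative=1,
                n_redundant=1,
                n_noise=0,
                effect_size=2.0,
                redundant_rho=0.95,
                seed=3,
            )
        )
        consensus = np.array([1, 1])
        final, dropped, _ = redundancy_filter(table, consensus, 0.9)
        assert len(dropped) == 1
        kept, drop, r = dropped[0]
        assert kept == truth.informative[0]
        assert drop == truth.redundant[0]
        assert abs(r) > 0.9

    def test_invalid_threshold(self):
        table, _ = generate_synthetic(SyntheticSpec(n_subjects_per_class=3, seed=0, n_noise=2, n_redundant=0, n_informative=1))
        with pytest.raises(ValueError):
            redundancy_filter(table, np.array([1, 1, 1]), 1.5)


class TestRunObefs:
    @pytest.fixture
    def small_cfg(self):
        return ObefsConfig(seed=4, pop_size=6, max_iters=8, lfcsa_max_iters=60, n_repeats=1)

    def test_single_feature_table_selected(self, small_cfg):
        table, _ = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=8, n_informative=1, n_redundant=0, n_noise=0,
                effect_size=2.0, seed=6,
            )
        )
        res = run_obefs(table, small_cfg)
        np.testing.assert_array_equal(res.final_mask, [1])

    def test_result_invariants_fuzzed(self, small_noisy_table, small_cfg):
        table, _ = small_noisy_table
        import dataclasses as dc

        for seed in range(5):
            res = run_obefs(table, dc.replace(small_cfg, seed=seed))
            counts = np.stack(list(res.input_masks.values())).sum(axis=0)
            np.testing.assert_array_equal(res.vote_counts, counts)
            if res.consensus_mask.sum() and (counts >= 2).any():
                np.testing.assert_array_equal(res.consensus_mask, counts >= 2)
            # final subset of consensus; never a feature no selector chose
            assert not np.any(res.final_mask & ~res.consensus_mask)
            assert not np.any(res.final_mask & (counts == 0))
            for _, _, r in res.dropped_redundant:
                assert abs(r) > small_cfg.r_threshold

    def test_same_seed_identical_end_to_end(self, small_noisy_table, small_cfg):
        table, _ = small_noisy_table
        r1 = run_obefs(table, small_cfg)
        r2 = run_obefs(table, small_cfg)
        np.testing.assert_array_equal(r1.final_mask, r2.final_mask)
        assert r1.to_dict() == r2.to_dict()

    def test_ensemble_not_worse_than_worst_selector(self):
        """Median informative-recovery F1 of the fused mask is at least the
        median F1 of the weakest single selector (seeded replicates)."""
        f1s = {"ensemble": [], "fmboa": [], "lfcsa": [], "afa": []}
        for seed in range(5):
            table, truth = generate_synthetic(
                SyntheticSpec(
                    n_subjects_per_class=10, n_informative=3, n_redundant=2,
                    n_noise=10, effect_size=2.0, seed=100 + seed,
                )
            )
            cfg = ObefsConfig(seed=seed, pop_size=8, max_iters=15, lfcsa_max_iters=150, n_repeats=1)
            res = run_obefs(table, cfg)
            inf = set(truth.informative)

            def f1(mask):
                s = set(np.flatnonzero(mask).tolist())
                if not s:
                    return 0.0
                p = len(inf & s) / len(s)
                r = len(inf & s) / len(inf)
                return 0.0 if p + r == 0 else 2 * p * r / (p + r)

            f1s["ensemble"].append(f1(res.final_mask))
            for name, m in res.input_masks.items():
                f1s[name].append(f1(m))
        worst_single = min(np.median(f1s[n]) for n in ("fmboa", "lfcsa", "afa"))
        assert np.median(f1s["ensemble"]) >= worst_single - 1e-9
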