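"""LOPO splitting, subject aggregation, the metric suite, and the pipeline."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from obefs import (
    ConfusionCounts,
    ObefsConfig,
    PipelineConfig,
    SyntheticSpec,
    aggregate_subject,
    compute_metrics,
    evaluate_pipeline,
    generate_synthetic,
    lopo_split,
)
from obefs.evaluation import _mask_hash, select_for_fold


class TestLopoSplit:
    def test_one_fold_per_subject(self):
        table, _ = generate_synthetic(SyntheticSpec(n_subjects_per_class=5, n_noise=2, n_redundant=0, n_informative=1, seed=0))
        folds = lopo_split(table)
        assert len(folds) == 10
        for _, te in folds:
            assert len(te) == 3

    def test_test_sets_partition_rows(self):
        table, _ = generate_synthetic(SyntheticSpec(n_subjects_per_class=4, n_noise=2, n_redundant=0, n_informative=1, seed=1))
        folds = lopo_split(table)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(table.n_recordings))

    def test_no_subject_leakage(self):
        table, _ = generate_synthetic(SyntheticSpec(n_subjects_per_class=4, n_noise=2, n_redundant=0, n_informative=1, seed=2))
        for tr, te in lopo_split(table):
            held_out = set(table.subject_id[te].tolist())
            assert len(held_out) == 1
            assert held_out.isdisjoint(set(table.subject_id[tr].tolist()))

    def test_single_subject_rejected(self, toy_table):
        single = toy_table.subset_rows([0, 1, 2])
        with pytest.raises(ValueError):
            lopo_split(single)


class TestAggregateSubject:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 0), 1), ((0, 0, 0), 0), ((1, 0), 1), ((0, 1, 1, 0), 1), ((0,), 0)],
    )
    def test_majority_with_positive_ties(self, votes, expected):
        assert aggregate_subject(np.array(votes)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject(np.array([]))


class TestComputeMetrics:
    def test_worked_confusion_matrix(self):
        """tp=90, fn=10, fp=5, tn=45 against hand-evaluated formulas."""
        m = compute_metrics(ConfusionCounts(tp=90, fp=5, fn=10, tn=45))
        assert m["precision"] == pytest.approx(90 / 95, abs=1e-4)
        assert m["recall"] == pytest.approx(0.9000, abs=1e-4)
        assert m["f_measure"] == pytest.approx(0.9231, abs=1e-4)
        assert m["accuracy"] == pytest.approx(90.00, abs=1e-10)
        assert m["error"] == pytest.approx(10.00, abs=1e-10)
        assert m["accuracy"] + m["error"] == 100.0
        mcc = (90 * 45 - 5 * 10) / np.sqrt(95 * 100 * 50 * 55)
        assert m["mcc"] == pytest.approx(mcc, abs=1e-12)
        assert m["mcc"] == pytest.approx(0.7826, abs=1e-4)

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(tp=7, tn=3))
        assert m["precision"] == m["recall"] == m["f_measure"] == 1.0
        assert m["accuracy"] == 100.0 and m["error"] == 0.0
        assert m["mcc"] == 1.0

    def test_inverted_prediction(self):
        m = compute_metrics(ConfusionCounts(fp=4, fn=6))
        assert m["mcc"] == -1.0

    def test_zero_denominators_flagged(self):
        m = compute_metrics(ConfusionCounts(tn=10))
        assert m["precision"] == 0.0 and m["recall"] == 0.0
        assert {"precision", "recall", "f_measure", "mcc"} <= set(m["flags"])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())

    def test_mcc_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            c = ConfusionCounts(
                tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                fn=int(((y_true == 1) & (y_pred == 0)).sum()),
                tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            )
            m = compute_metrics(c)
            expected = matthews_corrcoef(y_true, y_pred)
            assert m["mcc"] == pytest.approx(expected, abs=1e-10)

    def test_f_measure_between_precision_and_recall(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 4)))
            m = compute_metrics(c)
            assert min(m["precision"], m["recall"]) - 1e-12 <= m["f_measure"]
            assert m["f_measure"] <= max(m["precision"], m["recall"]) + 1e-12

    def test_mcc_symmetric_under_class_swap(self):
        c = ConfusionCounts(tp=12, fp=5, fn=3, tn=20)
        swapped = ConfusionCounts(tp=20, fp=3, fn=5, tn=12)
        assert compute_metrics(c)["mcc"] == pytest.approx(compute_metrics(swapped)["mcc"])


class TestEvaluatePipeline:
    def test_separable_data_high_subject_accuracy(self):
        table, _ = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=10, n_informative=3, n_redundant=0,
                n_noise=5, effect_size=3.0, seed=6,
            )
        )
        report = evaluate_pipeline(table, PipelineConfig(seed=0, selection="none"))
        assert report.counts.total == 20
        assert report.accuracy >= 95.0
        assert report.accuracy + report.error == 100.0

    def test_kpca_preprocessing_runs(self):
        table, _ = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=8, n_informative=3, n_redundant=0,
                n_noise=5, effect_size=3.0, seed=8,
            )
        )
        cfg = PipelineConfig(seed=0, selection="none", kpca_enabled=True, kpca_components=4)
        report = evaluate_pipeline(table, cfg)
        assert report.counts.total == 16
        assert report.accuracy >= 80.0

    def test_selection_inside_folds_is_recomputable(self):
        """Leakage audit: each fold's mask depends only on that fold's training
        rows and the fold seed; independent recomputation reproduces the hash."""
        table, _ = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=4, n_informative=2, n_redundant=1,
                n_noise=5, effect_size=2.5, seed=9,
            )
        )
        cfg = PipelineConfig(
            seed=1, selection="obefs",
            obefs=ObefsConfig(pop_size=4, max_iters=4, lfcsa_max_iters=20, n_repeats=1),
        )
        report = evaluate_pipeline(table, cfg)
        folds = lopo_split(table)
        for fold_index, (tr, _) in enumerate(folds):
            mask = select_for_fold(table.subset_rows(tr), cfg, fold_index)
            assert _mask_hash(mask) == report.fold_mask_hashes[fold_index]

    def test_select_once_mode_single_mask(self):
        table, _ = generate_synthetic(
            SyntheticSpec(
                n_subjects_per_class=4, n_informative=2, n_redundant=0,
                n_noise=4, effect_size=2.5, seed=10,
            )
        )
        cfg = PipelineConfig(
            seed=1, selection="obefs", select_once=True,
            obefs=ObefsConfig(pop_size=4, max_iters=4, lfcsa_max_iters=20, n_repeats=1),
        )
        report = evaluate_pipeline(table, cfg)
        assert len(set(report.fold_mask_hashes)) == 1

    def test_permuted_labels_mcc_near_zero(self):
        """Permutation null: mean subject-level MCC across seeds stays near 0."""
        mccs = []
        for seed in range(5):
            table, _ = generate_synthetic(
                SyntheticSpec(
                    n_subjects_per_class=10, n_informative=3, n_redundant=0,
                    n_noise=5, effect_size=2.0, seed=20 + seed,
                )
            )
            rng = np.random.default_rng(seed)
            subjects = np.unique(table.subject_id)
            lab = np.array([int(table.label[table.subject_id == s][0]) for s in subjects])
            perm = rng.permutation(lab)
            new = dict(zip(subjects.tolist(), perm.tolist()))
            table.label = np.array([new[s] for s in table.subject_id])
            report = evaluate_pipeline(table, PipelineConfig(seed=seed, selection="none"))
            mccs.append(report.mcc)
        assert abs(np.mean(mccs)) < 0.25
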