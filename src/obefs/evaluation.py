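"""Leave-one-person-out cross-validation and the binary metric suite.

Each fold holds out every recording of one subject; the pipeline (optional
KPCA, feature selection, classifier) is fitted on the remaining subjects'
rows only, the held-out recordings are predicted, and the subject's label is
the majority over its recording predictions (an even split resolves to the
positive class — clinically conservative).  Confusion counts are assembled at
the subject level and summarized as precision, recall, F-measure, accuracy
and error (the latter two on the percent scale, accuracy + error = 100
exactly) plus the Matthews correlation coefficient on [-1, 1].
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
from sklearn.model_selection import LeaveOneGroupOut

from ._rng import child_seed
from .classifier import predict_default, train_default
from .datamodel import FeatureTable
from .ensemble import EnsembleResult, ObefsConfig, run_obefs
from .kpca import fit_kpca, transform


@dataclasses.dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclasses.dataclass
class EvalReport:
    counts: ConfusionCounts
    precision: float
    recall: float
    f_measure: float
    accuracy: float  # percent
    error: float  # percent, = 100 - accuracy
    mcc: float  # [-1, 1]
    per_subject: list[tuple]  # (subject_id, true, predicted, recording votes)
    zero_denominator_flags: list[str]
    fold_mask_hashes: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": dataclasses.asdict(self.counts),
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "accuracy": self.accuracy,
            "error": self.error,
            "mcc": self.mcc,
            "per_subject": [
                {
                    "subject": str(s),
                    "true": int(t),
                    "predicted": int(p),
                    "votes": [int(v) for v in votes],
                }
                for s, t, p, votes in self.per_subject
            ],
            "zero_denominator_flags": self.zero_denominator_flags,
            "fold_mask_hashes": self.fold_mask_hashes,
        }


def lopo_split(table: FeatureTable) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_rows, test_rows) fold per subject, ordered by first appearance."""
    subjects = table.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-person-out needs at least 2 subjects")
    logo = LeaveOneGroupOut()
    folds = {
        table.subject_id[te[0]]: (tr, te)
        for tr, te in logo.split(table.values, table.label, groups=table.subject_id)
    }
    return [folds[s] for s in subjects]


def aggregate_subject(recording_predictions: np.ndarray) -> int:
    """Majority label over a subject's recordings; even split -> positive class."""
    preds = np.asarray(recording_predictions, dtype=int)
    if preds.size == 0:
        raise ValueError("no predictions to aggregate")
    return int(2 * preds.sum() >= preds.size)


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Precision/recall/F on [0,1]; accuracy/error in percent; MCC on [-1,1].

    Zero denominators yield 0 with a flag naming the metric.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    if total == 0:
        raise ValueError("confusion counts are all zero")
    flags: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f_measure = _ratio(2 * precision * recall, precision + recall, "f_measure")
    accuracy = 100.0 * (tp + tn) / total
    error = 100.0 - accuracy
    mcc_den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den2 == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(mcc_den2))
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "accuracy": accuracy,
        "error": error,
        "mcc": float(mcc),
        "flags": flags,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline evaluation


@dataclasses.dataclass
class PipelineConfig:
    """What happens inside each LOPO training fold.

    ``selection`` is "none" (use all features), "obefs" (full three-selector
    ensemble) — per-fold by default; ``select_once=True`` switches to the
    faster but leaky variant that selects on the full table before splitting.
    """

    seed: int = 0
    kpca_enabled: bool = False
    kpca_kernel: str = "rbf"
    kpca_components: int | None = None
    selection: str = "none"  # "none" | "obefs"
    select_once: bool = False
    obefs: ObefsConfig = dataclasses.field(default_factory=ObefsConfig)
    classifier_backend: str = "default"  # "default" | "fcbilstm"
    fcbilstm: "object | None" = None  # FcbilstmConfig when backend is fcbilstm


def _mask_hash(mask: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(mask, dtype=np.int8).tobytes()).hexdigest()


def select_for_fold(
    train_table: FeatureTable, cfg: PipelineConfig, fold_index: int
) -> np.ndarray:
    """Feature selection as performed inside one LOPO fold.

    Deterministic given the training rows, the config and the fold index; used
    both by :func:`evaluate_pipeline` and by leakage audits that recompute a
    fold's selection independently.
    """
    if cfg.selection == "none":
        return np.ones(train_table.n_features, dtype=np.int8)
    if cfg.selection != "obefs":
        raise ValueError(f"unknown selection mode {cfg.selection!r}")
    ob = dataclasses.replace(cfg.obefs, seed=child_seed(cfg.seed, "fold", fold_index))
    return run_obefs(train_table, ob).final_mask


def _fit_predict(
    train: FeatureTable, test_rows: np.ndarray, mask: np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    if cfg.classifier_backend == "default":
        model = train_default(train, mask, seed=child_seed(cfg.seed, "classifier"))
        return predict_default(model, test_rows)
    if cfg.classifier_backend == "fcbilstm":
        from .fcbilstm import FcbilstmConfig, predict_fcbilstm, train_fcbilstm

        fc = cfg.fcbilstm or FcbilstmConfig(seed=child_seed(cfg.seed, "classifier"))
        model = train_fcbilstm(train, mask, fc)
        return predict_fcbilstm(model, test_rows)
    raise ValueError(f"unknown classifier backend {cfg.classifier_backend!r}")


def evaluate_pipeline(table: FeatureTable, cfg: PipelineConfig | None = None) -> EvalReport:
    """Leave-one-person-out evaluation of the configured pipeline."""
    cfg = cfg or PipelineConfig()
    folds = lopo_split(table)
    subjects = table.subjects

    global_mask: np.ndarray | None = None
    if cfg.selection != "none" and cfg.select_once:
        if cfg.kpca_enabled:
            raise ValueError(
                "select_once with per-fold KPCA is ill-defined: the component "
                "space changes per fold; disable one of the two"
            )
        global_mask = select_for_fold(table, cfg, fold_index=0)

    counts = ConfusionCounts()
    per_subject = []
    mask_hashes = []
    for fold_index, (tr, te) in enumerate(folds):
        train = table.subset_rows(tr)
        test_values = table.values[te]
        if cfg.kpca_enabled:
            model = fit_kpca(
                train.values, kernel=cfg.kpca_kernel, n_components=cfg.kpca_components
            )
            train = train.with_values(
                transform(model, train.values),
                [f"kpc_{i}" for i in range(model.n_components)],
            )
            test_values = transform(model, table.values[te])
        if global_mask is not None:
            mask = global_mask
        else:
            mask = select_for_fold(train, cfg, fold_index)
        mask_hashes.append(_mask_hash(mask))
        votes = _fit_predict(train, test_values, mask, cfg)
        pred = aggregate_subject(votes)
        true = int(table.label[te[0]])
        if true == 1 and pred == 1:
            counts.tp += 1
        elif true == 0 and pred == 1:
            counts.fp += 1
        elif true == 1 and pred == 0:
            counts.fn += 1
        else:
            counts.tn += 1
        per_subject.append((subjects[fold_index], true, pred, list(votes)))

    metrics = compute_metrics(counts)
    return EvalReport(
        counts=counts,
        precision=metrics["precision"],
        recall=metrics["recall"],
        f_measure=metrics["f_measure"],
        accuracy=metrics["accuracy"],
        error=metrics["error"],
        mcc=metrics["mcc"],
        per_subject=per_subject,
        zero_denominator_flags=metrics["flags"],
        fold_mask_hashes=mask_hashes,
    )
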