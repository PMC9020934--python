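"""Feature tables in the speech-biomarker CSV dialect, and synthetic tables.

The data model mirrors voice-recording datasets in which every subject
contributes several recordings (rows), each described by a few hundred
precomputed acoustic features grouped into families (baseline, time-frequency,
MFCC, wavelet, TQWT, vocal-fold), with a binary diagnosis label that is
constant within subject.

The synthetic generator emulates that structure with known ground truth:
a handful of class-informative features (standardized mean shift between
classes), correlated redundant copies of them, pure-noise features, and a
per-subject random effect that correlates a subject's recordings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

FAMILIES = (
    "baseline",
    "time_frequency",
    "mfcc",
    "wavelet",
    "tqwt",
    "vocal_fold",
    "concat",
    "synthetic",
)


@dataclasses.dataclass
class FeatureTable:
    """Recordings-by-features matrix with subject ids, labels and family tags.

    Invariants (checked by :meth:`validate`): each subject carries one label
    across all of its rows; metadata lengths match the value matrix; no
    missing values.
    """

    values: np.ndarray  # (n_recordings, n_features) float64
    subject_id: np.ndarray  # (n_recordings,) int
    label: np.ndarray  # (n_recordings,) int in {0, 1}; 1 = positive/disease
    feature_names: list[str]
    feature_family: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        self.label = np.asarray(self.label, dtype=int)
        self.feature_names = list(self.feature_names)
        self.feature_family = list(self.feature_family)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_recordings(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids, in order of first appearance."""
        _, idx = np.unique(self.subject_id, return_index=True)
        return self.subject_id[np.sort(idx)]

    def validate(self) -> None:
        n, d = self.values.shape
        if len(self.subject_id) != n or len(self.label) != n:
            raise ValueError("subject_id/label length does not match value rows")
        if len(self.feature_names) != d or len(self.feature_family) != d:
            raise ValueError("feature metadata length does not match value columns")
        bad = set(self.feature_family) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown feature families: {sorted(bad)}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains missing/non-finite values")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("non-binary label")
        for sid in np.unique(self.subject_id):
            lab = np.unique(self.label[self.subject_id == sid])
            if len(lab) > 1:
                raise ValueError(
                    f"subject {sid} has conflicting labels {sorted(int(v) for v in lab)}"
                )

    # -- slicing -----------------------------------------------------------
    def subset_columns(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[:, idx],
            subject_id=self.subject_id.copy(),
            label=self.label.copy(),
            feature_names=[self.feature_names[i] for i in idx],
            feature_family=[self.feature_family[i] for i in idx],
        )

    def subset_rows(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            subject_id=self.subject_id[idx],
            label=self.label[idx],
            feature_names=list(self.feature_names),
            feature_family=list(self.feature_family),
        )

    def with_values(
        self, values: np.ndarray, feature_names: Sequence[str], family: str = "synthetic"
    ) -> "FeatureTable":
        """Same rows, new feature columns (e.g. after a KPCA projection)."""
        return FeatureTable(
            values=values,
            subject_id=self.subject_id.copy(),
            label=self.label.copy(),
            feature_names=list(feature_names),
            feature_family=[family] * values.shape[1],
        )

    def to_dataframe(self, id_column: str = "id", label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, id_column, self.subject_id)
        df[label_column] = self.label
        return df


def select_families(table: FeatureTable, families: Iterable[str]) -> FeatureTable:
    """Column-subset a table to the requested feature families, preserving order."""
    families = set(families)
    if not families:
        raise ValueError("families must be non-empty")
    present = set(table.feature_family)
    missing = families - present
    if missing:
        raise ValueError(f"feature families not present in table: {sorted(missing)}")
    idx = [i for i, fam in enumerate(table.feature_family) if fam in families]
    return table.subset_columns(idx)


# ---------------------------------------------------------------------------
# CSV I/O


def _infer_family(name: str, family_map: dict[str, str] | None, default: str) -> str:
    if family_map:
        if name in family_map:  # exact match wins
            return family_map[name]
        for prefix, fam in family_map.items():
            if name.startswith(prefix):
                return fam
    return default


def read_feature_table(
    path: str | Path,
    id_column: str = "id",
    label_column: str = "class",
    family_map: dict[str, str] | None = None,
    default_family: str = "concat",
    impute_mean: bool = False,
) -> FeatureTable:
    """Load a feature table from CSV (header row, one row per recording).

    ``family_map`` maps column-name prefixes (or exact names) to family tags;
    unmatched columns fall into ``default_family``.  If no map is given and a
    ``<path>.families.yaml`` sidecar exists (written by
    :func:`write_feature_table`), it is used.

    Rows containing non-numeric feature cells are rejected with their row
    indices reported; missing values are rejected unless ``impute_mean``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if family_map is None:
        sidecar = path.with_name(path.name + ".families.yaml")
        if sidecar.exists():
            family_map = yaml.safe_load(sidecar.read_text())
    df = pd.read_csv(path)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    # cells that were non-numeric text become NaN under coercion while the raw
    # cell was not null -> reject those rows explicitly
    nonnum = np.where((feats.isna() & df[feature_cols].notna()).any(axis=1))[0]
    if len(nonnum):
        raise ValueError(f"non-numeric feature cells in rows {nonnum.tolist()}")
    if feats.isna().any().any():
        if impute_mean:
            feats = feats.fillna(feats.mean())
        else:
            nan_rows = np.where(feats.isna().any(axis=1))[0]
            raise ValueError(f"missing feature values in rows {nan_rows.tolist()}")
    labels = pd.to_numeric(df[label_column], errors="coerce")
    if labels.isna().any() or not labels.isin([0, 1]).all():
        raise ValueError("non-binary label column")
    families = [_infer_family(c, family_map, default_family) for c in feature_cols]
    return FeatureTable(
        values=feats.to_numpy(dtype=float),
        subject_id=df[id_column].to_numpy(),
        label=labels.to_numpy(dtype=int),
        feature_names=feature_cols,
        feature_family=families,
    )


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    id_column: str = "id",
    label_column: str = "class",
    families_sidecar: bool = True,
) -> Path:
    """Write a table to CSV; by default also writes a family-map sidecar so the
    round trip preserves family tags."""
    path = Path(path)
    table.to_dataframe(id_column, label_column).to_csv(path, index=False)
    if families_sidecar:
        sidecar = path.with_name(path.name + ".families.yaml")
        sidecar.write_text(
            yaml.safe_dump(dict(zip(table.feature_names, table.feature_family)))
        )
    return path


# ---------------------------------------------------------------------------
# Synthetic tables


@dataclasses.dataclass
class SyntheticSpec:
    """Conditions for a synthetic speech-biomarker-like table.

    Defaults are the package's desk-scale benchmark conditions: 20 subjects per
    class with 3 recordings each (120 rows), 10 informative features with a
    standardized class shift of 1.2, 20 redundant copies at correlation 0.9,
    170 pure-noise features, and moderate within-subject correlation 0.3.
    """

    n_subjects_per_class: int = 20
    recordings_per_subject: int = 3
    n_informative: int = 10
    n_redundant: int = 20
    n_noise: int = 170
    effect_size: float = 1.2
    redundant_rho: float = 0.9
    within_subject_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.within_subject_rho < 1:
            raise ValueError("within_subject_rho must be in [0, 1)")
        if self.n_redundant > 0 and not 0 < self.redundant_rho < 1:
            raise ValueError("redundant_rho must be in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic table."""

    informative: list[int]
    redundant: list[int]
    noise: list[int]
    parent_of: dict[int, int]  # redundant column -> informative parent column

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["parent_of"] = {str(k): v for k, v in self.parent_of.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["parent_of"] = {int(k): v for k, v in d["parent_of"].items()}
        return cls(**d)


def generate_synthetic(spec: SyntheticSpec) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate a synthetic table with known informative/redundant/noise columns.

    Informative and noise columns have unit total variance; a per-subject
    random effect with variance ``within_subject_rho`` correlates a subject's
    recordings.  Informative columns carry class means of ±effect_size/2.
    Redundant column j is ``rho * parent + sqrt(1 - rho^2) * eps`` with its
    parent chosen round-robin among informative columns (parents include the
    class shift, so redundant copies are themselves class-correlated).
    """
    rng = np.random.default_rng(spec.seed)
    s, r = spec.n_subjects_per_class, spec.recordings_per_subject
    n_subjects = 2 * s
    n_rows = n_subjects * r
    subject_id = np.repeat(np.arange(n_subjects), r)
    label = np.repeat(np.concatenate([np.zeros(s, int), np.ones(s, int)]), r)

    w = spec.within_subject_rho
    n_base = spec.n_informative + spec.n_noise
    subj_effect = rng.standard_normal((n_subjects, n_base))
    base = np.sqrt(w) * subj_effect[subject_id] + np.sqrt(1.0 - w) * rng.standard_normal(
        (n_rows, n_base)
    )
    informative = base[:, : spec.n_informative].copy()
    noise = base[:, spec.n_informative :]
    shift = np.where(label == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    informative += shift[:, None]

    rho = spec.redundant_rho
    parents = np.arange(spec.n_redundant) % spec.n_informative
    redundant = rho * informative[:, parents] + np.sqrt(1.0 - rho**2) * rng.standard_normal(
        (n_rows, spec.n_redundant)
    )

    values = np.hstack([informative, redundant, noise])
    names = (
        [f"inf_{i:03d}" for i in range(spec.n_informative)]
        + [f"red_{j:03d}" for j in range(spec.n_redundant)]
        + [f"noise_{k:03d}" for k in range(spec.n_noise)]
    )
    table = FeatureTable(
        values=values,
        subject_id=subject_id,
        label=label,
        feature_names=names,
        feature_family=["synthetic"] * spec.n_features,
    )
    ninf, nred = spec.n_informative, spec.n_redundant
    truth = SyntheticTruth(
        informative=list(range(ninf)),
        redundant=list(range(ninf, ninf + nred)),
        noise=list(range(ninf + nred, spec.n_features)),
        parent_of={ninf + j: int(parents[j]) for j in range(nred)},
    )
    return table, truth
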