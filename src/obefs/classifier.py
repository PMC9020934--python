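"""Classification backends.

The default backend is a small deterministic k-nearest-neighbour classifier
used both for wrapper fitness and final evaluation.  The fuzzy-weighted
convolutional bidirectional LSTM backend lives in :mod:`obefs.fcbilstm` and is
optional: the pipeline runs end-to-end with the default backend alone.

Fuzzy feature weights score each feature's class relevance through Gaussian
membership functions: for each class the feature's class-conditional
distribution is summarized by a Gaussian (mu, sigma), and the weight is the
complement of the Bhattacharyya overlap between the two class Gaussians —
near the floor for a feature whose class distributions coincide, close to 1
for a cleanly separating feature.  The measure is invariant to affine
rescaling of the feature column.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .datamodel import FeatureTable

WEIGHT_FLOOR = 1e-3
SIGMA_FLOOR_REL = 1e-6  # relative to the pooled per-feature scale


@dataclasses.dataclass
class FuzzyWeights:
    mu: np.ndarray  # (2, n_features) class-conditional Gaussian centers
    sigma: np.ndarray  # (2, n_features), floored at a relative epsilon
    weight: np.ndarray  # (n_features,) in (0, 1]


def fuzzy_weights(table: FeatureTable) -> FuzzyWeights:
    """Per-feature fuzzy relevance weights from class-conditional Gaussians."""
    labels = np.unique(table.label)
    if len(labels) < 2:
        raise ValueError("fuzzy weights need both classes present")
    X = table.values
    mu = np.stack([X[table.label == c].mean(axis=0) for c in (0, 1)])
    sigma = np.stack([X[table.label == c].std(axis=0) for c in (0, 1)])
    pooled = X.std(axis=0)
    floor = SIGMA_FLOOR_REL * np.where(pooled > 0, pooled, 1.0)
    sigma = np.maximum(sigma, floor)

    # Bhattacharyya coefficient between the two class Gaussians
    s2sum = sigma[0] ** 2 + sigma[1] ** 2
    bc = np.sqrt(2.0 * sigma[0] * sigma[1] / s2sum) * np.exp(
        -((mu[0] - mu[1]) ** 2) / (4.0 * s2sum)
    )
    weight = np.maximum(1.0 - bc, WEIGHT_FLOOR)
    return FuzzyWeights(mu=mu, sigma=sigma, weight=weight)


@dataclasses.dataclass
class DefaultModel:
    columns: np.ndarray
    seed: int
    _clf: KNeighborsClassifier | None = None


def train_default(table: FeatureTable, mask: np.ndarray, seed: int = 0) -> DefaultModel:
    """Fit the default k-NN backend on the masked columns."""
    mask = np.asarray(mask, dtype=np.int8)
    if not mask.any():
        raise ValueError("mask selects no features")
    cols = np.flatnonzero(mask)
    k = min(5, table.n_recordings)
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(table.values[:, cols], table.label)
    return DefaultModel(columns=cols, seed=seed, _clf=clf)


def predict_default(model: DefaultModel, rows: np.ndarray) -> np.ndarray:
    """Predict per-recording labels for raw feature rows (all columns)."""
    if model._clf is None:
        raise RuntimeError("predict called before train")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return model._clf.predict(rows[:, model.columns])
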