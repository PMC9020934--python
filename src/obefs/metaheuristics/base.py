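"""Shared encoding, wrapper fitness, and run bookkeeping for the selectors.

Each individual carries a continuous position vector with one entry per
selectable feature, bounded in ``[low_k, up_k]`` (unit bounds by default).
The binary mask is the componentwise indicator ``position > threshold``.
Fitness is the subject-grouped k-fold CV accuracy of a small wrapper
classifier trained on the masked columns, optionally blended with a parsimony
term; evaluations are memoized by mask so re-visiting a subset costs nothing.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier

from ..datamodel import FeatureTable


@dataclasses.dataclass
class FitnessConfig:
    """Wrapper-fitness settings.

    ``size_penalty`` blends in a parsimony term:
    ``fitness = (1 - w) * accuracy + w * (1 - n_active / n_features)``.
    The default ``w = 0`` scores by classifier accuracy alone.

    ``n_repeats`` averages the CV accuracy over that many independent
    subject-grouped fold splits.  With a single fixed split a long search can
    overfit the fold structure (cherry-picking features that separate those
    particular folds by chance); averaging over splits makes luck much harder
    to exploit while real signal still scores well.
    """

    n_splits: int = 3
    n_repeats: int = 1
    n_neighbors: int = 5
    size_penalty: float = 0.0
    seed: int = 0


@dataclasses.dataclass
class SelectorConfig:
    pop_size: int = 25
    max_iters: int = 100
    binarize_threshold: float = 0.5
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    empty_mask_policy: str = "activate_argmax"  # or "reject"
    stall_patience: int | None = None  # early stop if best stalls this long
    fitness: FitnessConfig = dataclasses.field(default_factory=FitnessConfig)

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        low, up = self.bounds
        if not low < up:
            raise ValueError("bounds must satisfy low < up")


@dataclasses.dataclass
class Candidate:
    position: np.ndarray
    mask: np.ndarray
    fitness: float | None = None


@dataclasses.dataclass
class SelectorResult:
    best_mask: np.ndarray
    best_fitness: float
    trace: list[float]  # per-iteration best fitness, entry 0 = after init
    evaluations: int  # distinct wrapper-classifier fits
    seed: int
    algorithm: str = ""

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_mask": "".join(str(int(b)) for b in self.best_mask),
            "best_fitness": self.best_fitness,
            "trace": list(map(float, self.trace)),
            "evaluations": self.evaluations,
            "seed": self.seed,
        }


def binarize(
    position: np.ndarray,
    threshold: float = 0.5,
    empty_mask_policy: str = "activate_argmax",
) -> np.ndarray:
    """Threshold a continuous position into a binary mask.

    An all-zero mask is handled by policy: ``activate_argmax`` switches on the
    feature with the largest position entry; ``reject`` raises.
    """
    position = np.asarray(position, dtype=float)
    mask = (position > threshold).astype(np.int8)
    if not mask.any():
        if empty_mask_policy == "activate_argmax":
            mask[int(np.argmax(position))] = 1
        elif empty_mask_policy == "reject":
            raise ValueError("binarization produced an empty mask")
        else:
            raise ValueError(f"unknown empty_mask_policy {empty_mask_policy!r}")
    return mask


def init_positions(
    n: int, bounds: tuple[np.ndarray | float, np.ndarray | float], dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform initialization: position_k = mu * (up_k - low_k) + low_k, mu ~ U(0,1)."""
    low = np.broadcast_to(np.asarray(bounds[0], dtype=float), (dim,))
    up = np.broadcast_to(np.asarray(bounds[1], dtype=float), (dim,))
    if not (up > low).all():
        raise ValueError("bounds must satisfy up_k > low_k for all k")
    mu = rng.uniform(size=(n, dim))
    return mu * (up - low) + low


class WrapperFitness:
    """Memoized subject-grouped CV accuracy of a k-NN wrapper classifier.

    Folds are fixed once at construction (StratifiedGroupKFold on subject ids,
    shuffled by the fitness seed), so fitness is a deterministic function of
    the mask within one selector run.
    """

    def __init__(self, table: FeatureTable, cfg: FitnessConfig | None = None):
        self.table = table
        self.cfg = cfg or FitnessConfig()
        if len(np.unique(table.label)) < 2:
            raise ValueError("wrapper fitness needs both classes present")
        n_subjects = len(np.unique(table.subject_id))
        n_splits = max(2, min(self.cfg.n_splits, n_subjects))
        self.folds = []
        for rep in range(max(1, self.cfg.n_repeats)):
            splitter = StratifiedGroupKFold(
                n_splits=n_splits, shuffle=True, random_state=self.cfg.seed + 9973 * rep
            )
            self.folds.extend(
                splitter.split(table.values, table.label, groups=table.subject_id)
            )
        self.evaluations = 0
        self._cache: dict[bytes, float] = {}

    def accuracy(self, mask: np.ndarray) -> float:
        X, y = self.table.values, self.table.label
        cols = np.flatnonzero(mask)
        correct = 0
        for tr, te in self.folds:
            k = min(self.cfg.n_neighbors, len(tr))
            clf = KNeighborsClassifier(n_neighbors=k)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            correct += int((clf.predict(X[np.ix_(te, cols)]) == y[te]).sum())
        return correct / sum(len(te) for _, te in self.folds)

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=np.int8)
        if not mask.any():
            raise ValueError("cannot evaluate an empty mask")
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        self.evaluations += 1
        acc = self.accuracy(mask)
        w = self.cfg.size_penalty
        fit = (1.0 - w) * acc + w * (1.0 - mask.sum() / mask.size)
        self._cache[key] = fit
        return fit


def evaluate_fitness(
    mask: np.ndarray, table: FeatureTable, fitness_cfg: FitnessConfig | None = None
) -> float:
    """One-shot wrapper-fitness evaluation (builds a throwaway memo)."""
    return WrapperFitness(table, fitness_cfg)(mask)


def make_fitness(
    table: FeatureTable, cfg: SelectorConfig
) -> tuple[WrapperFitness, Callable[[np.ndarray], np.ndarray]]:
    """Build the memoized fitness and the binarizer bound to a config."""
    fit = WrapperFitness(table, cfg.fitness)

    def to_mask(position: np.ndarray) -> np.ndarray:
        return binarize(position, cfg.binarize_threshold, cfg.empty_mask_policy)

    return fit, to_mask


def clip(position: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(position, bounds[0], bounds[1])


class RunState:
    """Elitist bookkeeping shared by the three selector loops."""

    def __init__(self, algorithm: str, seed: int):
        self.algorithm = algorithm
        self.seed = seed
        self.best_mask: np.ndarray | None = None
        self.best_position: np.ndarray | None = None
        self.best_fitness = -np.inf
        self.trace: list[float] = []
        self._stall = 0

    def offer(self, position: np.ndarray, mask: np.ndarray, fitness: float) -> bool:
        if fitness > self.best_fitness:
            self.best_fitness = fitness
            self.best_mask = mask.copy()
            self.best_position = position.copy()
            return True
        return False

    def close_iteration(self) -> None:
        if self.trace and self.best_fitness <= self.trace[-1]:
            self._stall += 1
        else:
            self._stall = 0
        self.trace.append(self.best_fitness)

    def stalled(self, patience: int | None) -> bool:
        return patience is not None and self._stall >= patience

    def result(self, evaluations: int) -> SelectorResult:
        assert self.best_mask is not None
        return SelectorResult(
            best_mask=self.best_mask,
            best_fitness=self.best_fitness,
            trace=self.trace,
            evaluations=evaluations,
            seed=self.seed,
            algorithm=self.algorithm,
        )
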