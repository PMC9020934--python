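"""Consensus feature selection: majority vote + correlation redundancy filter.

The three selectors each return a binary feature mask.  A feature enters the
consensus set when at least two of the three masks select it.  Within the
consensus set, pairwise Pearson correlations are computed; pairs with
``|r| > r_threshold`` are scanned in descending |r| and, for each pair with
both members still active, the member less correlated with the class label is
dropped.  The surviving set is the final ensemble selection.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import metaheuristics as mh
from ._rng import child_seed
from .datamodel import FeatureTable

SELECTOR_ORDER = ("fmboa", "lfcsa", "afa")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

        r = (N Σxy − Σx Σy) / sqrt((N Σx² − (Σx)²)(N Σy² − (Σy)²))

    Returns NaN (flagged sentinel) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    num = n * (x * y).sum() - x.sum() * y.sum()
    den2 = (n * (x * x).sum() - x.sum() ** 2) * (n * (y * y).sum() - y.sum() ** 2)
    if den2 <= 0:
        return float("nan")
    return float(np.clip(num / np.sqrt(den2), -1.0, 1.0))


def majority_vote(masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature vote counts and the >= 2-of-3 consensus mask."""
    if len(masks) != 3:
        raise ValueError("majority vote expects exactly 3 masks")
    arr = np.asarray(masks, dtype=int)
    if arr.ndim != 2:
        raise ValueError("masks must have equal lengths")
    counts = arr.sum(axis=0)
    return counts, (counts >= 2).astype(np.int8)


def _label_relevance(values: np.ndarray, label: np.ndarray, col: int) -> float:
    """|point-biserial correlation| of a column with the class label; NaN -> -inf
    so uninformative constant columns lose every tie."""
    r = pearson(values[:, col], label.astype(float))
    return -np.inf if np.isnan(r) else abs(r)


def redundancy_filter(
    table: FeatureTable,
    consensus_mask: np.ndarray,
    r_threshold: float = 0.9,
) -> tuple[np.ndarray, list[tuple[int, int, float]], np.ndarray]:
    """Drop one member of every highly correlated consensus pair.

    Pairs with ``|r| > r_threshold`` are processed in descending |r| (ties by
    pair index); the member with the lower absolute label correlation is
    dropped (tie -> the higher column index).  Returns the final mask, the
    drop log ``(kept, dropped, r)`` in original column indices, and the
    correlation matrix over consensus features.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (0, 1)")
    consensus_mask = np.asarray(consensus_mask, dtype=np.int8)
    cols = np.flatnonzero(consensus_mask)
    m = len(cols)
    corr = np.zeros((m, m))
    for a in range(m):
        corr[a, a] = 1.0
        for b in range(a + 1, m):
            corr[a, b] = corr[b, a] = pearson(
                table.values[:, cols[a]], table.values[:, cols[b]]
            )

    pairs = [
        (a, b)
        for a in range(m)
        for b in range(a + 1, m)
        if not np.isnan(corr[a, b]) and abs(corr[a, b]) > r_threshold
    ]
    pairs.sort(key=lambda ab: -abs(corr[ab[0], ab[1]]))

    active = np.ones(m, dtype=bool)
    dropped: list[tuple[int, int, float]] = []
    for a, b in pairs:
        if not (active[a] and active[b]):
            continue
        rel_a = _label_relevance(table.values, table.label, int(cols[a]))
        rel_b = _label_relevance(table.values, table.label, int(cols[b]))
        if rel_a > rel_b:
            keep, drop = a, b
        elif rel_b > rel_a:
            keep, drop = b, a
        else:  # tie: drop the higher column index
            keep, drop = (a, b) if cols[a] < cols[b] else (b, a)
        active[drop] = False
        dropped.append((int(cols[keep]), int(cols[drop]), float(corr[a, b])))

    final = np.zeros_like(consensus_mask)
    final[cols[active]] = 1
    return final, dropped, corr


@dataclasses.dataclass
class EnsembleResult:
    input_masks: dict[str, np.ndarray]
    vote_counts: np.ndarray
    consensus_mask: np.ndarray
    correlation_matrix: np.ndarray  # over consensus features
    dropped_redundant: list[tuple[int, int, float]]
    final_mask: np.ndarray
    selector_results: dict[str, mh.SelectorResult] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_masks": {
                k: "".join(str(int(b)) for b in v) for k, v in self.input_masks.items()
            },
            "vote_counts": self.vote_counts.tolist(),
            "consensus_mask": "".join(str(int(b)) for b in self.consensus_mask),
            "dropped_redundant": [list(t) for t in self.dropped_redundant],
            "final_mask": "".join(str(int(b)) for b in self.final_mask),
            "selectors": {k: r.to_dict() for k, r in self.selector_results.items()},
        }


@dataclasses.dataclass
class ObefsConfig:
    """Settings of a full ensemble selection run.

    Per-selector and per-fitness seeds are derived deterministically from
    ``seed`` (see :mod:`obefs._rng`); each selector therefore also sees its
    own internal CV fold split, which decorrelates the chance structure the
    three selectors can exploit.
    """

    seed: int = 0
    pop_size: int = 20
    max_iters: int = 120  # generations for the population-sweep selectors
    lfcsa_max_iters: int | None = None  # None -> 20 * max_iters (one proposal/iter)
    binarize_threshold: float = 0.5
    size_penalty: float = 0.1  # mild parsimony weight of the wrapper fitness
    n_repeats: int = 2  # repeated-CV splits inside the wrapper fitness
    r_threshold: float = 0.9
    empty_consensus_policy: str = "union"  # or "error"
    filter_order: str = "vote_then_filter"  # or "filter_then_vote"
    lfcsa: mh.LfcsaParams = dataclasses.field(
        # step scale suited to flipping bits of unit-bounded mask positions
        default_factory=lambda: mh.LfcsaParams(alpha0=200.0, prb_a=0.1)
    )
    afa: mh.AfaParams = dataclasses.field(default_factory=mh.AfaParams)
    fmboa: mh.FmboaParams = dataclasses.field(default_factory=mh.FmboaParams)

    def selector_config(self, index: int, name: str = "") -> mh.SelectorConfig:
        # an LFCSA iteration costs ~1 evaluation vs ~pop_size for the
        # population-sweep selectors; scale its iteration count to roughly
        # equalize the evaluation budgets
        iters = self.max_iters
        if name == "lfcsa":
            iters = self.lfcsa_max_iters or 20 * self.max_iters
        return mh.SelectorConfig(
            pop_size=self.pop_size,
            max_iters=iters,
            binarize_threshold=self.binarize_threshold,
            seed=child_seed(self.seed, "selector", index),
            fitness=mh.FitnessConfig(
                size_penalty=self.size_penalty,
                n_repeats=self.n_repeats,
                seed=child_seed(self.seed, "fitness", index),
            ),
        )


def run_obefs(table: FeatureTable, config: ObefsConfig | None = None) -> EnsembleResult:
    """Run the three selectors, vote, and filter redundancy."""
    config = config or ObefsConfig()
    results: dict[str, mh.SelectorResult] = {}
    for idx, name in enumerate(SELECTOR_ORDER):
        cfg = config.selector_config(idx, name)
        params = getattr(config, name)
        results[name] = mh.SELECTORS[name](table, cfg, params)
    masks = {name: results[name].best_mask for name in SELECTOR_ORDER}

    if config.filter_order == "filter_then_vote":
        filtered = {}
        for name, mask in masks.items():
            fmask, _, _ = redundancy_filter(table, mask, config.r_threshold)
            filtered[name] = fmask
        vote_input = [filtered[n] for n in SELECTOR_ORDER]
    elif config.filter_order == "vote_then_filter":
        vote_input = [masks[n] for n in SELECTOR_ORDER]
    else:
        raise ValueError(f"unknown filter_order {config.filter_order!r}")

    counts, consensus = majority_vote(vote_input)
    if not consensus.any():
        if config.empty_consensus_policy == "union":
            consensus = (counts >= 1).astype(np.int8)
        else:
            raise ValueError("majority vote produced an empty consensus set")

    if config.filter_order == "vote_then_filter":
        final, dropped, corr = redundancy_filter(table, consensus, config.r_threshold)
    else:
        final, dropped, corr = consensus, [], np.zeros((0, 0))
        # per-selector filtering already removed redundancy; still report the
        # consensus correlation matrix for provenance
        _, _, corr = redundancy_filter(table, consensus, config.r_threshold)
        final = consensus

    if not final.any():  # filtering can never empty a non-empty set, but guard
        final = consensus.copy()
    return EnsembleResult(
        input_masks=masks,
        vote_counts=counts,
        consensus_mask=consensus,
        correlation_matrix=corr,
        dropped_redundant=dropped,
        final_mask=final,
        selector_results=results,
    )
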