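"""Monarch butterfly optimization over feature masks.

Canonical MBO: the population is sorted by fitness and split into two
subpopulations ("lands") of sizes ceil(p*N) and N - ceil(p*N).

- Migration operator: every member of land 1 is rebuilt dimension-wise from
  random donors — from land 1 when ``rand * peri <= p``, else from land 2.
- Butterfly adjusting operator: every member of land 2 takes each dimension
  from the global best when ``rand <= p``, else from a random land-2 member;
  when ``rand > bar`` a Lévy-scaled perturbation dampened by ``s_max / t^2``
  is added.

Elitism re-injects the previous best over the worst newcomer, so the fitness
trace is non-decreasing.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ..datamodel import FeatureTable
from .base import RunState, SelectorConfig, SelectorResult, init_positions, make_fitness
from .levy import levy_sample


@dataclasses.dataclass
class FmboaParams:
    p: float = 5.0 / 12.0  # subpopulation partition ratio
    peri: float = 1.2  # migration period
    bar: float = 5.0 / 12.0  # butterfly adjusting rate
    s_max: float = 1.0  # max walk step of the adjusting perturbation
    beta_levy: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("partition ratio p must be in (0, 1)")
        if self.peri <= 0 or self.s_max <= 0:
            raise ValueError("peri and s_max must be > 0")


def _partition_sizes(p: float, n: int) -> tuple[int, int]:
    """Subpopulation sizes, clamped so both lands keep at least one member."""
    n1 = min(max(int(math.ceil(p * n)), 1), n - 1)
    return n1, n - n1


def run_fmboa(
    table: FeatureTable,
    config: SelectorConfig,
    params: FmboaParams | None = None,
) -> SelectorResult:
    params = params or FmboaParams()
    rng = np.random.default_rng(config.seed)
    fit, to_mask = make_fitness(table, config)
    n, dim = config.pop_size, table.n_features
    n1, _ = _partition_sizes(params.p, n)

    positions = init_positions(n, config.bounds, dim, rng)
    masks = [to_mask(p_) for p_ in positions]
    fitness = np.array([fit(m) for m in masks])

    state = RunState("fmboa", config.seed)
    for i in range(n):
        state.offer(positions[i], masks[i], fitness[i])
    state.close_iteration()

    for t in range(1, config.max_iters + 1):
        order = np.argsort(-fitness, kind="stable")
        positions = positions[order]
        fitness = fitness[order]
        land1, land2 = positions[:n1], positions[n1:]
        new_positions = positions.copy()

        # migration operator rebuilds land 1
        for i in range(n1):
            r = rng.uniform(size=dim) * params.peri
            from1 = r <= params.p
            donors1 = rng.integers(len(land1), size=dim)
            donors2 = rng.integers(len(land2), size=dim)
            new_positions[i] = np.where(
                from1,
                land1[donors1, np.arange(dim)],
                land2[donors2, np.arange(dim)],
            )

        # butterfly adjusting operator rebuilds land 2
        alpha_t = params.s_max / (t * t)
        for i in range(n1, n):
            take_best = rng.uniform(size=dim) <= params.p
            donors2 = rng.integers(len(land2), size=dim)
            cand = np.where(
                take_best,
                state.best_position,
                land2[donors2, np.arange(dim)],
            )
            perturb = rng.uniform(size=dim) > params.bar
            if perturb.any():
                dx = levy_sample(dim, params.beta_levy, rng)
                cand = cand + perturb * alpha_t * (dx - 0.5)
            new_positions[i] = np.clip(cand, config.bounds[0], config.bounds[1])

        positions = new_positions
        masks = [to_mask(p_) for p_ in positions]
        fitness = np.array([fit(m) for m in masks])
        for i in range(n):
            state.offer(positions[i], masks[i], fitness[i])

        # elitism: re-inject the global best over the current worst
        worst = int(np.argmin(fitness))
        if state.best_fitness > fitness[worst]:
            positions[worst] = state.best_position.copy()
            masks[worst] = state.best_mask.copy()
            fitness[worst] = state.best_fitness

        state.close_iteration()
        if state.stalled(config.stall_patience):
            break

    return state.result(fit.evaluations)
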