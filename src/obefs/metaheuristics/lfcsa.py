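"""Lévy-flight cuckoo search over feature masks.

Each nest is a continuous position whose thresholded mask is a candidate
feature subset.  Per iteration a randomly chosen nest proposes a Lévy-flight
replacement (accepted greedily if fitter), then a fraction ``prb_a`` of the
worst nests are abandoned and redrawn uniformly.  The best nest is tracked
elitistically, so the fitness trace is non-decreasing.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..datamodel import FeatureTable
from .base import RunState, SelectorConfig, SelectorResult, init_positions, make_fitness
from .levy import levy_step


@dataclasses.dataclass
class LfcsaParams:
    prb_a: float = 0.25  # fraction of worst nests abandoned per iteration
    alpha0: float = 1.0  # base step size scaling the Levy move
    beta_levy: float = 1.5  # stability index of the Levy generator
    abandonment: str = "worst_fraction"  # or "bernoulli"
    psi: str = "uniform"  # modulation vector of the Levy move

    def __post_init__(self) -> None:
        if not 0.0 <= self.prb_a <= 1.0:
            raise ValueError("prb_a must be in [0, 1]")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")


def run_lfcsa(
    table: FeatureTable,
    config: SelectorConfig,
    params: LfcsaParams | None = None,
) -> SelectorResult:
    params = params or LfcsaParams()
    rng = np.random.default_rng(config.seed)
    fit, to_mask = make_fitness(table, config)
    n, dim = config.pop_size, table.n_features

    positions = init_positions(n, config.bounds, dim, rng)
    masks = [to_mask(p) for p in positions]
    fitness = np.array([fit(m) for m in masks])

    state = RunState("lfcsa", config.seed)
    for i in range(n):
        state.offer(positions[i], masks[i], fitness[i])
    state.close_iteration()

    for _ in range(config.max_iters):
        # Levy-flight proposal at a random nest, greedy acceptance
        j = int(rng.integers(n))
        proposal = levy_step(
            positions[j],
            state.best_position,
            params.alpha0,
            params.beta_levy,
            rng,
            config.bounds,
            params.psi,
        )
        pmask = to_mask(proposal)
        pfit = fit(pmask)
        if pfit > fitness[j]:
            positions[j], masks[j], fitness[j] = proposal, pmask, pfit
            state.offer(proposal, pmask, pfit)

        # abandonment: redraw the worst nests (or per-nest Bernoulli)
        if params.abandonment == "worst_fraction":
            k = int(np.floor(params.prb_a * n))
            victims = np.argsort(fitness, kind="stable")[:k]
        else:
            victims = np.flatnonzero(rng.uniform(size=n) < params.prb_a)
        for v in victims:
            positions[v] = init_positions(1, config.bounds, dim, rng)[0]
            masks[v] = to_mask(positions[v])
            fitness[v] = fit(masks[v])
            state.offer(positions[v], masks[v], fitness[v])

        state.close_iteration()
        if state.stalled(config.stall_patience):
            break

    return state.result(fit.evaluations)
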