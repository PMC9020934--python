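"""Adaptive-step firefly algorithm over feature masks.

Light intensity is the wrapper fitness.  Each firefly is attracted to every
brighter firefly with strength ``beta0 * exp(-gamma r^2)`` and additionally
takes a Gaussian randomization step scaled by its own adaptive step
``alpha_i``, which is recomputed every generation from its fitness gap to the
global best and a two-generation personal-best history:

    h_i(t)      = 1 / ((f_pi(t-1) - f_pi(t-2))^2 + 1)
    alpha_i(t+1) = 1 - 1 / (sqrt((f_best - f_i)^2 + h_i(t)^2) + 1)

so fireflies far from the best explore with larger steps while converged
fireflies settle.  A firefly's position accumulates all attraction moves of
its inner loop and is re-evaluated once per generation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..datamodel import FeatureTable
from .base import RunState, SelectorConfig, SelectorResult, init_positions, make_fitness


@dataclasses.dataclass
class AfaParams:
    beta0: float = 1.0  # attractiveness at distance 0
    gamma: float | None = None  # light absorption; None -> 1/D (distance scales with dim)
    alpha_init: float = 0.5  # step used while the history is still filling
    step_form: str = "sqrt"  # "sqrt" (Euclidean) or "plain" reading of the step rule

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.alpha_init < 1.0:
            raise ValueError("alpha_init must be in [0, 1)")


def attractiveness(r: float, beta0: float = 1.0, gamma: float = 1.0) -> float:
    """Firefly pull strength beta0 * exp(-gamma r^2) at distance r."""
    if r < 0:
        raise ValueError("distance must be >= 0")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(beta0 * np.exp(-gamma * r * r))


def adaptive_step(
    f_best: float,
    f_i: float,
    f_pi_prev1: float,
    f_pi_prev2: float,
    form: str = "sqrt",
) -> float:
    """Self-adaptive randomization step alpha_i(t+1) in [0, 1)."""
    h = 1.0 / ((f_pi_prev1 - f_pi_prev2) ** 2 + 1.0)
    gap2 = (f_best - f_i) ** 2
    if form == "sqrt":
        return 1.0 - 1.0 / (np.sqrt(gap2 + h * h) + 1.0)
    if form == "plain":
        return 1.0 - 1.0 / (gap2 + h * h + 1.0)
    raise ValueError(f"unknown step form {form!r}")


def firefly_move(
    x_i: np.ndarray,
    x_j: np.ndarray,
    beta0: float,
    gamma: float,
    alpha_i: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
    printed_sign: bool = False,
) -> np.ndarray:
    """Move firefly i toward the brighter firefly j, plus Gaussian noise.

    ``printed_sign=True`` restores the repulsive (x_i - x_j) attraction term
    for fidelity experiments; the default attracts i to j.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    r2 = float(((x_i - x_j) ** 2).sum())
    beta = beta0 * np.exp(-gamma * r2)
    direction = (x_i - x_j) if printed_sign else (x_j - x_i)
    new = x_i + beta * direction + alpha_i * rng.normal(size=x_i.shape)
    return np.clip(new, bounds[0], bounds[1])


def run_afa(
    table: FeatureTable,
    config: SelectorConfig,
    params: AfaParams | None = None,
) -> SelectorResult:
    params = params or AfaParams()
    rng = np.random.default_rng(config.seed)
    fit, to_mask = make_fitness(table, config)
    n, dim = config.pop_size, table.n_features
    gamma = params.gamma if params.gamma is not None else 1.0 / dim

    positions = init_positions(n, config.bounds, dim, rng)
    masks = [to_mask(p) for p in positions]
    fitness = np.array([fit(m) for m in masks])

    # per-firefly personal best and its two-generation history; the history is
    # bootstrapped with the initial fitness so generations 0-1 use alpha_init
    personal_best = fitness.copy()
    history = [[fitness[i], fitness[i]] for i in range(n)]  # [f_pi(t-1), f_pi(t-2)]
    alpha = np.full(n, params.alpha_init)

    state = RunState("afa", config.seed)
    for i in range(n):
        state.offer(positions[i], masks[i], fitness[i])
    state.close_iteration()

    for t in range(config.max_iters):
        for i in range(n):
            moved = False
            for j in range(n):
                if fitness[j] > fitness[i]:
                    positions[i] = firefly_move(
                        positions[i],
                        positions[j],
                        params.beta0,
                        gamma,
                        alpha[i],
                        rng,
                        config.bounds,
                    )
                    moved = True
            if moved:
                masks[i] = to_mask(positions[i])
                fitness[i] = fit(masks[i])
                state.offer(positions[i], masks[i], fitness[i])
            # shift the personal-best history
            history[i][1] = history[i][0]
            history[i][0] = personal_best[i]
            personal_best[i] = max(personal_best[i], fitness[i])
        if t >= 1:  # history now holds two real generations
            for i in range(n):
                alpha[i] = adaptive_step(
                    state.best_fitness,
                    fitness[i],
                    history[i][0],
                    history[i][1],
                    params.step_form,
                )
        state.close_iteration()
        if state.stalled(config.stall_patience):
            break

    return state.result(fit.evaluations)
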