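"""Lévy-flight step generation by Mantegna's method.

A symmetric Lévy-stable step of index ``beta`` is approximated by the ratio
``u / |v|^(1/beta)`` of two Gaussians, where ``v`` is standard normal and
``u`` has standard deviation ``phi_hat`` (the Mantegna factor)

    phi_hat = [ Gamma(1+b) sin(pi b / 2)
                / ( Gamma((1+b)/2) * b * 2^((b-1)/2) ) ]^(1/b).

The resulting step-length distribution has a power-law tail
``P(|s| > x) ~ x^(-beta)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma as _gamma


def mantegna_factor(beta: float) -> float:
    """Standard deviation of the numerator Gaussian in Mantegna's generator.

    Valid for stability index ``1 < beta <= 3``.
    """
    if not 1.0 < beta <= 3.0:
        raise ValueError("beta must satisfy 1 < beta <= 3")
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_sample(
    shape: int | tuple[int, ...], beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Raw heavy-tailed steps s = u / |v|^(1/beta)."""
    sigma_u = mantegna_factor(beta)
    u = rng.normal(0.0, sigma_u, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1.0 / beta)


def levy_step(
    position: np.ndarray,
    best_position: np.ndarray,
    alpha0: float,
    beta_levy: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
    psi: str = "uniform",
) -> np.ndarray:
    """One Lévy-flight move of a cuckoo nest toward/around the best nest.

    The raw Lévy draw is scaled by ``0.01 * (position - best_position)`` — so
    the best nest itself is a fixed point of the move — then modulated
    componentwise by a random vector Psi (uniform(0,1) by default, Gaussian
    selectable) and clipped into bounds.
    """
    position = np.asarray(position, dtype=float)
    best_position = np.asarray(best_position, dtype=float)
    if position.shape != best_position.shape:
        raise ValueError("position and best_position shapes differ")
    raw = levy_sample(position.shape, beta_levy, rng)
    step = alpha0 * 0.01 * raw * (position - best_position)
    if psi == "uniform":
        mod = rng.uniform(size=position.shape)
    elif psi == "gaussian":
        mod = rng.normal(size=position.shape)
    else:
        raise ValueError(f"unknown psi {psi!r}")
    return np.clip(position + step * mod, bounds[0], bounds[1])
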