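"""Enhanced sparrow search algorithm (EGSSA).

Three modifications to the baseline SSA producer/incumbent machinery:

* hunger-state producer foraging (safe branch): the producer position is
  remapped coordinate-wise through 1 - exp(-|best - current|), scaled by a
  fresh uniform draw and the adjustment parameter ``o`` — once the gap to
  the incumbent underflows, coordinates collapse to exactly 0, which is
  what lets origin-optimum functions bottom out at 0.0 in double precision;
* a decaying, sign-randomized balance factor (alarmed branch) steering
  producers toward or past the incumbent best;
* a greedy Cauchy perturbation of the incumbent at the end of every
  iteration, which never worsens it.

Scrounger and scout stages are identical to the baseline SSA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ssa import (
    Objective,
    SwarmConfig,
    SwarmState,
    _begin_iteration,
    _clip,
    _finish_iteration,
    _select_scouts,
    init_population,
    scout_update,
    scrounger_update,
)

__all__ = [
    "EGSSAConfig",
    "phfs_update",
    "eeps_update",
    "pes_perturb",
    "optimize_egssa",
]


@dataclass
class EGSSAConfig(SwarmConfig):
    o: float = 2.0  # hunger-map adjustment parameter
    delta: float = 2.0  # balance-factor control parameter
    cauchy_scale: float = 1.0
    # experimental variants, off by default
    phfs_anchored: bool = False  # add the hunger term to the incumbent instead
    cauchy_per_coordinate: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.o <= 0:
            raise ValueError("o must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy_scale must be positive")


def phfs_update(
    producer_position: np.ndarray,
    best_position: np.ndarray,
    config: EGSSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hunger-state producer move (safe branch).

    new_d = (1 - exp(-|best_d - current_d|)) * u_d * o with u_d ~ U(0, 1)
    per coordinate; the result is an absolute position, clipped to the box.
    """
    gap = np.abs(best_position - producer_position)
    u = rng.uniform(size=gap.shape)
    term = (1.0 - np.exp(-gap)) * u * config.o
    new = best_position + term if config.phfs_anchored else term
    return np.clip(new, config.lower, config.upper)


def eeps_update(
    producer_position: np.ndarray,
    best_position: np.ndarray,
    iter: int,
    config: EGSSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balance-factor producer move (alarmed branch).

    bf = (2 para - 1) * delta * (1 - iter/iter_max) with para ~ U(0, 1)
    drawn once per call; new = bf * (best - current) + Q with Q standard
    normal per coordinate.
    """
    para = rng.uniform()
    bf = (2.0 * para - 1.0) * (config.delta * (1.0 - iter / config.iter_max))
    q = rng.standard_normal(producer_position.shape)
    new = bf * (best_position - producer_position) + q
    return np.clip(new, config.lower, config.upper)


def pes_perturb(
    best_position: np.ndarray,
    best_fitness: float,
    objective: Objective,
    config: EGSSAConfig,
    rng: np.random.Generator,
):
    """Greedy Cauchy perturbation of the incumbent; never worsens.

    r = tan((u - 0.5) pi) is a standard Cauchy draw (one scalar per call);
    the candidate best + r * best is clipped, evaluated, and kept only if
    strictly better.
    """
    size = best_position.shape if config.cauchy_per_coordinate else None
    u = rng.uniform(size=size)
    r = config.cauchy_scale * np.tan((u - 0.5) * np.pi)
    candidate = np.clip(best_position + r * best_position, config.lower, config.upper)
    f = float(objective(candidate))
    if f < best_fitness:
        return candidate, f
    return best_position, best_fitness


def _producer_update_egssa(
    state: SwarmState, config: EGSSAConfig, producers: np.ndarray
) -> None:
    producers = np.asarray(producers, dtype=int)
    if producers.size == 0:
        raise ValueError("empty producer set")
    r2 = state.rng.uniform()
    if r2 < config.ST:
        for idx in producers:
            state.positions[idx] = phfs_update(
                state.positions[idx], state.best_position, config, state.rng
            )
    else:
        for idx in producers:
            state.positions[idx] = eeps_update(
                state.positions[idx],
                state.best_position,
                state.iteration,
                config,
                state.rng,
            )
    _clip(state.positions, config)


def optimize_egssa(objective: Objective, config: EGSSAConfig):
    """Run the enhanced SSA; returns (best_position, best_fitness, curve)."""
    state = init_population(config, objective)
    scroungers = np.arange(config.n_producers, config.pop_size)
    for t in range(1, config.iter_max + 1):
        state.iteration = t
        producers = _begin_iteration(state, config)
        _producer_update_egssa(state, config, producers)
        state.best_producer_position = state.positions[0].copy()
        scrounger_update(state, config, scroungers)
        scout_update(state, config, _select_scouts(state, config))
        _finish_iteration(state, objective)
        state.best_position, state.best_fitness = pes_perturb(
            state.best_position, state.best_fitness, objective, config, state.rng
        )
        state.convergence_curve.append(state.best_fitness)
    return state.best_position, state.best_fitness, np.array(state.convergence_curve)
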