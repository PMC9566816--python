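"""Baseline sparrow search algorithm (SSA).

Population machinery for a minimization problem on a box. Each iteration
the population is sorted by fitness (ascending); the top PD fraction act
as producers, the rest as scroungers, and a random SD fraction additionally
react as scouts. The RNG draw order is fixed: one alarm value R2, then the
per-producer draws in rank order, then the per-scrounger draws, then the
scout selection, then the per-scout draws. All positions are clipped to
the box after every update stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "init_population",
    "producer_update_ssa",
    "scrounger_update",
    "scout_update",
    "optimize_ssa",
    "save_curve",
]

Objective = Callable[[np.ndarray], float]
Bound = Union[float, Sequence[float]]


@dataclass
class SwarmConfig:
    pop_size: int
    dim: int
    lower: Bound
    upper: Bound
    iter_max: int
    ST: float = 0.8  # warning threshold
    PD: float = 0.20  # producer fraction
    SD: float = 0.10  # scout (detection) fraction
    epsilon: float = 1e-50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.iter_max < 1:
            raise ValueError("iter_max must be >= 1")
        if not 0.5 < self.ST < 1.0:
            raise ValueError("ST must lie in (0.5, 1)")
        if not 0.0 < self.PD <= 1.0:
            raise ValueError("PD must lie in (0, 1]")
        if not 0.0 < self.SD <= 1.0:
            raise ValueError("SD must lie in (0, 1]")
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def n_producers(self) -> int:
        return math.ceil(self.PD * self.pop_size)

    @property
    def n_scouts(self) -> int:
        return math.ceil(self.SD * self.pop_size)


@dataclass
class SwarmState:
    positions: np.ndarray
    fitnesses: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    worst_position: np.ndarray
    worst_fitness: float
    rng: np.random.Generator
    best_producer_position: Optional[np.ndarray] = None
    iteration: int = 0
    convergence_curve: list = field(default_factory=list)


def _clip(positions: np.ndarray, config: SwarmConfig) -> None:
    np.clip(positions, config.lower, config.upper, out=positions)


def _evaluate_all(objective: Objective, positions: np.ndarray) -> np.ndarray:
    fit = np.array([objective(row) for row in positions], dtype=float)
    if not np.all(np.isfinite(fit)):
        bad = int(np.flatnonzero(~np.isfinite(fit))[0])
        raise RuntimeError(
            f"objective returned a non-finite value {fit[bad]} at {positions[bad]}"
        )
    return fit


def init_population(config: SwarmConfig, objective: Objective) -> SwarmState:
    """Uniform random initialization on the box; evaluates every member."""
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(
        config.lower, config.upper, size=(config.pop_size, config.dim)
    )
    fitnesses = _evaluate_all(objective, positions)
    i_best = int(np.argmin(fitnesses))
    i_worst = int(np.argmax(fitnesses))
    return SwarmState(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[i_best].copy(),
        best_fitness=float(fitnesses[i_best]),
        worst_position=positions[i_worst].copy(),
        worst_fitness=float(fitnesses[i_worst]),
        rng=rng,
    )


def _sort_by_fitness(state: SwarmState) -> None:
    order = np.argsort(state.fitnesses, kind="stable")
    state.positions = state.positions[order]
    state.fitnesses = state.fitnesses[order]


def producer_update_ssa(state: SwarmState, config: SwarmConfig, producers: np.ndarray) -> None:
    """Producer move: shrink toward the origin when safe, diffuse when alarmed.

    Draws one alarm value R2 per call. If R2 < ST, producer i (1-based rank)
    is multiplied coordinate-wise by exp(-i / (alpha * iter_max)) with
    alpha ~ U(0, 1] per producer; otherwise each producer takes a shared
    normal step Q broadcast over coordinates.
    """
    producers = np.asarray(producers, dtype=int)
    if producers.size == 0:
        raise ValueError("empty producer set")
    rng = state.rng
    r2 = rng.uniform()
    ranks = np.arange(1, producers.size + 1, dtype=float)
    if r2 < config.ST:
        alpha = 1.0 - rng.random(producers.size)  # uniform on (0, 1]
        mult = np.exp(-ranks / (alpha * config.iter_max))
        state.positions[producers] *= mult[:, None]
    else:
        q = rng.standard_normal(producers.size)
        state.positions[producers] += q[:, None]
    _clip(state.positions, config)


def scrounger_update(state: SwarmState, config: SwarmConfig, scroungers: np.ndarray) -> None:
    """Scrounger move following the best producer position.

    Individuals ranked worse than n/2 fly off toward the current worst with
    a normal factor; the rest step toward the best producer along the
    pseudo-inverse direction A+ . L, which for a 1 x d row A of random +-1
    entries reduces to a scalar step (|gap| . A^T) / d added to every
    coordinate.
    """
    scroungers = np.asarray(scroungers, dtype=int)
    if scroungers.size == 0:
        return
    rng = state.rng
    n = config.pop_size
    posi_a = state.best_producer_position
    q = rng.standard_normal(scroungers.size)
    signs = rng.integers(0, 2, size=(scroungers.size, config.dim)) * 2 - 1
    for j, idx in enumerate(scroungers):
        rank = idx + 1  # 1-based rank in the sorted population
        if rank > n / 2:
            state.positions[idx] = q[j] * np.exp(
                (state.worst_position - state.positions[idx]) / rank**2
            )
        else:
            gap = np.abs(state.positions[idx] - posi_a)
            step = float(gap @ signs[j]) / config.dim
            state.positions[idx] = posi_a + step
    _clip(state.positions, config)


def scout_update(state: SwarmState, config: SwarmConfig, scouts: np.ndarray) -> None:
    """Danger reaction of a random subset: jump near the incumbent best, or
    drift away from the worst when already at the incumbent fitness."""
    scouts = np.asarray(scouts, dtype=int)
    if scouts.size == 0:
        return
    rng = state.rng
    beta = rng.standard_normal(scouts.size)
    kappa = rng.uniform(-1.0, 1.0, size=scouts.size)
    for j, idx in enumerate(scouts):
        fi = state.fitnesses[idx]
        if fi > state.best_fitness:
            state.positions[idx] = state.best_position + beta[j] * np.abs(
                state.positions[idx] - state.best_position
            )
        elif fi == state.best_fitness:
            gap = np.abs(state.positions[idx] - state.worst_position)
            denom = (fi - state.worst_fitness) + config.epsilon
            state.positions[idx] = state.positions[idx] + kappa[j] * (gap / denom)
    _clip(state.positions, config)


def _select_scouts(state: SwarmState, config: SwarmConfig) -> np.ndarray:
    return state.rng.choice(config.pop_size, size=config.n_scouts, replace=False)


def _finish_iteration(state: SwarmState, objective: Objective) -> None:
    state.fitnesses = _evaluate_all(objective, state.positions)
    i_best = int(np.argmin(state.fitnesses))
    i_worst = int(np.argmax(state.fitnesses))
    if state.fitnesses[i_best] < state.best_fitness:
        state.best_fitness = float(state.fitnesses[i_best])
        state.best_position = state.positions[i_best].copy()
    state.worst_fitness = float(state.fitnesses[i_worst])
    state.worst_position = state.positions[i_worst].copy()


def _begin_iteration(state: SwarmState, config: SwarmConfig) -> np.ndarray:
    _sort_by_fitness(state)
    state.worst_position = state.positions[-1].copy()
    state.worst_fitness = float(state.fitnesses[-1])
    return np.arange(config.n_producers)


def optimize_ssa(objective: Objective, config: SwarmConfig):
    """Run the baseline SSA; returns (best_position, best_fitness, curve)."""
    state = init_population(config, objective)
    n_prod = config.n_producers
    scroungers = np.arange(n_prod, config.pop_size)
    for t in range(1, config.iter_max + 1):
        state.iteration = t
        producers = _begin_iteration(state, config)
        producer_update_ssa(state, config, producers)
        state.best_producer_position = state.positions[0].copy()
        scrounger_update(state, config, scroungers)
        scout_update(state, config, _select_scouts(state, config))
        _finish_iteration(state, objective)
        state.convergence_curve.append(state.best_fitness)
    return state.best_position, state.best_fitness, np.array(state.convergence_curve)


def save_curve(path, curve) -> None:
    """Write a convergence curve as two-column delimited text."""
    arr = np.column_stack([np.arange(1, len(curve) + 1), np.asarray(curve, dtype=float)])
    np.savetxt(path, arr, delimiter="\t", header="iteration\tbest_fitness", comments="")
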