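"""Bald Eagle Search (BES): a three-phase population metaheuristic.

BES minimises a black-box objective over a box-bounded continuous
space. Each iteration runs three phases mimicking a bald eagle hunt:

* **select** — each individual moves toward the best-so-far position,
  perturbed by the population centroid:
  ``P_new = P_best + α·γ·(P_mean − P_i)`` with γ ~ U(0, 1);
* **search** — individuals spiral around the centroid and their
  neighbour using max-normalised Archimedean-spiral coordinates
  (θ = a·π·rand, r = θ + R·rand, x ∝ r·sinθ, y ∝ r·cosθ);
* **swoop** — a dive toward the prey using hyperbolic spiral
  coordinates (r = θ, x ∝ r·sinhθ, y ∝ r·coshθ):
  ``P_new = rand·P_best + x1·(P_i − c1·P_mean) + y1·(P_i − c2·P_best)``.

Candidates are accepted greedily (only if strictly better), so the
best-so-far fitness history is monotone nonincreasing. Positions are
clipped to the bounds after every move; the population centroid is
recomputed after every accepted move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BESConfig", "BESState", "BESResult", "optimize",
           "select_phase", "search_phase", "swoop_phase",
           "spiral_coords", "hyperbolic_spiral_coords"]

log = logging.getLogger(__name__)


class BESError(RuntimeError):
    pass


@dataclass(frozen=True)
class BESConfig:
    """Search-space bounds and algorithm parameters.

    ``alpha`` ∈ [1.5, 2] controls the pull toward the centroid in the
    select phase; ``a_corner`` ∈ [5, 10] the spiral corner angle;
    ``R_cycles`` ∈ [0.5, 2] the number of search cycles; ``c1, c2`` ∈
    [1, 2] the swoop intensities toward centre and best.
    """

    lower: tuple
    upper: tuple
    pop_size: int = 30
    iterations: int = 100
    alpha: float = 2.0
    a_corner: float = 10.0
    R_cycles: float = 1.5
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", tuple(lower))
        object.__setattr__(self, "upper", tuple(upper))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D and the same length")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if np.any(lower >= upper):
            raise ValueError("each lower bound must be below its upper bound")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2 (search phase uses a neighbour)")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not 1.5 <= self.alpha <= 2.0:
            raise ValueError("alpha must lie in [1.5, 2]")
        if not 5.0 <= self.a_corner <= 10.0:
            raise ValueError("a_corner must lie in [5, 10]")
        if not 0.5 <= self.R_cycles <= 2.0:
            raise ValueError("R_cycles must lie in [0.5, 2]")
        if not (1.0 <= self.c1 <= 2.0 and 1.0 <= self.c2 <= 2.0):
            raise ValueError("c1 and c2 must lie in [1, 2]")

    @property
    def bounds(self):
        return np.asarray(self.lower, float), np.asarray(self.upper, float)


@dataclass
class BESState:
    positions: np.ndarray          # (pop, dim)
    fitness: np.ndarray            # (pop,)
    best_position: np.ndarray      # (dim,)
    best_fitness: float
    history: list = field(default_factory=list)

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass(frozen=True)
class BESResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    state: BESState


def spiral_coords(rand_theta, rand_r, a: float, R: float):
    """Max-normalised Archimedean spiral coordinates of the search phase.

    θ_i = a·π·rand, r_i = θ_i + R·rand; xr = r·sin θ, yr = r·cos θ;
    returned x, y are divided by max|xr|, max|yr| so both lie in [−1, 1].
    """
    theta = a * np.pi * np.asarray(rand_theta, float)
    r = theta + R * np.asarray(rand_r, float)
    xr = r * np.sin(theta)
    yr = r * np.cos(theta)
    return xr / np.max(np.abs(xr)), yr / np.max(np.abs(yr))


def hyperbolic_spiral_coords(rand_theta, a: float):
    """Max-normalised hyperbolic spiral coordinates of the swoop phase.

    θ_i = a·π·rand, r_i = θ_i; xr = r·sinh θ, yr = r·cosh θ, then
    max-|·| normalisation as in the search phase.
    """
    theta = a * np.pi * np.asarray(rand_theta, float)
    r = theta
    xr = r * np.sinh(theta)
    yr = r * np.cosh(theta)
    return xr / np.max(np.abs(xr)), yr / np.max(np.abs(yr))


def _try_accept(state: BESState, i: int, candidate: np.ndarray, objective, lower, upper):
    candidate = np.clip(candidate, lower, upper)
    f = objective(candidate)
    if not np.isfinite(f):
        log.debug("rejecting non-finite objective value at individual %d", i)
        return
    if f < state.fitness[i]:
        state.positions[i] = candidate
        state.fitness[i] = f
        if f < state.best_fitness:
            state.best_fitness = float(f)
            state.best_position = candidate.copy()


def select_phase(state: BESState, config: BESConfig, rng, objective) -> BESState:
    """P_new = P_best + α·γ·(P_mean − P_i), fresh γ ~ U(0,1) per eagle."""
    lower, upper = config.bounds
    for i in range(len(state.positions)):
        gamma = rng.random()
        cand = state.best_position + config.alpha * gamma * (
            state.mean_position - state.positions[i]
        )
        _try_accept(state, i, cand, objective, lower, upper)
    return state


def search_phase(state: BESState, config: BESConfig, rng, objective) -> BESState:
    """Spiral move around centroid and (circularly wrapped) neighbour."""
    lower, upper = config.bounds
    n = len(state.positions)
    x, y = spiral_coords(rng.random(n), rng.random(n), config.a_corner, config.R_cycles)
    for i in range(n):
        neighbour = state.positions[(i + 1) % n]
        cand = (
            state.positions[i]
            + x[i] * (state.positions[i] - state.mean_position)
            + y[i] * (state.positions[i] - neighbour)
        )
        _try_accept(state, i, cand, objective, lower, upper)
    return state


def swoop_phase(state: BESState, config: BESConfig, rng, objective) -> BESState:
    """Hyperbolic-spiral dive toward the best position."""
    lower, upper = config.bounds
    n = len(state.positions)
    x1, y1 = hyperbolic_spiral_coords(rng.random(n), config.a_corner)
    scale = rng.random(n)
    for i in range(n):
        cand = (
            scale[i] * state.best_position
            + x1[i] * (state.positions[i] - config.c1 * state.mean_position)
            + y1[i] * (state.positions[i] - config.c2 * state.best_position)
        )
        _try_accept(state, i, cand, objective, lower, upper)
    return state


def _initialize(objective, config: BESConfig, rng) -> BESState:
    lower, upper = config.bounds
    positions = lower + rng.random((config.pop_size, lower.size)) * (upper - lower)
    fitness = np.array([objective(p) for p in positions], dtype=float)
    finite = np.isfinite(fitness)
    if not finite.any():
        raise BESError("objective non-finite at every initial position")
    fitness[~finite] = np.inf
    best = int(np.argmin(fitness))
    return BESState(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
    )


def optimize(objective, config: BESConfig) -> BESResult:
    """Run BES to minimise ``objective`` within the configured bounds.

    The population is initialised uniformly within bounds under the
    configured seed; each iteration runs select → search → swoop with
    greedy acceptance. ``history`` holds the best-so-far fitness after
    initialisation and after each iteration (length iterations + 1) and
    is monotone nonincreasing by construction. Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    state = _initialize(objective, config, rng)
    state.history.append(state.best_fitness)
    for _ in range(config.iterations):
        select_phase(state, config, rng, objective)
        search_phase(state, config, rng, objective)
        swoop_phase(state, config, rng, objective)
        state.history.append(state.best_fitness)
    return BESResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=np.asarray(state.history),
        state=state,
    )
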