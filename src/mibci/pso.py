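"""Global-best particle swarm optimization with a constant inertia weight.

Particles move through a box-bounded search space under three pulls:
inertia ``w`` on their current velocity, a cognitive pull ``c1`` toward
their personal best and a social pull ``c2`` toward the swarm's global
best.  Per particle, dimension and iteration:

    v <- w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
    x <- x + v

with ``r1, r2 ~ U(0, 1)`` drawn independently per dimension.  Velocities
are clamped elementwise to ``[v_min, v_max]`` (default 0.2 times the box
width); positions are clipped to the box and the offending velocity
component zeroed, so candidate points always stay legal.  The convention
is maximization — fitness here is typically a classification accuracy.

The plain update without inertia is the special case ``w = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class PSOConfig:
    """Swarm setting; bounds define the search box per dimension.

    Defaults follow the common BCI parameter-tuning setup: inertia
    ``w = 0.8`` with learning factors ``c1 = 1.5`` and ``c2 = 1.7``.
    """

    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    n_particles: int = 50
    max_iterations: int = 100
    inertia_w: float = 0.8
    c1: float = 1.5
    c2: float = 1.7
    v_min: np.ndarray | None = None
    v_max: np.ndarray | None = None
    seed: int = 0
    #: optional early stop: quit after `patience` iterations with gbest
    #: improvement below `tolerance` (disabled when patience is None)
    tolerance: float = 0.0
    patience: int | None = None

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower_bounds, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper_bounds, dtype=float))
        object.__setattr__(self, "lower_bounds", lo)
        object.__setattr__(self, "upper_bounds", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ConfigurationError("bounds must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ConfigurationError("lower_bounds must be < upper_bounds elementwise")
        if self.n_particles < 1 or self.max_iterations < 1:
            raise ConfigurationError("n_particles and max_iterations must be positive")
        if self.inertia_w <= 0:
            raise ConfigurationError("inertia_w must be positive")
        if self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("c1 and c2 must be nonnegative")
        span = hi - lo
        vmax = (
            np.atleast_1d(np.asarray(self.v_max, dtype=float))
            if self.v_max is not None
            else 0.2 * span
        )
        vmin = (
            np.atleast_1d(np.asarray(self.v_min, dtype=float))
            if self.v_min is not None
            else -0.2 * span
        )
        object.__setattr__(self, "v_max", vmax)
        object.__setattr__(self, "v_min", vmin)
        if vmin.shape != lo.shape or vmax.shape != lo.shape:
            raise ConfigurationError("velocity clamps must match the bound dimension")
        if not (np.all(vmin <= 0) and np.all(vmax >= 0)):
            raise ConfigurationError("velocity clamps must satisfy v_min <= 0 <= v_max")

    @property
    def n_dims(self) -> int:
        return self.lower_bounds.size


@dataclass
class Swarm:
    """Mutable swarm state: positions, velocities, personal and global bests."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0


@dataclass(frozen=True)
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    #: gbest fitness after initialization and after each iteration
    trace: np.ndarray
    #: swarm-mean fitness alongside the trace (same length)
    mean_trace: np.ndarray
    n_iterations: int = 0


def _evaluate(fitness: Callable, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[~np.isfinite(vals)][0]
        raise ValidationError(f"fitness returned a non-finite value at x = {bad}")
    return vals


def initialize_swarm(cfg: PSOConfig, rng_seed: int | None = None) -> Swarm:
    """Uniform random positions in the box and velocities within the clamps."""
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    shape = (cfg.n_particles, cfg.n_dims)
    x = rng.uniform(cfg.lower_bounds, cfg.upper_bounds, size=shape)
    v = rng.uniform(cfg.v_min, cfg.v_max, size=shape)
    return Swarm(
        positions=x,
        velocities=v,
        pbest_positions=x.copy(),
        pbest_fitness=np.full(cfg.n_particles, -np.inf),
        gbest_position=x[0].copy(),
        gbest_fitness=-np.inf,
    )


def update_velocity(
    x: np.ndarray,
    v: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    cfg: PSOConfig,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
) -> np.ndarray:
    """Inertia-weighted velocity update, clamped to [v_min, v_max].

    ``r1`` and ``r2`` are injectable (scalars or per-dimension vectors) so
    the arithmetic is exactly testable; the optimizer draws them per
    particle, dimension and iteration.
    """
    v_new = (
        cfg.inertia_w * np.asarray(v, dtype=float)
        + cfg.c1 * np.asarray(r1) * (np.asarray(pbest) - np.asarray(x))
        + cfg.c2 * np.asarray(r2) * (np.asarray(gbest) - np.asarray(x))
    )
    return np.clip(v_new, cfg.v_min, cfg.v_max)


def update_position(x: np.ndarray, v_new: np.ndarray, cfg: PSOConfig) -> np.ndarray:
    """Move and clip to the search box."""
    return np.clip(np.asarray(x, dtype=float) + np.asarray(v_new), cfg.lower_bounds, cfg.upper_bounds)


def optimize(fitness: Callable[[np.ndarray], float], cfg: PSOConfig) -> PSOResult:
    """Run the swarm; returns the global best and its per-iteration trace.

    The trace starts with the post-initialization gbest and appends one
    value per iteration; it is non-decreasing by construction.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_particles, cfg.n_dims)
    swarm = initialize_swarm(cfg, rng_seed=cfg.seed)

    def absorb(vals: np.ndarray):
        better = vals > swarm.pbest_fitness
        swarm.pbest_positions[better] = swarm.positions[better]
        swarm.pbest_fitness[better] = vals[better]
        top = int(np.argmax(swarm.pbest_fitness))
        if swarm.pbest_fitness[top] > swarm.gbest_fitness:
            swarm.gbest_fitness = float(swarm.pbest_fitness[top])
            swarm.gbest_position = swarm.pbest_positions[top].copy()

    vals = _evaluate(fitness, swarm.positions)
    absorb(vals)
    trace = [swarm.gbest_fitness]
    mean_trace = [float(vals.mean())]

    stall = 0
    for t in range(cfg.max_iterations):
        r1 = rng.uniform(size=shape)
        r2 = rng.uniform(size=shape)
        v_new = update_velocity(
            swarm.positions,
            swarm.velocities,
            swarm.pbest_positions,
            swarm.gbest_position,
            cfg,
            r1,
            r2,
        )
        x_new = update_position(swarm.positions, v_new, cfg)
        # zero the velocity where the box boundary absorbed the move
        clipped = x_new != swarm.positions + v_new
        v_new[clipped] = 0.0
        swarm.positions, swarm.velocities = x_new, v_new
        swarm.iteration = t + 1

        prev_best = swarm.gbest_fitness
        vals = _evaluate(fitness, swarm.positions)
        absorb(vals)
        trace.append(swarm.gbest_fitness)
        mean_trace.append(float(vals.mean()))

        if cfg.patience is not None:
            stall = 0 if swarm.gbest_fitness - prev_best > cfg.tolerance else stall + 1
            if stall >= cfg.patience:
                break

    return PSOResult(
        best_position=swarm.gbest_position.copy(),
        best_fitness=float(swarm.gbest_fitness),
        trace=np.asarray(trace),
        mean_trace=np.asarray(mean_trace),
        n_iterations=swarm.iteration,
    )
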