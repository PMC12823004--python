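"""Chaotic particle swarm optimizer (C_PSO).

Standard inertia-weight PSO whose stochastic structure is driven by the
logistic chaos map ``x <- mu * x * (1 - x)``: the initial swarm is laid
out along per-dimension chaotic orbits, and (by default) the acceleration
coefficients r1/r2 are successive chaotic iterates rather than uniform
draws.  At ``mu = 4`` the map is fully chaotic and its orbit densely
covers [0, 1], which gives the swarm a well-spread initialization without
an extra quasi-random generator.

Used in this package to tune the gradient-boosting stage's
hyperparameters by minimizing validation RMSE.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .isma import _evaluate
from .searchspace import IterationRecord, OptimizationResult, ParameterBox

__all__ = ["Particle", "SwarmConfig", "logistic_map", "velocity_update", "run_cpso"]


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: float = math.inf


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    ``e`` is the inertia weight, ``c1``/``c2`` the cognitive and social
    learning factors (0.7 / 1.5 / 1.5, conventional PSO practice), ``mu``
    the logistic-map parameter (4 = fully chaotic regime).  ``v_max``
    caps per-dimension velocity as a fraction of the box width.
    ``chaos_mode`` selects where chaos enters: initialization only, or
    initialization plus the r1/r2 coefficients (default).
    """

    e: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    mu: float = 4.0
    swarm_size: int = 30
    T: int = 100
    v_max_fraction: float = 0.2
    chaos_mode: str = "init_and_coefficients"

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if not 0 < self.mu <= 4:
            raise ValueError("mu must lie in (0, 4]")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if self.chaos_mode not in ("init_only", "init_and_coefficients"):
            raise ValueError(f"unknown chaos_mode {self.chaos_mode!r}")


def logistic_map(x: float, mu: float) -> float:
    """One logistic-map iterate ``mu * x * (1 - x)``; stays in [0,1] for mu<=4."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x={x} outside [0, 1]")
    if not 0 < mu <= 4:
        raise ValueError("mu must lie in (0, 4]")
    return mu * x * (1.0 - x)


class _ChaosStream:
    """Endless logistic-map iterate source with a seeded start point.

    Start points are drawn uniformly from (0.01, 0.99) excluding a small
    neighbourhood of 0.5, whose orbit collapses to the fixed point 0 at
    mu = 4.
    """

    def __init__(self, rng: np.random.Generator, mu: float):
        self.mu = mu
        x = rng.uniform(0.01, 0.99)
        while abs(x - 0.5) < 1e-3:
            x = rng.uniform(0.01, 0.99)
        self.x = x

    def next(self) -> float:
        self.x = logistic_map(self.x, self.mu)
        return self.x

    def take(self, n: int) -> np.ndarray:
        return np.array([self.next() for _ in range(n)])


def velocity_update(particle: Particle, g: np.ndarray, cfg: SwarmConfig,
                    r1: float, r2: float,
                    v_max: np.ndarray | None = None) -> np.ndarray:
    """Inertia + cognitive + social velocity rule, clamped to ``±v_max``.

    ``v' = e*v + c1*r1*(p_i - x) + c2*r2*(g - x)``.
    """
    if not (0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0):
        raise ValueError("r1 and r2 must lie in [0, 1]")
    g = np.asarray(g, dtype=float)
    if g.shape != particle.position.shape:
        raise ValueError("global best / particle dimension mismatch")
    v = (cfg.e * particle.velocity
         + cfg.c1 * r1 * (particle.personal_best - particle.position)
         + cfg.c2 * r2 * (g - particle.position))
    if v_max is not None:
        v = np.clip(v, -v_max, v_max)
    return v


def run_cpso(objective, box: ParameterBox, cfg: SwarmConfig | None = None,
             seed: int = 0) -> OptimizationResult:
    """Minimize ``objective`` over ``box`` with the chaotic swarm.

    Positions are initialized from per-dimension logistic orbits rescaled
    to the box; the swarm then advances with the standard position rule
    ``x <- x + v`` under an elitist global best.  Deterministic per seed.
    """
    cfg = cfg or SwarmConfig()
    rng = np.random.default_rng(seed)
    v_max = cfg.v_max_fraction * box.width

    # chaotic initialization: one orbit per dimension, one iterate per particle
    u = np.column_stack([
        _ChaosStream(rng, cfg.mu).take(cfg.swarm_size) for _ in range(box.ndim)
    ])
    positions = box.lower + u * box.width
    particles = [Particle(position=p, velocity=np.zeros(box.ndim),
                          personal_best=p.copy()) for p in positions]

    if cfg.chaos_mode == "init_and_coefficients":
        s1, s2 = _ChaosStream(rng, cfg.mu), _ChaosStream(rng, cfg.mu)
        draw_r = lambda: (s1.next(), s2.next())
    else:
        draw_r = lambda: tuple(rng.uniform(size=2))

    fitness = _evaluate(objective, positions)
    evaluations = cfg.swarm_size
    for p, f in zip(particles, fitness):
        p.personal_best_fitness = float(f)
    best_i = int(np.argmin(fitness))
    g_best = particles[best_i].position.copy()
    g_fitness = float(fitness[best_i])

    history: list[IterationRecord] = []
    for t in range(1, cfg.T + 1):
        for p in particles:
            r1, r2 = draw_r()
            p.velocity = velocity_update(p, g_best, cfg, r1, r2, v_max)
            p.position = box.clip(p.position + p.velocity)
        fitness = _evaluate(objective, [p.position for p in particles])
        evaluations += cfg.swarm_size
        for p, f in zip(particles, fitness):
            if f < p.personal_best_fitness:
                p.personal_best_fitness = float(f)
                p.personal_best = p.position.copy()
        cand = int(np.argmin(fitness))
        if fitness[cand] < g_fitness:
            g_fitness = float(fitness[cand])
            g_best = particles[cand].position.copy()
        history.append(IterationRecord(iteration=t, best_fitness=g_fitness))

    return OptimizationResult(best_position=g_best, best_fitness=g_fitness,
                              history=history, evaluations=evaluations, seed=seed)
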