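"""Improved slime-mould optimizer (ISMA).

A population metaheuristic modelled on slime-mould foraging, extended with

* fitness-proportional *dynamic weights*: per-iteration weights
  ``w_i = lam * fnorm_i / sum_j fnorm_j`` whose budget ``lam`` decays
  linearly over the run, and
* an *adaptive search mechanism*: step size ``alpha`` and shape parameters
  ``beta``, ``gamma`` all decay linearly from a configured maximum to a
  minimum, moving the population from coarse global exploration to fine
  local refinement.

Candidates move toward the elite solution with a sign-guided power-law
step ``x' = x + alpha * sgn(d) * (|d| * beta) ** gamma`` (``d`` the vector
to the incumbent best).  Because that update is purely contractive, the
lowest-weight fraction of the population is re-seeded uniformly each
iteration as a diversity mechanism.

The optimizer minimizes; in the water-quality pipeline the objective is
the validation RMSE of an RBF support vector regressor, so "higher
fitness" in the weighting sense means lower RMSE (see
:func:`normalize_fitness`).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .searchspace import IterationRecord, OptimizationResult, ParameterBox

__all__ = [
    "ScheduleConfig",
    "SlimePopulation",
    "normalize_fitness",
    "update_weights",
    "linear_schedule",
    "position_update",
    "run_isma",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScheduleConfig:
    """Linear-decay bounds for the control parameters and iteration cap.

    Defaults follow the reference configuration for the water-quality
    study: ``alpha`` in [0.1, 1], ``beta`` and ``gamma`` in [0.5, 1],
    ``T = 100`` iterations.  The weight budget ``lam`` mirrors ``alpha``'s
    [0.1, 1] span (its bounds are not fixed by the reference table).
    """

    lambda_max: float = 1.0
    lambda_min: float = 0.1
    alpha_max: float = 1.0
    alpha_min: float = 0.1
    beta_max: float = 1.0
    beta_min: float = 0.5
    gamma_max: float = 1.0
    gamma_min: float = 0.5
    T: int = 100

    def __post_init__(self):
        for name in ("lambda", "alpha", "beta", "gamma"):
            hi = getattr(self, f"{name}_max")
            lo = getattr(self, f"{name}_min")
            if hi < lo:
                raise ValueError(f"{name}_max must be >= {name}_min")
        if self.T < 0:
            raise ValueError("T must be non-negative")


@dataclass
class SlimePopulation:
    """Population state: positions, fitness, weights and the elite."""

    positions: np.ndarray
    fitness: np.ndarray
    weights: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0


def normalize_fitness(fitness, direction: str = "minimize") -> np.ndarray:
    """Map raw fitness values onto [0, 1].

    ``direction="maximize"`` is the literal min-max normalization
    ``(f - min) / (max - min)``.  The pipeline default
    ``direction="minimize"`` inverts it, ``(max - f) / (max - min)``, so
    the *best* (lowest-RMSE) solution maps to 1 and receives the largest
    weight.  A population with all-equal fitness maps to all-ones so that
    the weight denominator never vanishes.
    """
    f = np.asarray(fitness, dtype=float)
    if f.size == 0:
        raise ValueError("fitness vector must be non-empty")
    bad = np.nonzero(~np.isfinite(f))[0]
    if bad.size:
        raise ValueError(f"non-finite fitness at index {int(bad[0])}")
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"unknown direction {direction!r}")
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return np.ones_like(f)
    if direction == "maximize":
        return (f - lo) / (hi - lo)
    return (hi - f) / (hi - lo)


def update_weights(normalized_fitness, lam: float) -> np.ndarray:
    """Fitness-proportional weights scaled to a total budget ``lam``.

    ``w_i = lam * fnorm_i / sum_j fnorm_j``; the weights are non-negative,
    order-preserving in ``fnorm`` and sum to ``lam`` exactly (up to
    floating-point round-off).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    f = np.asarray(normalized_fitness, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError(
            "normalized fitness sums to zero; use normalize_fitness, whose "
            "degenerate fallback guarantees a positive sum"
        )
    return lam * f / total


def linear_schedule(t: int, T: int, v_max: float, v_min: float) -> float:
    """Linear decay from ``v_max`` at ``t=0`` to ``v_min`` at ``t=T``."""
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    if t == 0:
        return float(v_max)
    if t == T:
        return float(v_min)
    return float(v_max - (v_max - v_min) * t / T)


def position_update(x, x_best, alpha: float, beta: float, gamma: float,
                    box: ParameterBox) -> np.ndarray:
    """Sign-guided power-law step toward the incumbent best.

    Elementwise ``x' = x + alpha * sgn(d) * (|d| * beta) ** gamma`` with
    ``d = x_best - x`` and ``sgn(0) = 0``, so a candidate sitting on the
    best solution does not move.  The result is clipped to the box.
    """
    x = np.asarray(x, dtype=float)
    x_best = np.asarray(x_best, dtype=float)
    if x.shape[-1] != box.ndim or x_best.shape[-1] != box.ndim:
        raise ValueError("position/best/box dimension mismatch")
    d = x_best - x
    step = alpha * np.sign(d) * (np.abs(d) * beta) ** gamma
    return box.clip(x + step)


def _normalize_with_failures(fitness: np.ndarray) -> np.ndarray:
    """Minimize-direction normalization tolerating +inf (failed) candidates.

    Failed candidates get normalized fitness 0 (hence the lowest weights);
    an all-failed population degenerates to all-ones so the weight
    denominator stays positive.
    """
    f = np.asarray(fitness, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        return np.ones_like(f)
    out = np.zeros_like(f)
    out[finite] = normalize_fitness(f[finite], "minimize")
    return out


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    out = np.empty(len(positions))
    for i, x in enumerate(positions):
        try:
            v = float(objective(x))
        except Exception:
            logger.warning("objective raised at %s; assigning +inf", x, exc_info=True)
            v = math.inf
        if not math.isfinite(v):
            logger.warning("non-finite objective value at %s; assigning +inf", x)
            v = math.inf
        out[i] = v
    return out


def run_isma(objective, box: ParameterBox, schedule: ScheduleConfig | None = None,
             pop_size: int = 50, seed: int = 0, restart_fraction: float = 0.1,
             tol: float = 1e-6, patience: int = 20,
             dynamic_weights: bool = True,
             adaptive_search: bool = True) -> OptimizationResult:
    """Minimize ``objective`` over ``box`` with the improved slime-mould loop.

    Parameters
    ----------
    objective
        Callable ``position -> float``.  Exceptions and non-finite returns
        are logged and treated as ``+inf`` fitness.
    schedule
        Control-parameter decay bounds and iteration cap ``T``.
    restart_fraction
        Each iteration, the ``ceil(restart_fraction * pop_size)``
        lowest-weight individuals are re-seeded uniformly in the box.
    tol, patience
        Early stop once the incumbent best improves by less than ``tol``
        for ``patience`` consecutive iterations.  Set ``patience`` to
        ``None`` (or ``tol`` to 0) to disable.
    dynamic_weights, adaptive_search
        Ablation toggles: with ``dynamic_weights=False`` every individual
        gets the uniform weight ``lam / N``; with ``adaptive_search=False``
        the control parameters stay pinned at their configured maxima.

    The run is bit-reproducible for a fixed ``(objective, config, seed)``.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    if not 0.0 <= restart_fraction <= 1.0:
        raise ValueError("restart_fraction must lie in [0, 1]")
    sched = schedule or ScheduleConfig()
    rng = np.random.default_rng(seed)

    positions = box.sample(rng, pop_size)
    fitness = _evaluate(objective, positions)
    evaluations = pop_size

    best_i = int(np.argmin(fitness))  # lowest index wins ties
    best_position = positions[best_i].copy()
    best_fitness = float(fitness[best_i])

    history: list[IterationRecord] = []
    stall = 0
    n_restart = math.ceil(restart_fraction * pop_size) if restart_fraction > 0 else 0

    for t in range(1, sched.T + 1):
        lam = linear_schedule(t, sched.T, sched.lambda_max, sched.lambda_min)
        if adaptive_search:
            alpha = linear_schedule(t, sched.T, sched.alpha_max, sched.alpha_min)
            beta = linear_schedule(t, sched.T, sched.beta_max, sched.beta_min)
            gamma = linear_schedule(t, sched.T, sched.gamma_max, sched.gamma_min)
        else:
            alpha, beta, gamma = sched.alpha_max, sched.beta_max, sched.gamma_max

        if dynamic_weights:
            weights = update_weights(_normalize_with_failures(fitness), lam)
        else:
            weights = np.full(pop_size, lam / pop_size)

        positions = position_update(positions, best_position, alpha, beta, gamma, box)
        if n_restart:
            worst = np.argsort(weights, kind="stable")[:n_restart]
            positions[worst] = box.sample(rng, len(worst))

        fitness = _evaluate(objective, positions)
        evaluations += pop_size

        prev_best = best_fitness
        cand = int(np.argmin(fitness))
        if fitness[cand] < best_fitness:
            best_fitness = float(fitness[cand])
            best_position = positions[cand].copy()

        history.append(IterationRecord(
            iteration=t, best_fitness=best_fitness, lam=lam,
            alpha=alpha, beta=beta, gamma=gamma,
            weight_sum=float(weights.sum()),
        ))

        if patience is not None and tol > 0:
            stall = stall + 1 if prev_best - best_fitness < tol else 0
            if stall >= patience:
                break

    return OptimizationResult(
        best_position=best_position, best_fitness=best_fitness,
        history=history, evaluations=evaluations, seed=seed,
    )
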