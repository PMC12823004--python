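"""Shared containers for the population optimizers.

Both the slime-mould optimizer and the chaotic particle swarm search a
bounded continuous box and report their trajectory through the same
:class:`OptimizationResult` record, so downstream code (hyperparameter
tuning, the ablation harness) can treat them interchangeably.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParameterBox", "IterationRecord", "OptimizationResult"]


@dataclass(frozen=True)
class ParameterBox:
    """Axis-aligned continuous search box with named dimensions.

    Parameters
    ----------
    names
        Unique label per dimension (e.g. ``["log10_C", "log10_r", "epsilon"]``).
    lower, upper
        Per-dimension bounds; ``lower[d] < upper[d]`` is required.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, names, lower, upper):
        names = tuple(names)
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if len(set(names)) != len(names):
            raise ValueError("dimension names must be unique")
        if not (len(names) == lower.size == upper.size):
            raise ValueError("names, lower and upper must have equal length")
        if not np.all(lower < upper):
            bad = [names[i] for i in np.nonzero(~(lower < upper))[0]]
            raise ValueError(f"lower must be strictly below upper for {bad}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` points uniformly inside the box."""
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )


@dataclass
class IterationRecord:
    """One row of an optimizer trajectory.

    ``lam``/``alpha``/``beta``/``gamma``/``weight_sum`` are populated by the
    slime-mould optimizer only; the particle swarm leaves them ``None``.
    """

    iteration: int
    best_fitness: float
    lam: float | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    weight_sum: float | None = None


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[IterationRecord] = field(default_factory=list)
    evaluations: int = 0
    seed: int = 0

    def best_as_dict(self, box: ParameterBox) -> dict[str, float]:
        return dict(zip(box.names, map(float, self.best_position)))
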