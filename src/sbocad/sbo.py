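"""Satin bowerbird optimization (SBO).

A population metaheuristic modeled on male satin bowerbirds building display
bowers to attract mates.  Each candidate solution (a "bower") is a real vector
inside a box.  Every cycle, candidates move toward a fitness-weighted blend of
a roulette-selected target bower and the elite (best-so-far) bower, a small
Gaussian mutation perturbs individual coordinates, and the old and new
populations are pooled, sorted by objective and truncated, so the elite is
never lost.

The optimizer is objective-agnostic and minimizes; it is reused both for
refining CNN weights and for wrapper feature selection elsewhere in the
package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Bower",
    "SBOConfig",
    "OptimizationResult",
    "fitness_of",
    "selection_probs",
    "step_size",
    "init_population",
    "update_positions",
    "mutate",
    "optimize",
]


@dataclass
class Bower:
    """One candidate solution: position, raw objective, fitness, selection prob."""

    position: np.ndarray
    objective: float = math.nan
    fitness: float = math.nan
    prob: float = math.nan


@dataclass
class SBOConfig:
    """Parameters of the bowerbird search.

    ``alpha_max`` is the greatest step size toward the target/elite blend,
    ``mutation_prob`` the per-coordinate chance of a Gaussian kick, and
    ``variance_ratio`` the mutation scale as a fraction of each box width
    (sigma_j = variance_ratio * (upper_j - lower_j)).  Defaults for the
    three follow the original formulation of the algorithm.
    """

    population_size: int
    max_iterations: int
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    alpha_max: float = 0.94
    mutation_prob: float = 0.05
    variance_ratio: float = 0.02
    seed: int = 0
    # roulette target drawn per element (default) or once per individual
    roulette_per_element: bool = True
    # literal printed update (position-free) instead of the corrected one
    legacy_update: bool = False

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.alpha_max < 0:
            raise ValueError("alpha_max must be non-negative")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.variance_ratio < 0:
            raise ValueError("variance_ratio must be non-negative")
        if self.lower_bounds.shape != self.upper_bounds.shape:
            raise ValueError("bound vectors must share a shape")
        if not (np.isfinite(self.lower_bounds).all() and np.isfinite(self.upper_bounds).all()):
            raise ValueError("bounds must be finite")
        if not np.all(self.lower_bounds < self.upper_bounds):
            raise ValueError("lower_bounds must be elementwise below upper_bounds")

    @property
    def dimension(self) -> int:
        return int(self.lower_bounds.size)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_objective: float
    history: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        """JSON-serializable summary (seed always recorded)."""
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_objective": float(self.best_objective),
            "history": [float(v) for v in self.history],
            "seed": int(self.seed),
        }


def fitness_of(objective_value: float) -> float:
    """Map a raw objective f to a strictly positive fitness.

    fit = 1/(1+f) for f >= 0 and 1 + |f| for f < 0, so lower objectives
    always earn higher fitness and the map never touches zero.
    """
    f = float(objective_value)
    if not math.isfinite(f):
        raise ValueError("objective value must be finite")
    return 1.0 / (1.0 + f) if f >= 0 else 1.0 + abs(f)


def selection_probs(fitness: np.ndarray) -> np.ndarray:
    """Normalize fitness values into roulette-wheel probabilities."""
    fit = np.asarray(fitness, dtype=float)
    if fit.size == 0:
        raise ValueError("empty population")
    return fit / fit.sum()


def step_size(alpha_max: float, target_prob: float) -> float:
    """Attraction step lambda = alpha_max / (1 + o) toward a target of prob o.

    Bounded in [alpha_max/2, alpha_max] since o lies in [0, 1].
    """
    if alpha_max < 0:
        raise ValueError("alpha_max must be non-negative")
    if not 0.0 <= target_prob <= 1.0:
        raise ValueError("target_prob must lie in [0, 1]")
    return alpha_max / (1.0 + target_prob)


def init_population(config: SBOConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random positions inside the box, one row per bower."""
    return rng.uniform(
        config.lower_bounds,
        config.upper_bounds,
        size=(config.population_size, config.dimension),
    )


def update_positions(
    positions: np.ndarray,
    probs: np.ndarray,
    elite: np.ndarray,
    config: SBOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move every coordinate toward the midpoint of a roulette target and the elite.

    new = old + lambda * ((target + elite)/2 - old), clipped to the box;
    lambda = alpha_max / (1 + prob(target)).  With ``legacy_update`` the
    literal position-free variant new = lambda*(target+elite)/2 is used.
    """
    nb, dim = positions.shape
    if config.roulette_per_element:
        targets = rng.choice(nb, size=(nb, dim), p=probs)
    else:
        targets = np.repeat(rng.choice(nb, size=(nb, 1), p=probs), dim, axis=1)
    lam = config.alpha_max / (1.0 + probs[targets])
    target_vals = positions[targets, np.arange(dim)[None, :]]
    blend = 0.5 * (target_vals + elite[None, :])
    if config.legacy_update:
        new = lam * blend
    else:
        new = positions + lam * (blend - positions)
    return np.clip(new, config.lower_bounds, config.upper_bounds)


def mutate(positions: np.ndarray, config: SBOConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-element Gaussian mutation with std = variance_ratio * box width."""
    sigma = config.variance_ratio * (config.upper_bounds - config.lower_bounds)
    hit = rng.random(positions.shape) < config.mutation_prob
    kicked = positions + hit * (sigma * rng.standard_normal(positions.shape))
    return np.clip(kicked, config.lower_bounds, config.upper_bounds)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.empty(len(positions))
    for i, p in enumerate(positions):
        v = float(objective(p))
        if not math.isfinite(v):
            logger.warning("objective returned non-finite value; treating as +inf")
            v = math.inf
        vals[i] = v
    return vals


def optimize(
    objective,
    config: SBOConfig,
    rng: np.random.Generator | None = None,
    initial: np.ndarray | None = None,
) -> OptimizationResult:
    """Run the full SBO loop for ``max_iterations`` cycles.

    Each cycle: compute fitness/probabilities, move positions toward the
    target/elite blend, mutate, evaluate the moved population, then pool it
    with the old one, sort by objective and keep the best ``population_size``
    rows.  Pool-and-truncate makes the per-iteration best monotone
    non-increasing (elitism).

    ``initial``, if given, seeds one bower of the starting population, so the
    returned best can never be worse than the supplied start point.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = init_population(config, rng)
    if initial is not None:
        positions[0] = np.clip(np.asarray(initial, dtype=float),
                               config.lower_bounds, config.upper_bounds)
    objectives = _evaluate(objective, positions)
    history: list[float] = []

    for _ in range(config.max_iterations):
        fitness = np.array([fitness_of(v) if math.isfinite(v) else np.finfo(float).tiny
                            for v in objectives])
        probs = selection_probs(fitness)
        elite = positions[int(np.argmin(objectives))]
        moved = update_positions(positions, probs, elite, config, rng)
        moved = mutate(moved, config, rng)
        moved_obj = _evaluate(objective, moved)
        pool = np.vstack([positions, moved])
        pool_obj = np.concatenate([objectives, moved_obj])
        order = np.argsort(pool_obj, kind="stable")[: config.population_size]
        positions, objectives = pool[order], pool_obj[order]
        history.append(float(objectives[0]))

    best = int(np.argmin(objectives))
    return OptimizationResult(
        best_position=positions[best].copy(),
        best_objective=float(objectives[best]),
        history=history,
        seed=config.seed,
    )
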