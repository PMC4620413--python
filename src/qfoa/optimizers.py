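"""Fruit fly optimization: quantum-phase variant and classic baseline.

The fruit fly optimization algorithm (FOA) is a swarm metaheuristic: candidate
"flies" scatter randomly around the swarm position (smell search), each decodes
its position into a solution whose objective value is its smell concentration,
and the swarm relocates to the best fly (vision search).

The quantum-phase variant encodes each solution coordinate as a pair of phase
angles (theta_x, theta_y).  The angle pair defines cosine and sine amplitude
pairs, so every fly decodes into TWO complementary candidate solutions at the
price of one position — doubling the effective search space.  Diversity is
maintained by a quantum NOT-gate mutation (theta -> pi/2 - theta, which swaps
the cosine and sine amplitudes) whose acceptance follows a Boltzmann-style
annealing rule: improving mutations are always kept, worsening ones survive
with a probability that decays with both the fitness loss and the iteration
count.

Both optimizers minimize a scalar objective and are deterministic for a fixed
seed: every random draw comes from one injected ``numpy.random.Generator``
consumed in a fixed, documented order (per iteration: perturbation draws for
all flies, then per fly one mutation-trigger draw, plus — only when the
mutation fires — one coordinate-index draw and one acceptance draw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhasePosition",
    "SolutionPair",
    "OptimizerConfig",
    "OptimizationResult",
    "ObjectiveEvaluationError",
    "wrap_angles",
    "init_phase_population",
    "decode_solutions",
    "perturb_position",
    "mutate_not_gate",
    "acceptance_probability",
    "qfoa_optimize",
    "foa_optimize",
]

Objective = Callable[[np.ndarray], float]


class ObjectiveEvaluationError(RuntimeError):
    """The objective returned a non-finite value; carries the solution."""

    def __init__(self, value: float, solution: np.ndarray):
        super().__init__(
            f"objective returned non-finite value {value!r} at solution {solution!r}"
        )
        self.value = value
        self.solution = np.asarray(solution)


@dataclass(frozen=True)
class PhasePosition:
    """Per-fly phase angles, one (theta_x, theta_y) pair per dimension."""

    x_angles: np.ndarray
    y_angles: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_angles, dtype=float)
        y = np.asarray(self.y_angles, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x_angles and y_angles must be 1-D and equal length")
        object.__setattr__(self, "x_angles", x)
        object.__setattr__(self, "y_angles", y)

    @property
    def dimension(self) -> int:
        return self.x_angles.size


@dataclass(frozen=True)
class SolutionPair:
    """Cosine and sine solutions in [0,1]^n decoded from one position."""

    s_cos: np.ndarray
    s_sin: np.ndarray


@dataclass(frozen=True)
class OptimizerConfig:
    population_size: int = 20
    max_iterations: int = 100
    mutation_prob: float = 0.2
    perturb_range: float = 1.0
    seed: int = 0
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.perturb_range < 0:
            raise ValueError("perturb_range must be >= 0")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")


@dataclass
class OptimizationResult:
    best_fitness_per_iteration: np.ndarray
    best_solution: np.ndarray
    best_position: object
    best_fitness: float
    evaluations: int
    seed: int


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap angles into [-pi, pi]; already-valid angles pass through exactly."""
    a = np.asarray(angles, dtype=float)
    in_range = (a >= -np.pi) & (a <= np.pi)
    return np.where(in_range, a, (a + np.pi) % (2.0 * np.pi) - np.pi)


def init_phase_population(
    config: OptimizerConfig, rng: np.random.Generator
) -> list[PhasePosition]:
    """Draw M positions with every angle theta = pi * (2u - 1), u ~ U[0,1]."""
    out = []
    for _ in range(config.population_size):
        x = np.pi * (2.0 * rng.random(config.dimension) - 1.0)
        y = np.pi * (2.0 * rng.random(config.dimension) - 1.0)
        out.append(PhasePosition(x, y))
    return out


def decode_solutions(pos: PhasePosition) -> SolutionPair:
    """Decode a phase position into its cosine and sine solutions.

    Per dimension j the cosine amplitudes (cos theta_x_j, cos theta_y_j) have
    squared length cos^2 + cos^2 in [0, 2]; dividing by the maximum 2 lands
    the value in [0, 1] and makes the cosine and sine solutions exactly
    complementary (s_cos + s_sin = 1), mirroring amplitude normalization
    cos^2 + sin^2 = 1.
    """
    cx, cy = np.cos(pos.x_angles), np.cos(pos.y_angles)
    s_cos = (cx * cx + cy * cy) / 2.0
    return SolutionPair(s_cos=s_cos, s_sin=1.0 - s_cos)


def perturb_position(
    base: PhasePosition, config: OptimizerConfig, rng: np.random.Generator
) -> PhasePosition:
    """Add an independent U[-perturb_range, +perturb_range] draw per angle, then wrap."""
    r = config.perturb_range
    vx = rng.uniform(-r, r, size=base.dimension)
    vy = rng.uniform(-r, r, size=base.dimension)
    return PhasePosition(wrap_angles(base.x_angles + vx), wrap_angles(base.y_angles + vy))


def mutate_not_gate(
    pos: PhasePosition, rng: np.random.Generator, mutation_prob: float
) -> tuple[PhasePosition, bool]:
    """With probability ``mutation_prob``, apply theta -> pi/2 - theta to one angle.

    The gate exchanges the cosine and sine amplitudes of the chosen coordinate
    (cos(pi/2 - theta) = sin(theta)) and is an involution.  The mutated angle
    is wrapped back into [-pi, pi).  Draw order: one trigger draw always; one
    coordinate-index draw only when the mutation fires.
    """
    if rng.random() >= mutation_prob:
        return pos, False
    n = pos.dimension
    idx = int(rng.integers(2 * n))
    x = pos.x_angles.copy()
    y = pos.y_angles.copy()
    if idx < n:
        x[idx] = wrap_angles(np.pi / 2.0 - x[idx])
    else:
        y[idx - n] = wrap_angles(np.pi / 2.0 - y[idx - n])
    return PhasePosition(x, y), True


def acceptance_probability(f_new: float, f_old: float, iteration: int) -> float:
    """Boltzmann-style acceptance of a mutated position at a given iteration.

    Strict improvements are accepted with probability 1; otherwise the
    logistic ``1 / (1 + exp(iteration * (f_new - f_old)))`` applies, which is
    <= 1/2 and decays both in the worsening and in the iteration count, so the
    search anneals toward pure descent.
    """
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    if f_new < f_old:
        return 1.0
    arg = iteration * (f_new - f_old)
    if arg > 700.0:  # exp overflow guard
        return 0.0
    return 1.0 / (1.0 + math.exp(arg))


def _check_finite(value: float, solution: np.ndarray) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ObjectiveEvaluationError(value, solution)
    return value


class _DualEvaluator:
    """Evaluates both decoded solutions of a position; tracks call count."""

    def __init__(self, objective: Objective):
        self.objective = objective
        self.evaluations = 0

    def __call__(self, pos: PhasePosition) -> tuple[float, np.ndarray]:
        pair = decode_solutions(pos)
        f_cos = _check_finite(self.objective(pair.s_cos), pair.s_cos)
        f_sin = _check_finite(self.objective(pair.s_sin), pair.s_sin)
        self.evaluations += 2
        if f_cos <= f_sin:
            return f_cos, pair.s_cos
        return f_sin, pair.s_sin


def qfoa_optimize(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` over [0,1]^n with the quantum-phase fruit fly search.

    Each fly is scored by the better (smaller) of its cosine and sine
    solutions.  The trajectory records the incumbent best after initialization
    and after every iteration, so it is non-increasing and has
    ``max_iterations + 1`` entries; with a zero iteration budget the result is
    simply the best of the initial population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaluate = _DualEvaluator(objective)

    population = init_phase_population(config, rng)
    fitnesses, solutions = [], []
    for pos in population:
        f, s = evaluate(pos)
        fitnesses.append(f)
        solutions.append(s)
    best_i = int(np.argmin(fitnesses))
    best_fitness = fitnesses[best_i]
    best_solution = solutions[best_i].copy()
    best_position = population[best_i]
    axes = best_position  # swarm center the flies scatter around

    trajectory = [best_fitness]
    for it in range(1, config.max_iterations + 1):
        iter_best_f = math.inf
        iter_best: tuple[PhasePosition, np.ndarray] | None = None
        for _ in range(config.population_size):
            pos = perturb_position(axes, config, rng)
            f, s = evaluate(pos)
            mutated, fired = mutate_not_gate(pos, rng, config.mutation_prob)
            if fired:
                f_m, s_m = evaluate(mutated)
                if rng.random() < acceptance_probability(f_m, f, it):
                    pos, f, s = mutated, f_m, s_m
            if f < iter_best_f:
                iter_best_f = f
                iter_best = (pos, s)
        if iter_best is not None and iter_best_f < best_fitness:
            best_fitness = iter_best_f
            best_position, best_solution = iter_best[0], iter_best[1].copy()
            axes = best_position
        trajectory.append(best_fitness)

    return OptimizationResult(
        best_fitness_per_iteration=np.asarray(trajectory),
        best_solution=best_solution,
        best_position=best_position,
        best_fitness=best_fitness,
        evaluations=evaluate.evaluations,
        seed=config.seed,
    )


def foa_optimize(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    init_range: float = 10.0,
    minimize: bool = True,
) -> OptimizationResult:
    """Classic fruit fly baseline over the reciprocal-distance decoding.

    Per dimension the fly holds planar coordinates (X, Y); its smell
    concentration determination value is S = 1 / sqrt(X^2 + Y^2), fed to the
    objective.  The swarm axes start uniformly in [0, init_range]^n and each
    fly scatters by U[-perturb_range, +perturb_range] per coordinate.  A fly
    landing exactly on the origin (S undefined) is re-sampled.  ``minimize``
    selects the optimization sense; the classic formulation maximizes smell,
    but the diagnostic fitness used in this package is minimized.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.dimension
    better = (lambda a, b: a < b) if minimize else (lambda a, b: a > b)
    evaluations = 0

    def scatter(ax: np.ndarray, ay: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        r = config.perturb_range
        while True:
            x = ax + rng.uniform(-r, r, size=n)
            y = ay + rng.uniform(-r, r, size=n)
            dist = np.hypot(x, y)
            if np.all(dist > 0):
                return x, y, 1.0 / dist

    ax = init_range * rng.random(n)
    ay = init_range * rng.random(n)

    best_fitness = math.inf if minimize else -math.inf
    best_xy: tuple[np.ndarray, np.ndarray] | None = None
    best_solution: np.ndarray | None = None
    trajectory = []

    for it in range(config.max_iterations + 1):
        iter_best_f = None
        iter_best = None
        for _ in range(config.population_size):
            x, y, s = scatter(ax, ay)
            f = _check_finite(objective(s), s)
            evaluations += 1
            if iter_best_f is None or better(f, iter_best_f):
                iter_best_f, iter_best = f, (x, y, s)
        if best_xy is None or better(iter_best_f, best_fitness):
            best_fitness = iter_best_f
            best_xy = (iter_best[0], iter_best[1])
            best_solution = iter_best[2].copy()
            ax, ay = best_xy
        trajectory.append(best_fitness)

    return OptimizationResult(
        best_fitness_per_iteration=np.asarray(trajectory),
        best_solution=best_solution,
        best_position=best_xy,
        best_fitness=best_fitness,
        evaluations=evaluations,
        seed=config.seed,
    )
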