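"""Genghis Khan Shark Optimizer (GKSO) and its improved variant IGKSO.

GKSO is a population-based continuous minimizer mimicking the predatory
behaviour of the Genghis Khan shark: individuals alternate between a hunting
drive toward the current prey (global best), a foraging contraction around it,
and an occasional self-protection jump that re-randomises part of a position.
The improved variant (IGKSO) adds two ingredients aimed at global search:

* **Bernoulli chaotic initialization** — initial positions are taken from
  orbits of the piecewise-linear Bernoulli shift map on (0, 1), whose mixing
  dynamics spread the initial population more evenly than i.i.d. uniforms.
* **Spiral-flight mutation** — with a small per-individual probability, a
  logarithmic-spiral move around the global best is proposed and kept only if
  it improves fitness (greedy acceptance, so elitism is preserved).

Everything is a minimizer over a box; maximization problems are handled by
negating the objective at the call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "OptimizationResult",
    "bernoulli_map_step",
    "bernoulli_orbit",
    "init_population",
    "spiral_flight_mutate",
    "gkso_step",
    "optimize",
]

# Baseline GKSO dynamics constants (reconstructed predatory phases, not part
# of the two IGKSO improvements):
# self-protection jump probability per individual per iteration, and the
# per-dimension re-randomisation probability inside a jump.
_SELF_PROTECT_PROB = 0.1
_SELF_PROTECT_DIM_PROB = 0.3
# foraging attention amplitude a = max(_ATTENTION_AMP * p, _MIN_FORAGE_AMP):
# the envelope shrinks as the exploration weight p decays but keeps a floor of
# perturbation noise so the shoal never freezes entirely.
_ATTENTION_AMP = 2.0
_MIN_FORAGE_AMP = 0.2
# IGKSO: spiral mutants may replace their parent (greedy) only once the run
# enters its refinement phase; before that they only challenge the archived
# best, so the mutation cannot collapse swarm diversity mid-exploration.
_REFINE_PHASE = 0.75

_EPS = 1e-12


@dataclass(frozen=True)
class SearchSpace:
    """A bounded axis-aligned box in R^dim."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if lower.size < 1:
            raise ValueError("search space dimension must be >= 1")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        if not np.all(lower < upper):
            raise ValueError("lower must be strictly below upper elementwise")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    @classmethod
    def cube(cls, dim: int, lower: float, upper: float) -> "SearchSpace":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 30
    iterations: int = 200
    seed: int = 0
    bernoulli_lambda: float = 0.4
    spiral_b: float = 1.0
    mutation_prob: float = 0.2
    variant: str = "igkso"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.bernoulli_lambda < 1.0:
            raise ValueError("bernoulli_lambda must be in (0, 1)")
        if self.spiral_b <= 0:
            raise ValueError("spiral_b must be > 0")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.variant not in ("gkso", "igkso"):
            raise ValueError("variant must be 'gkso' or 'igkso'")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    convergence_curve: np.ndarray
    evaluations: int
    config: OptimizerConfig | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "convergence_curve": [float(v) for v in self.convergence_curve],
            "evaluations": int(self.evaluations),
        }


# ---------------------------------------------------------------------------
# Bernoulli chaotic initialization
# ---------------------------------------------------------------------------

def bernoulli_map_step(x: float, lam: float) -> float:
    """One step of the piecewise-linear Bernoulli shift map on (0, 1).

    x -> x / (1 - lam)            if x <= 1 - lam
    x -> (x - (1 - lam)) / lam    otherwise
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"x must lie in the open interval (0, 1), got {x}")
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must lie in (0, 1), got {lam}")
    if x <= 1.0 - lam:
        out = x / (1.0 - lam)
    else:
        out = (x - (1.0 - lam)) / lam
    # keep the orbit strictly inside (0,1) so boundary fixed points cannot trap it
    return min(max(out, _EPS), 1.0 - _EPS)


def bernoulli_orbit(
    x0: float, lam: float, length: int, burn_in: int = 20, thin: int = 10
) -> np.ndarray:
    """Sample `length` values of the Bernoulli map orbit after a burn-in.

    Consecutive orbit values are strongly autocorrelated (the map is linear on
    each branch), so the orbit is thinned: every ``thin``-th value is kept,
    which makes the sampled coordinates effectively independent while
    preserving the chaotic (mixing, uniform-marginal) character of the draw.
    """
    x = min(max(float(x0), _EPS), 1.0 - _EPS)
    for _ in range(burn_in):
        x = bernoulli_map_step(x, lam)
    out = np.empty(length)
    for i in range(length):
        for _ in range(thin):
            x = bernoulli_map_step(x, lam)
        out[i] = x
    return out


def init_population(
    space: SearchSpace,
    population: int,
    lam: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Chaotic population initialization: one Bernoulli orbit per individual.

    Each individual draws a random starting point x0 ~ U(0,1), the map is
    burned in for 20 steps, and the next `dim` orbit values become the
    coordinates in [0,1], affinely mapped onto the box.
    """
    if population < 2:
        raise ValueError("population must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coords = np.empty((population, space.dim))
    for i in range(population):
        x0 = rng.uniform(_EPS, 1.0 - _EPS)
        coords[i] = bernoulli_orbit(x0, lam, space.dim)
    return space.lower + coords * (space.upper - space.lower)


# ---------------------------------------------------------------------------
# Spiral-flight mutation
# ---------------------------------------------------------------------------

def spiral_flight_mutate(
    x: np.ndarray,
    best: np.ndarray,
    b: float,
    l: float,
    space: SearchSpace,
) -> np.ndarray:
    """Logarithmic-spiral move around the global best.

    x' = |best - x| * exp(b*l) * cos(2*pi*l) + best, clamped to the box.
    The spiral parameter l in [-1, 1] is drawn by the caller.
    """
    x = np.asarray(x, dtype=float)
    best = np.asarray(best, dtype=float)
    dist = np.abs(best - x)
    out = dist * math.exp(b * l) * math.cos(2.0 * math.pi * l) + best
    return space.clamp(out)


# ---------------------------------------------------------------------------
# Baseline GKSO dynamics
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    positions: np.ndarray  # (n, dim)
    fitness: np.ndarray    # (n,)
    best_position: np.ndarray
    best_fitness: float
    evaluations: int = 0


def _evaluate(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    return float(objective(x))


def _safe_evaluate(
    objective: Callable[[np.ndarray], float],
    x: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """Evaluate; non-finite values trigger a uniform reset and re-evaluation."""
    f = _evaluate(objective, x)
    n_eval = 1
    while not math.isfinite(f):
        x = rng.uniform(space.lower, space.upper)
        f = _evaluate(objective, x)
        n_eval += 1
    return x, f, n_eval


def gkso_step(
    state: PopulationState,
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    progress: float,
    rng: np.random.Generator,
) -> PopulationState:
    """One iteration of the reconstructed GKSO population update.

    Three predatory behaviours, chosen per individual:

    * hunting drive (exploration): move toward the best with a differential
      kick from two random peers, `x + r1*(best - x) + p*r2*(xa - xb)`;
    * foraging contraction (exploitation): close in on the prey with a
      stochastic per-dimension attention term, `best - A*|C*best - x|` with
      A ~ U(-a, a), a = max(2p, 0.2), and C ~ U(0, 2), so the envelope
      shrinks as p decays but retains a floor of perturbation noise;
    * self-protection (rarely): re-randomise a random subset of dimensions
      uniformly inside the bounds; the jump is taken unconditionally (a
      restart that maintains diversity), all other moves are accepted only
      on improvement.

    `progress` in [0, 1] drives the exploration weight p = 1 - progress,
    which sets both the phase-selection probability (early iterations hunt,
    late iterations forage around the prey) and the foraging radius.
    The global best is tracked over everything evaluated, so it is monotone
    even across forced self-protection restarts.
    """
    n, dim = state.positions.shape
    p = 1.0 - progress
    positions = state.positions
    fitness = state.fitness.copy()
    new_positions = positions.copy()
    best = state.best_position
    evals = 0

    explore = rng.random(n) < p
    r1 = rng.random((n, dim))
    r2 = rng.random((n, dim))
    r3 = rng.random((n, dim))
    r4 = rng.random((n, dim))
    peers_a = rng.integers(0, n, size=n)
    peers_b = rng.integers(0, n, size=n)
    protect = rng.random(n) < _SELF_PROTECT_PROB
    protect_dims = rng.random((n, dim)) < _SELF_PROTECT_DIM_PROB
    uniform_draw = rng.uniform(space.lower, space.upper, size=(n, dim))

    a = max(_ATTENTION_AMP * p, _MIN_FORAGE_AMP)
    attention = np.abs(2.0 * r4 * best - positions)
    candidate = np.where(
        explore[:, None],
        positions + r1 * (best - positions)
        + p * r2 * (positions[peers_a] - positions[peers_b]),
        best - (2.0 * a * r3 - a) * attention,
    )
    jump = protect[:, None] & protect_dims
    candidate = np.where(jump, uniform_draw, candidate)
    candidate = space.clamp(candidate)

    best_fit = state.best_fitness
    best_pos = state.best_position.copy()
    for i in range(n):
        xi, fi, ne = _safe_evaluate(objective, candidate[i], space, rng)
        evals += ne
        if fi < fitness[i] or protect[i]:
            new_positions[i] = xi
            fitness[i] = fi
        if fi < best_fit:
            best_fit = fi
            best_pos = xi.copy()

    return PopulationState(
        positions=new_positions,
        fitness=fitness,
        best_position=best_pos,
        best_fitness=best_fit,
        evaluations=state.evaluations + evals,
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig,
) -> OptimizationResult:
    """Minimize `objective` over `space` with GKSO or IGKSO.

    IGKSO uses Bernoulli-chaotic initialization and, after every baseline
    step, proposes a spiral-flight mutation for each individual with
    probability `mutation_prob`.  Acceptance is greedy: a mutant never
    replaces anything unless its fitness improves on it.  During the
    exploration phase mutants challenge only the archived best; once the run
    enters the refinement phase they may also replace their parent
    individual, turning the spiral into a local-search intensifier without
    draining diversity while the swarm is still exploring.
    """
    if not isinstance(config, OptimizerConfig):
        raise TypeError("config must be an OptimizerConfig")
    seq = np.random.SeedSequence(config.seed)
    init_seed, dyn_seed, mut_seed = seq.spawn(3)
    rng_init = np.random.default_rng(init_seed)
    rng = np.random.default_rng(dyn_seed)
    rng_mut = np.random.default_rng(mut_seed)

    if config.variant == "igkso":
        positions = init_population(space, config.population, config.bernoulli_lambda, rng_init)
    else:
        positions = rng_init.uniform(
            space.lower, space.upper, size=(config.population, space.dim)
        )

    fitness = np.empty(config.population)
    evals = 0
    for i in range(config.population):
        positions[i], fitness[i], ne = _safe_evaluate(objective, positions[i], space, rng)
        evals += ne
    best_idx = int(np.argmin(fitness))
    state = PopulationState(
        positions=positions,
        fitness=fitness,
        best_position=positions[best_idx].copy(),
        best_fitness=float(fitness[best_idx]),
        evaluations=evals,
    )

    # The reported best is an archive over everything evaluated.  Mutants
    # enter the swarm's own guiding best only during the refinement phase:
    # an exploration-phase mutant that merely beats the incumbent would
    # otherwise re-anchor the whole shoal and collapse diversity early.
    archive_pos = state.best_position.copy()
    archive_fit = state.best_fitness

    curve = np.empty(config.iterations)
    for t in range(config.iterations):
        progress = t / max(config.iterations - 1, 1)
        state = gkso_step(state, objective, space, progress, rng)
        if state.best_fitness < archive_fit:
            archive_fit = state.best_fitness
            archive_pos = state.best_position.copy()

        if config.variant == "igkso" and config.mutation_prob > 0.0:
            refine = progress >= _REFINE_PHASE
            for i in range(config.population):
                if rng_mut.random() >= config.mutation_prob:
                    continue
                l = rng_mut.uniform(-1.0, 1.0)
                mutant = spiral_flight_mutate(
                    state.positions[i], state.best_position, config.spiral_b, l, space
                )
                mutant, f_mut, ne = _safe_evaluate(objective, mutant, space, rng_mut)
                state.evaluations += ne
                if refine and f_mut < state.fitness[i]:
                    state.positions[i] = mutant
                    state.fitness[i] = f_mut
                    if f_mut < state.best_fitness:
                        state.best_fitness = f_mut
                        state.best_position = mutant.copy()
                if f_mut < archive_fit:
                    archive_fit = f_mut
                    archive_pos = mutant.copy()
        curve[t] = archive_fit

    return OptimizationResult(
        best_position=archive_pos,
        best_fitness=archive_fit,
        convergence_curve=curve,
        evaluations=state.evaluations,
        config=config,
    )
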