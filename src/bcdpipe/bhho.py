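"""Binary Harris Hawk Optimization (BHHO).

A swarm optimizer modeled on the cooperative "surprise pounce" of Harris
hawks, specialized to binary search spaces.  Each hawk carries a binary
position (a 0/1 vector).  An update computes a continuous displacement
from the hawk, the prey (the elitist incumbent — the best solution seen
so far) and the population mean, clips it to [lb, ub], maps every
coordinate through the S-shaped sigmoid transfer to a bit-activation
probability and samples the new binary position, which is then evaluated.
Storing the transferred bits as the position keeps coordinates inside the
sigmoid's steep region, so the sampling stays diverse instead of
saturating at the bounds.

Per hawk and iteration the prey's escape energy G = 2 G0 (1 - J/it_max),
with G0 ~ U(-1, 1), selects the move:

* |G| >= 1 - exploration (random-hawk or mean-referenced jump);
* |G| >= 0.5, e >= 0.5 - soft siege;
* |G| <  0.5, e >= 0.5 - hard siege;
* |G| >= 0.5, e <  0.5 - soft siege with progressive rapid dives
  (greedy, Levy-flight fallback);
* |G| <  0.5, e <  0.5 - hard siege with progressive dives, referenced to
  the population mean.

e ~ U(0, 1) is the prey's escape chance, drawn fresh per update.  The
dive phases are greedy: a candidate replaces the hawk only if its
fitness improves on the hawk's current fitness (at most two extra
evaluations).  All other moves are accepted unconditionally.  All
randomness flows from one seeded generator; identical seed + config +
fitness give a bit-identical result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as gamma_fn

from .config import BHHOConfig

logger = logging.getLogger(__name__)

FitnessFn = Callable[[np.ndarray], float]


@dataclass
class BHHOResult:
    """Best binary solution with its fitness and convergence trace."""

    best_mask: np.ndarray
    best_fitness: float
    trace: list[float]
    iterations: int
    seed: int
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "best_fitness": float(self.best_fitness),
            "n_selected": int(self.best_mask.sum()),
            "dim": int(len(self.best_mask)),
            "iterations": self.iterations,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "trace": [float(f) for f in self.trace],
        }


@dataclass
class HawkPopulation:
    """Hawk states: binary positions, their fitness, and the incumbent prey."""

    positions: np.ndarray          # (pop_size, dim) floats in {0, 1}
    fitness: np.ndarray            # (pop_size,)
    prey_position: np.ndarray      # binary incumbent (best evaluated mask)
    prey_fitness: float
    lb: float
    ub: float
    n_evaluations: int = 0
    _rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def bits(self) -> np.ndarray:
        return self.positions.astype(np.int8)


def sigmoid_transfer(x: np.ndarray | float) -> np.ndarray | float:
    """S-shaped transfer 1 / (1 + exp(-x)): bit-activation probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def binarize(position: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """bit_j = 1 iff draw_j < sigmoid(position_j)."""
    position = np.asarray(position, dtype=float)
    draws = np.asarray(draws, dtype=float)
    if position.shape != draws.shape:
        raise ValueError("position and draws must have equal length")
    return (draws < sigmoid_transfer(position)).astype(np.int8)


def escape_energy(g0: float, j: int, it_max: int) -> float:
    """G = 2 G0 (1 - J / it_max): decays linearly to zero over the run."""
    if not (0 <= j <= it_max):
        raise ValueError("iteration index must lie in [0, it_max]")
    return 2.0 * g0 * (1.0 - j / it_max)


def mean_position(positions: np.ndarray) -> np.ndarray:
    """Arithmetic mean of hawk positions, per dimension."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("population must be non-empty")
    return positions.mean(axis=0)


def levy_sigma(beta: float) -> float:
    """Scale of the Mantegna Levy-step numerator for exponent beta."""
    num = gamma_fn(1 + beta) * math.sin(math.pi * beta / 2.0)
    den = gamma_fn((1 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy(dim: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step 0.01 u / |v|^(1/beta) (Mantegna construction)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    u = rng.normal(0.0, levy_sigma(beta), dim)
    v = rng.normal(0.0, 1.0, dim)
    return 0.01 * u / np.abs(v) ** (1.0 / beta)


def select_phase(g: float, e: float) -> str:
    """Dispatch on (|G|, e): exactly one update rule per draw pair."""
    if abs(g) >= 1.0:
        return "exploration"
    if abs(g) >= 0.5:
        return "soft_siege" if e >= 0.5 else "soft_siege_dive"
    return "hard_siege" if e >= 0.5 else "hard_siege_dive"


def _clip(x: np.ndarray, lb: float, ub: float) -> np.ndarray:
    return np.clip(x, lb, ub)


def exploration_step(
    x: np.ndarray,
    x_rand: np.ndarray,
    x_prey: np.ndarray,
    x_mean: np.ndarray,
    lb: float,
    ub: float,
    r1: float,
    r2: float,
    r3: float,
    r4: float,
    p: float,
) -> np.ndarray:
    """Exploration move: random-hawk jump (p >= 0.5) or mean-referenced jump."""
    if p >= 0.5:
        new = x_rand - r1 * np.abs(x_rand - 2.0 * r2 * x)
    else:
        new = (x_prey - x_mean) - r3 * (lb + r4 * (ub - lb))
    return _clip(new, lb, ub)


def soft_siege_step(x: np.ndarray, x_prey: np.ndarray, g: float, t: float,
                    lb: float, ub: float) -> np.ndarray:
    """Soft siege: delta-to-prey minus an energy-scaled jump term."""
    delta = x_prey - x
    return _clip(delta - g * np.abs(t * x_prey - x), lb, ub)


def hard_siege_step(x: np.ndarray, x_prey: np.ndarray, g: float,
                    lb: float, ub: float) -> np.ndarray:
    """Hard siege: contract straight toward the prey."""
    return _clip(x - g * np.abs(x_prey - x), lb, ub)


def dive_target_soft(x: np.ndarray, x_prey: np.ndarray, g: float, t: float,
                     lb: float, ub: float) -> np.ndarray:
    """First dive candidate Y of the soft siege with rapid dives."""
    return _clip(x_prey - g * np.abs(t * x_prey - x), lb, ub)


def dive_target_hard(x_mean: np.ndarray, x_prey: np.ndarray, g: float, t: float,
                     lb: float, ub: float) -> np.ndarray:
    """First dive candidate Y of the hard siege with dives (mean-referenced)."""
    return _clip(x_prey - g * np.abs(t * x_prey - x_mean), lb, ub)


def init_population(
    dim: int,
    config: BHHOConfig,
    seed: int,
    fitness_fn: FitnessFn,
    init_masks: Sequence[np.ndarray] | None = None,
) -> HawkPopulation:
    """Random initial hawks, evaluated, with the prey set to the best.

    Initial positions are uniform draws in [lb, ub] passed through the
    transfer sampling.  ``init_masks`` are binary vectors injected into
    the initial population and evaluated directly, so the incumbent never
    starts worse than any of them.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    config.validate()
    rng = np.random.default_rng(seed)
    positions = np.empty((config.pop_size, dim))
    for i in range(config.pop_size):
        positions[i] = binarize(rng.uniform(config.lb, config.ub, dim), rng.random(dim))
    init_masks = [np.asarray(m, dtype=np.int8) for m in (init_masks or [])]
    for i, mask in enumerate(init_masks[: config.pop_size]):
        positions[i] = mask

    fitness = np.empty(config.pop_size)
    for i in range(config.pop_size):
        fitness[i] = fitness_fn(positions[i].astype(np.int8))
    n_eval = config.pop_size

    best = int(np.argmin(fitness))
    prey_pos = positions[best].copy()
    prey_fit = float(fitness[best])
    for mask in init_masks[config.pop_size:]:
        f = float(fitness_fn(mask))
        n_eval += 1
        if f < prey_fit:
            prey_fit = f
            prey_pos = mask.astype(float)

    return HawkPopulation(positions, fitness, prey_pos, prey_fit,
                          config.lb, config.ub, n_eval, rng)


def optimize(
    fitness_fn: FitnessFn,
    dim: int,
    config: BHHOConfig | None = None,
    seed: int = 0,
    init_masks: Sequence[np.ndarray] | None = None,
) -> BHHOResult:
    """Run the full BHHO loop and return the best binary vector found.

    ``fitness_fn`` maps a {0,1}^dim vector to a real (lower is better; may
    return +inf for invalid masks).
    """
    config = config or BHHOConfig()
    pop = init_population(dim, config, seed, fitness_fn, init_masks)
    rng = pop._rng
    lb, ub = pop.lb, pop.ub

    def transfer_sample(continuous: np.ndarray) -> np.ndarray:
        """Clip, map through the sigmoid and sample the new binary position."""
        return binarize(_clip(continuous, lb, ub), rng.random(dim)).astype(float)

    def track_prey(position: np.ndarray, f: float) -> None:
        if f < pop.prey_fitness:
            pop.prey_fitness = f
            pop.prey_position = position.copy()

    trace: list[float] = []
    for j in range(1, config.it_max + 1):
        x_mean = mean_position(pop.positions)
        for i in range(config.pop_size):
            x = pop.positions[i]
            g0 = rng.uniform(-1.0, 1.0)
            g = escape_energy(g0, j, config.it_max)
            e = rng.random()
            phase = select_phase(g, e)
            if phase == "exploration":
                p = rng.random()
                r1, r2, r3, r4 = rng.random(4)
                x_rand = pop.positions[rng.integers(config.pop_size)]
                new = transfer_sample(exploration_step(
                    x, x_rand, pop.prey_position, x_mean, lb, ub, r1, r2, r3, r4, p))
            elif phase == "soft_siege":
                t = 2.0 * (1.0 - rng.random())
                new = transfer_sample(soft_siege_step(x, pop.prey_position, g, t, lb, ub))
            elif phase == "hard_siege":
                new = transfer_sample(hard_siege_step(x, pop.prey_position, g, lb, ub))
            else:  # progressive dives, greedy with Levy fallback
                t = 2.0 * (1.0 - rng.random())
                if phase == "soft_siege_dive":
                    y = transfer_sample(dive_target_soft(x, pop.prey_position, g, t, lb, ub))
                else:
                    y = transfer_sample(dive_target_hard(x_mean, pop.prey_position, g, t, lb, ub))
                fy = float(fitness_fn(y.astype(np.int8)))
                pop.n_evaluations += 1
                track_prey(y, fy)
                if fy < pop.fitness[i]:
                    pop.positions[i] = y
                    pop.fitness[i] = fy
                else:
                    z = transfer_sample(y + rng.random(dim) * levy(dim, config.levy_beta, rng))
                    fz = float(fitness_fn(z.astype(np.int8)))
                    pop.n_evaluations += 1
                    track_prey(z, fz)
                    if fz < pop.fitness[i]:
                        pop.positions[i] = z
                        pop.fitness[i] = fz
                    # else: the hawk keeps its position and fitness
                continue
            f = float(fitness_fn(new.astype(np.int8)))
            pop.n_evaluations += 1
            pop.positions[i] = new
            pop.fitness[i] = f
            track_prey(new, f)
        trace.append(pop.prey_fitness)

    logger.info("BHHO: best fitness %.6g after %d iterations (%d evaluations)",
                pop.prey_fitness, config.it_max, pop.n_evaluations)
    return BHHOResult(pop.prey_position.astype(np.int8), pop.prey_fitness, trace,
                      config.it_max, seed, pop.n_evaluations)
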