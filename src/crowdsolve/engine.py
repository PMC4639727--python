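"""Stochastic engine: iterations, scoring, rounds, selection, full games.

One iteration of a group of size ``S``:

1. every player independently joins the collectivists with its own
   probability ``p_i`` (otherwise it plays the iteration alone as an
   individualist);
2. every individualist draws a desired gain ``G`` uniformly from the
   integer range ``[G_min, G_max]``;
3. every collectivist solves the task with probability ``R``; every
   individualist solves its ``G``-times harder task with probability
   ``R**G``.

Scoring: if ``s >= 1`` collectivists solved, the group's capacity is
incremented first (``Sigma -> Sigma + 1``) and then every solving
collectivist contributes the updated capacity ``Sigma`` to every member
of the group, whatever that member's role or outcome — a per-member
shared gain of ``s * Sigma``.  A solving individualist additionally
pockets its drawn ``G`` privately; if no collectivist solved, the shared
gain is zero but private gains are still paid.  Sharing the capacity
itself makes collective payoffs grow superlinearly as knowledge
accumulates, the incremental-advances effect the capacity models.

A round is ``iterations_per_round`` such steps; between rounds a fraction
of the players with below-average fitness is replaced by fresh players
with new uniform ``p``, and all fitness and capacity counters reset.

``run_round`` draws its randomness in whole-round blocks of shape
``(T, n, S)`` (roles, gains, solve draws, in that order) so a round is a
handful of array operations; with ``iterations_per_round=1`` it consumes
the stream exactly like a single :func:`run_iteration` call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    IterationOutcome,
    ModelParams,
    PopulationState,
    init_population,
    spawn_rng,
)

__all__ = [
    "RoundResult",
    "GameResult",
    "sample_roles",
    "solve_probability",
    "apply_iteration_scores",
    "run_iteration",
    "run_round",
    "apply_selection",
    "run_game",
]


@dataclass
class RoundResult:
    """End-of-round snapshot: population, mean fitness, per-group capacity."""

    population: PopulationState
    mean_fitness: float
    per_group_capacity: np.ndarray


@dataclass
class GameResult:
    """End-of-game summary.

    ``final_capacity`` is the capacity each group reached within the last
    round (capacity resets every round, so this is the maximal capacity
    Sigma_max of the evolved population).  ``p_distribution`` is the
    multiset of surviving collaboration probabilities.
    """

    final_mean_p: float
    final_mean_fitness: float
    final_capacity: np.ndarray
    final_capacity_mean: float
    p_distribution: np.ndarray


def sample_roles(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boolean collectivist mask: entry i is True with probability p[i]."""
    p = np.asarray(p, dtype=np.float64)
    return rng.random(p.shape) < p


def solve_probability(role: str, R: float, G: int | None = None) -> float:
    """Per-attempt solving probability for one player.

    Collectivists face the task together and solve it with probability
    ``R``; an individualist with drawn gain ``G`` faces a ``G``-times
    harder task and solves with probability ``R**G``.
    """
    if role == "collectivist":
        return float(R)
    if role == "individualist":
        if G is None:
            raise ValueError("individualist solve probability requires G")
        if G < 1:
            raise ValueError(f"G must be a positive integer, got {G}")
        return float(R) ** int(G)
    raise ValueError(f"unknown role {role!r}")


def apply_iteration_scores(
    population: PopulationState, outcome: IterationOutcome
) -> PopulationState:
    """Apply one iteration's scoring to the population, in place.

    Capacity increments by one in every group where at least one
    collectivist solved; then every member of such a group receives
    ``s * Sigma_new`` (``s`` solving collectivists, each contributing the
    just-updated capacity ``Sigma_new`` to every member).  Solving
    individualists additionally receive their private ``G``, whether or
    not any collectivist solved.
    """
    s = np.sum(outcome.collectivist & outcome.solved, axis=1)
    if not np.array_equal(s, outcome.solver_count):
        raise RuntimeError("inconsistent IterationOutcome: solver_count mismatch")
    inc = outcome.capacity_incremented
    population.capacity += inc
    shared = s * population.capacity  # zero wherever s == 0
    population.fitness += shared[:, None]
    own = np.where(~outcome.collectivist & outcome.solved, outcome.gain, 0)
    population.fitness += own
    return population


def run_iteration(
    population: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, IterationOutcome]:
    """One simultaneous iteration for every group; mutates the population."""
    shape = population.p.shape
    collectivist = rng.random(shape) < population.p
    gain = rng.integers(params.G_min, params.G_max + 1, size=shape)
    prob = np.where(collectivist, params.R, np.float64(params.R) ** gain)
    solved = rng.random(shape) < prob
    outcome = IterationOutcome(collectivist=collectivist, gain=gain, solved=solved)
    apply_iteration_scores(population, outcome)
    return population, outcome


def run_round(
    population: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
) -> RoundResult:
    """Run ``iterations_per_round`` iterations, vectorised as one block.

    The random stream is consumed as three blocks of shape ``(T, n, S)``:
    role draws, gain draws, solve draws.  Fitness and capacity accumulate
    exactly as the per-iteration rules prescribe: the shared gain paid in
    iteration ``t`` uses the capacity *after* that iteration's increment.
    """
    T = params.iterations_per_round
    n, S = population.p.shape
    if T == 0:
        return RoundResult(
            population=population,
            mean_fitness=float(population.fitness.mean()),
            per_group_capacity=population.capacity.copy(),
        )
    u_roles = rng.random((T, n, S))
    gains = rng.integers(params.G_min, params.G_max + 1, size=(T, n, S))
    u_solve = rng.random((T, n, S))

    collectivist = u_roles < population.p  # broadcasts (n, S)
    prob = np.where(collectivist, params.R, np.float64(params.R) ** gains)
    solved = u_solve < prob

    s = np.sum(collectivist & solved, axis=2)  # (T, n) solving collectivists
    inc = s >= 1
    sigma = population.capacity[None, :] + np.cumsum(inc, axis=0)  # (T, n)
    shared = (s * sigma).sum(axis=0)  # per-member shared receipts
    own = np.where(~collectivist & solved, gains, 0).sum(axis=0)

    population.fitness += shared[:, None] + own
    population.capacity += inc.sum(axis=0)
    return RoundResult(
        population=population,
        mean_fitness=float(population.fitness.mean()),
        per_group_capacity=population.capacity.copy(),
    )


def apply_selection(
    population: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Evolutionary replacement between rounds, in place.

    Players with fitness strictly below the population mean form the
    removal pool; ``min(floor(replacement_fraction * N), pool size)`` of
    them, sampled uniformly without replacement, are replaced in their
    group slots by fresh players with new uniform ``p``.  Afterwards all
    fitness values and all capacities reset to zero.  Group sizes never
    change, and a player at or above the mean is never removed.
    """
    fitness_flat = population.fitness.ravel()
    mean_fitness = fitness_flat.mean()
    pool = np.flatnonzero(fitness_flat < mean_fitness)
    k = min(math.floor(params.replacement_fraction * population.N), pool.size)
    if k > 0:
        chosen = rng.choice(pool, size=k, replace=False)
        population.p.flat[chosen] = rng.random(k)
    population.fitness[:] = 0.0
    population.capacity[:] = 0
    return population


def run_game(params: ModelParams) -> GameResult:
    """Run one full game: ``rounds_per_game`` rounds with selection.

    Selection is applied at the beginning of every round after the
    first, so a single-round game applies no selection at all.  Child
    random streams are derived per (purpose, round index) from the
    params seed, making the trajectory reproducible and independent of
    any other game.
    """
    pop = init_population(params, spawn_rng(params.seed, 0))
    last: RoundResult | None = None
    for r in range(params.rounds_per_game):
        if r > 0:
            apply_selection(pop, params, spawn_rng(params.seed, 2, r))
        last = run_round(pop, params, spawn_rng(params.seed, 1, r))
    assert last is not None
    return GameResult(
        final_mean_p=float(pop.p.mean()),
        final_mean_fitness=last.mean_fitness,
        final_capacity=last.per_group_capacity,
        final_capacity_mean=float(last.per_group_capacity.mean()),
        p_distribution=pop.p.ravel().copy(),
    )
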