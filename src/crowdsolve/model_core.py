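"""Domain types, parameter validation and the seedable randomness contract.

The model describes a population of ``N`` players partitioned into
``n = N/S`` groups of equal size ``S``.  Each player carries a fixed
collaboration probability ``p`` (the tendency to attempt tasks together
with the group rather than alone) and an accumulated fitness ``pi``.
Each group carries an integer capacity ``Sigma`` counting the iterations
in which at least one of its collectivists solved the task.

State is stored in dense numpy arrays of shape ``(n, S)`` so that the
engine can vectorise whole rounds; :class:`PlayerState` and
:class:`GroupState` are light record views used by oracles and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "ModelParams",
    "PlayerState",
    "GroupState",
    "PopulationState",
    "IterationOutcome",
    "make_params",
    "init_population",
    "draw_gain",
    "spawn_rng",
]


class ConfigError(ValueError):
    """Raised when a configuration mapping violates the model invariants."""


#: Keys accepted in configuration mappings, with their defaults.
#: ``None`` means the key is required.
PARAM_FIELDS: dict[str, Any] = {
    "N": None,
    "S": None,
    "R": None,
    "G_min": 1,
    "G_max": 10,
    "iterations_per_round": 1000,
    "rounds_per_game": 2000,
    "games": 20,
    "replacement_fraction": 0.2,
    "seed": None,
}


@dataclass(frozen=True)
class ModelParams:
    """All constants of one simulation.

    Parameters
    ----------
    N : int
        Total number of players in the population.
    S : int
        Group size; must divide ``N``.
    R : float
        Task simplicity in ``(0, 1]``.  A collectivist solves the task
        with probability ``R``; an individualist drawing gain ``G``
        solves a ``G``-times harder task, with probability ``R**G``.
    G_min, G_max : int
        Inclusive range of the individualist gain draw (uniform integer).
    iterations_per_round : int
        Task attempts per round before selection.
    rounds_per_game : int
        Rounds per game; selection is applied at the start of every round
        after the first.
    games : int
        Independent games averaged per parameter cell.
    replacement_fraction : float
        Fraction of the population replaced between rounds (drawn from
        the players with fitness strictly below the population mean).
    seed : int
        Root seed of the deterministic random stream.
    """

    N: int
    S: int
    R: float
    G_min: int = 1
    G_max: int = 10
    iterations_per_round: int = 1000
    rounds_per_game: int = 2000
    games: int = 20
    replacement_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ConfigError(f"N must be a positive integer, got {self.N}")
        if self.S < 1:
            raise ConfigError(f"S must be a positive integer, got {self.S}")
        if self.N % self.S != 0:
            raise ConfigError(
                f"group size S={self.S} does not divide population size "
                f"N={self.N}: the number of groups n = N/S must be an integer"
            )
        if not (0.0 < self.R <= 1.0):
            raise ConfigError(f"R must lie in (0, 1], got {self.R}")
        if self.G_min < 1 or self.G_max < self.G_min:
            raise ConfigError(
                f"gain range requires 1 <= G_min <= G_max, got "
                f"[{self.G_min}, {self.G_max}]"
            )
        if self.iterations_per_round < 0:
            raise ConfigError("iterations_per_round must be >= 0")
        if self.rounds_per_game < 1:
            raise ConfigError("rounds_per_game must be >= 1")
        if self.games < 1:
            raise ConfigError("games must be >= 1")
        if not (0.0 <= self.replacement_fraction <= 1.0):
            raise ConfigError(
                f"replacement_fraction must lie in [0, 1], got "
                f"{self.replacement_fraction}"
            )
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    @property
    def n_groups(self) -> int:
        """Number of groups ``n = N / S``."""
        return self.N // self.S

    def with_(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class PlayerState:
    """One player: fixed collaboration probability and accumulated fitness."""

    p: float
    fitness: float = 0.0


@dataclass(frozen=True)
class GroupState:
    """One group: its players (in slot order) and its capacity Sigma."""

    players: tuple[PlayerState, ...]
    capacity: int = 0

    @property
    def size(self) -> int:
        return len(self.players)


@dataclass
class PopulationState:
    """Dense array view of the whole population.

    Attributes
    ----------
    p : ndarray of shape (n, S)
        Collaboration probabilities; row ``j`` is group ``j``.
    fitness : ndarray of shape (n, S)
        Accumulated fitness of each player (reset between rounds).
    capacity : ndarray of shape (n,)
        Integer capacity Sigma_j of each group (reset between rounds).
    """

    p: np.ndarray
    fitness: np.ndarray
    capacity: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.fitness = np.asarray(self.fitness, dtype=np.float64)
        self.capacity = np.asarray(self.capacity, dtype=np.int64)
        if self.p.ndim != 2 or self.p.shape != self.fitness.shape:
            raise ValueError("p and fitness must be matching (n, S) arrays")
        if self.capacity.shape != (self.p.shape[0],):
            raise ValueError("capacity must be a length-n vector")

    @property
    def n_groups(self) -> int:
        return self.p.shape[0]

    @property
    def S(self) -> int:
        return self.p.shape[1]

    @property
    def N(self) -> int:
        return self.p.size

    def group(self, j: int) -> GroupState:
        """Record view of group ``j`` (used by oracles and tests)."""
        players = tuple(
            PlayerState(p=float(self.p[j, i]), fitness=float(self.fitness[j, i]))
            for i in range(self.S)
        )
        return GroupState(players=players, capacity=int(self.capacity[j]))

    def copy(self) -> "PopulationState":
        return PopulationState(
            p=self.p.copy(), fitness=self.fitness.copy(), capacity=self.capacity.copy()
        )


@dataclass
class IterationOutcome:
    """Realised randomness of one iteration, for every group at once.

    ``gain`` holds the drawn gain ``G`` for every player; it is only
    meaningful where ``collectivist`` is False (individualists).
    ``solver_count`` counts solving collectivists per group; the capacity
    increments exactly where ``solver_count >= 1``.
    """

    collectivist: np.ndarray  # (n, S) bool
    gain: np.ndarray  # (n, S) int
    solved: np.ndarray  # (n, S) bool
    solver_count: np.ndarray = field(init=False)  # (n,)
    capacity_incremented: np.ndarray = field(init=False)  # (n,) bool

    def __post_init__(self) -> None:
        self.solver_count = np.sum(self.collectivist & self.solved, axis=1)
        self.capacity_incremented = self.solver_count >= 1


def make_params(raw_config: Mapping[str, Any]) -> ModelParams:
    """Build validated :class:`ModelParams` from a configuration mapping.

    Omitted optional keys take the model defaults; unknown keys and
    missing required keys (``N``, ``S``, ``R``, ``seed``) are errors.
    """
    unknown = set(raw_config) - set(PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = [
        k for k, default in PARAM_FIELDS.items()
        if default is None and k != "seed" and k not in raw_config
    ]
    if "seed" not in raw_config:
        missing.append("seed")
    if missing:
        raise ConfigError(f"missing required configuration keys: {missing}")
    values = {k: raw_config.get(k, d) for k, d in PARAM_FIELDS.items() if k in raw_config or d is not None}
    int_fields = {
        "N", "S", "G_min", "G_max", "iterations_per_round",
        "rounds_per_game", "games", "seed",
    }
    cast: dict[str, Any] = {}
    for k, v in values.items():
        if k in int_fields:
            if float(v) != int(v):
                raise ConfigError(f"{k} must be an integer, got {v!r}")
            cast[k] = int(v)
        else:
            cast[k] = float(v)
    return ModelParams(**cast)


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, *key) path.

    Child streams are derived with :class:`numpy.random.SeedSequence`
    so that e.g. the stream of (game g, round r) never depends on how
    many other games or rounds were run before it.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def init_population(
    params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Fresh population: every ``p`` uniform on [0, 1], all scores zero."""
    n = params.n_groups
    p = rng.random((n, params.S))
    return PopulationState(
        p=p,
        fitness=np.zeros((n, params.S)),
        capacity=np.zeros(n, dtype=np.int64),
    )


def draw_gain(params: ModelParams, rng: np.random.Generator, size=None):
    """Uniform integer gain(s) ``G`` in ``[G_min, G_max]`` inclusive."""
    out = rng.integers(params.G_min, params.G_max + 1, size=size)
    return int(out) if size is None else out
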