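"""Mean-field analysis of collectivist vs. individualist expected fitness.

Treating a group's capacity ``Sigma`` as a quasi-static continuous
parameter and the collectivist density ``alpha`` as fixed, the expected
per-iteration payoffs under the engine's scoring rule have closed forms.
Each solving collectivist contributes the updated capacity ``Sigma`` to
every member of its group, so with ``alpha*S`` collectivists each
solving with probability ``R``:

* a group member whose ``alpha*S`` co-present collectivists solve at
  rate ``R`` expects the shared gain ``alpha * S * R * Sigma``;
* an individualist (defector) expects the shared receipts produced by
  the remaining ``alpha*(S-1)`` collectivists, ``alpha*(S-1)*R*Sigma``,
  plus its private expected gain ``E(R) = E[G * R**G]`` over the uniform
  integer gain draw.

Within one group a defector's realised receipts always dominate a
collectivist's (it receives every shared payment plus its private
gains), so with a single group (``S = N``) individualism is the best
strategy.  Competition *between* groups reverses this: an
all-collectivist group builds capacity faster, and once its capacity
advantage ``delta`` over a group carrying a defector exceeds the
threshold computed by :func:`capacity_gap_threshold`, its members
out-earn the defector and selection favours cooperation.

These forms are the mean-field counterpart of the exact same scoring
rule the stochastic engine implements, so analytics and simulation are
mutually consistent by construction.  The absolute scale of the
thresholds depends on the sharing normalisation (whether each solver
contributes ``Sigma`` or ``Sigma/S``); see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MeanFieldConfig",
    "expected_individual_gain",
    "expected_collectivist_fitness",
    "expected_defector_fitness",
    "capacity_gap_threshold",
    "meanfield_table",
]


@dataclass(frozen=True)
class MeanFieldConfig:
    """Quasi-static group description for the mean-field payoffs.

    ``alpha`` is the collectivist density in the group, ``capacity`` the
    current (continuously treated) capacity ``Sigma``.
    """

    R: float
    S: int
    alpha: float
    capacity: float
    G_min: int = 1
    G_max: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.R <= 1.0):
            raise ValueError(f"R must lie in (0, 1], got {self.R}")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.capacity < 0:
            raise ValueError("capacity must be non-negative")
        if self.G_min < 1 or self.G_max < self.G_min:
            raise ValueError("gain range requires 1 <= G_min <= G_max")


def expected_individual_gain(R: float, G_min: int = 1, G_max: int = 10) -> float:
    """Expected private payoff per iteration of a lone individualist.

    The gain ``G`` is uniform on the integers ``[G_min, G_max]`` and pays
    off with probability ``R**G``, so the expectation is
    ``mean_g(g * R**g)``.  Monotone non-decreasing in ``R``; equals the
    plain mean of the gain range at ``R = 1`` and vanishes as ``R -> 0``.
    """
    if G_min < 1 or G_max < G_min:
        raise ValueError("gain range requires 1 <= G_min <= G_max")
    g = np.arange(G_min, G_max + 1, dtype=np.float64)
    return float(np.mean(g * np.asarray(R, dtype=np.float64) ** g))


def expected_collectivist_fitness(cfg: MeanFieldConfig) -> float:
    """Expected per-iteration shared payoff of a group member.

    ``alpha*S`` collectivists each solve with probability ``R`` and each
    solver contributes ``Sigma`` to every member:
    ``alpha * S * R * Sigma``.  Linear in the capacity, so payoffs grow
    as collective knowledge accumulates.
    """
    return cfg.alpha * cfg.S * cfg.R * cfg.capacity


def expected_defector_fitness(cfg: MeanFieldConfig) -> float:
    """Expected per-iteration payoff of a defector in the same group.

    Shared receipts come from the ``alpha*(S-1)`` collectivists among
    the other members; on top the defector collects its private expected
    gain ``E[G R**G]``.
    """
    shared = cfg.alpha * (cfg.S - 1) * cfg.R * cfg.capacity
    return shared + expected_individual_gain(cfg.R, cfg.G_min, cfg.G_max)


def capacity_gap_threshold(
    R: float,
    S: int,
    regime: str = "large_S",
    G_min: int = 1,
    G_max: int = 10,
) -> float:
    """Minimal capacity advantage at which full cooperation wins.

    Compares an all-collectivist group ``l`` (capacity ``Sigma_l``)
    against a group ``j`` carrying a single defector: the collectivists
    of ``l`` earn at rate ``S * R * Sigma_l`` while ``j``'s defector
    earns ``(S-1) * R * Sigma_j + E[G R**G]``.

    * ``regime="large_S"``: with ``S >> 1`` and measuring from the
      early-game baseline ``Sigma_j ~ 0``, cooperation wins once the
      capacity gap ``delta = Sigma_l - Sigma_j`` exceeds
      ``E[G R**G] / (S * R)`` — continuous and monotone non-decreasing
      in ``R``.
    * ``regime="unit_S"``: for ``S = 1`` the defector receives no shared
      gain at all, so the threshold is the smallest integer capacity
      ``Sigma_l`` with ``R * Sigma_l > E[G R**G]``.

    Undefined at ``R = 0`` (raises).
    """
    if R <= 0.0:
        raise ValueError("capacity gap threshold is undefined at R = 0")
    if R > 1.0:
        raise ValueError(f"R must lie in (0, 1], got {R}")
    if S < 1:
        raise ValueError("S must be >= 1")
    e_gain = expected_individual_gain(R, G_min, G_max)
    if regime == "large_S":
        return e_gain / (S * R)
    if regime == "unit_S":
        return float(math.floor(e_gain / R) + 1)
    raise ValueError(f"regime must be 'large_S' or 'unit_S', got {regime!r}")


def meanfield_table(
    R_values,
    S: int = 100,
    G_min: int = 1,
    G_max: int = 10,
) -> pd.DataFrame:
    """Threshold table over an R grid: (R, delta_large_S, delta_unit_S)."""
    rows = [
        {
            "R": float(R),
            "delta_large_S": capacity_gap_threshold(R, S, "large_S", G_min, G_max),
            "delta_unit_S": capacity_gap_threshold(R, 1, "unit_S", G_min, G_max),
        }
        for R in R_values
    ]
    return pd.DataFrame(rows, columns=["R", "delta_large_S", "delta_unit_S"])
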