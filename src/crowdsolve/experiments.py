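"""Parameter-grid experiments: response surfaces over (S, R) and findings.

The study protocol runs, for each group size ``S`` and task simplicity
``R`` on a fixed grid, a number of independent games and averages three
end-of-game summaries: the mean collaboration probability ``p_bar``, the
mean fitness ``pi_bar`` and the final capacity ``Sigma_max`` (averaged
over the groups of a game, which are statistically equivalent).  The
default grid is ``S in {1, 2, 5, 10, 25, 50, 100}`` for ``N = 100`` and
``R in {0.0001, 0.001, 0.01, 0.1, 0.2, ..., 1}`` — 91 cells.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import run_game
from .model_core import ConfigError, ModelParams

__all__ = [
    "DEFAULT_S_VALUES",
    "DEFAULT_R_VALUES",
    "PRESETS",
    "apply_preset",
    "cell_seed",
    "run_cell",
    "run_grid",
    "find_optimal_size",
    "robustness_scan",
    "trend_summary",
]

DEFAULT_S_VALUES: tuple[int, ...] = (1, 2, 5, 10, 25, 50, 100)
DEFAULT_R_VALUES: tuple[float, ...] = (
    0.0001, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)

#: Budget presets: "paper" is the full study budget, "desk" a scaled-down
#: budget for interactive runs and testing.
PRESETS: dict[str, dict[str, int]] = {
    "paper": {"iterations_per_round": 1000, "rounds_per_game": 2000, "games": 20},
    "desk": {"iterations_per_round": 200, "rounds_per_game": 200, "games": 5},
}

#: CSV column order of a surface table.
SURFACE_COLUMNS = ["S", "R", "mean_p", "mean_fitness", "capacity_max", "games", "seed"]


def apply_preset(params: ModelParams, preset: str) -> ModelParams:
    """Return params with the budget fields of the named preset applied."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return params.with_(**PRESETS[preset])


def cell_seed(base_seed: int, s_index: int, r_index: int, game_index: int) -> int:
    """Deterministic per-game seed for one grid cell.

    Keyed on the (S index, R index, game index) triple so extending the
    grid never perturbs the streams of existing cells.
    """
    ss = np.random.SeedSequence([int(base_seed), s_index, r_index, game_index])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def run_cell(
    base_params: ModelParams,
    S: int,
    R: float,
    s_index: int,
    r_index: int,
) -> dict[str, float]:
    """Run and average all games of one (S, R) grid cell."""
    mean_p, mean_fit, cap = [], [], []
    for g in range(base_params.games):
        seed = cell_seed(base_params.seed, s_index, r_index, g)
        params = base_params.with_(S=S, R=R, seed=seed)
        result = run_game(params)
        mean_p.append(result.final_mean_p)
        mean_fit.append(result.final_mean_fitness)
        cap.append(result.final_capacity_mean)
    return {
        "S": S,
        "R": R,
        "mean_p": float(np.mean(mean_p)),
        "mean_fitness": float(np.mean(mean_fit)),
        "capacity_max": float(np.mean(cap)),
        "games": base_params.games,
        "seed": base_params.seed,
    }


def run_grid(
    base_params: ModelParams,
    S_values: Sequence[int] = DEFAULT_S_VALUES,
    R_values: Sequence[float] = DEFAULT_R_VALUES,
) -> pd.DataFrame:
    """Run the full S x R grid; one row of averaged summaries per cell.

    Every S must divide N; this is checked for the whole grid before any
    simulation starts.
    """
    bad = [S for S in S_values if base_params.N % S != 0]
    if bad:
        raise ConfigError(
            f"group sizes {bad} do not divide N={base_params.N}; "
            f"every S on the grid must yield an integer number of groups"
        )
    rows = [
        run_cell(base_params, S, R, si, ri)
        for si, S in enumerate(S_values)
        for ri, R in enumerate(R_values)
    ]
    return pd.DataFrame(rows, columns=SURFACE_COLUMNS)


def find_optimal_size(
    surface: pd.DataFrame, R: float, criterion: str = "mean_fitness"
) -> int:
    """Group size maximising the criterion at simplicity R.

    Ties break toward the smaller S.  Raises if the requested R is
    absent or the criterion column missing.
    """
    if criterion not in ("mean_fitness", "capacity_max"):
        raise ValueError(f"criterion must be mean_fitness or capacity_max, got {criterion!r}")
    rows = surface[np.isclose(surface["R"], R)]
    if rows.empty:
        raise ValueError(f"surface has no rows at R={R}; available R: "
                         f"{sorted(surface['R'].unique())}")
    rows = rows.sort_values("S")  # ties resolve to the smaller S
    best = rows.loc[rows[criterion].idxmax()]
    return int(best["S"])


def divisors(N: int) -> list[int]:
    """All positive divisors of N, ascending."""
    return [d for d in range(1, N + 1) if N % d == 0]


def robustness_scan(
    N_values: Iterable[int],
    R: float,
    base_params: ModelParams,
    candidates: dict[int, Sequence[int]] | None = None,
    criterion: str = "mean_fitness",
) -> pd.DataFrame:
    """Optimal group size as a function of population size N.

    For each N the candidate sizes default to the divisors of N; the
    table reports the optimum ``S*`` and the ratio ``S*/N``.
    """
    rows = []
    for N in N_values:
        S_values = list((candidates or {}).get(N, divisors(N)))
        params = base_params.with_(N=N, S=S_values[0])
        surface = run_grid(params, S_values=S_values, R_values=[R])
        s_star = find_optimal_size(surface, R, criterion)
        rows.append({"N": N, "optimal_S": s_star, "ratio": s_star / N})
    return pd.DataFrame(rows, columns=["N", "optimal_S", "ratio"])


def trend_summary(surface: pd.DataFrame, axis: str = "R") -> pd.DataFrame:
    """Sign of the rank association of mean_p along one axis.

    For ``axis="R"`` each row gives, for one fixed S, the sign of the
    Spearman association between mean_p and R (+1 increasing, -1
    decreasing, 0 flat); profiles with fewer than 3 points are marked
    undefined.  The ``rho`` column carries the raw coefficient so the
    strength of the trend can be compared across profiles.
    """
    if axis not in ("S", "R"):
        raise ValueError(f"axis must be 'S' or 'R', got {axis!r}")
    other = "S" if axis == "R" else "R"
    rows = []
    for value, prof in surface.groupby(other):
        prof = prof.sort_values(axis)
        if len(prof) < 3:
            rows.append({other: value, "sign": None, "rho": np.nan,
                         "descriptor": "undefined"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(prof[axis], prof["mean_p"]).statistic
        sign = 0 if np.isnan(rho) else int(np.sign(rho))
        rows.append({
            other: value,
            "sign": sign,
            "rho": 0.0 if np.isnan(rho) else float(rho),
            "descriptor": {1: "increasing", -1: "decreasing", 0: "flat"}[sign],
        })
    return pd.DataFrame(rows, columns=[other, "sign", "rho", "descriptor"])
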