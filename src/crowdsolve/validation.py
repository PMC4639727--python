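"""Closed-form oracles that certify the stochastic engine at small scale.

For one iteration of a frozen group configuration (fixed ``p`` vector,
fixed capacity ``Sigma``) every per-iteration expectation has an exact
closed form, so the engine can be checked by Monte-Carlo against it:

* the capacity increments with probability
  ``1 - prod_i (1 - p_i * R)`` (at least one collectivist solves);
* the expected shared gain of every member is
  ``(Sigma + 1) * R * sum_i p_i`` — valid because the shared payment
  is ``s * Sigma_new`` and ``Sigma_new = Sigma + 1`` exactly on the
  event ``s >= 1`` where the payment is non-zero;
* player ``i`` expects the private gain
  ``(1 - p_i) * E[G * R**G]`` from its individualist iterations.

:func:`oracle_suite` replays many independent single iterations through
the real engine and z-tests the empirical means against these forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import run_iteration
from .meanfield import expected_individual_gain
from .model_core import ModelParams, PopulationState, spawn_rng

__all__ = [
    "OracleReport",
    "exact_iteration_expectations",
    "oracle_suite",
    "run_oracle_battery",
]


@dataclass(frozen=True)
class OracleReport:
    """One Monte-Carlo vs. closed-form comparison.

    ``passed`` is True iff the z-score is defined and |z| <= threshold.
    """

    quantity: str
    analytic: float
    estimate: float
    std_error: float
    z: float
    passed: bool

    def __str__(self) -> str:  # compact table row
        return (
            f"{self.quantity:<32s} analytic={self.analytic:11.5f} "
            f"mc={self.estimate:11.5f} se={self.std_error:9.5f} "
            f"z={self.z:+7.2f} {'PASS' if self.passed else 'FAIL'}"
        )


def exact_iteration_expectations(
    p,
    R: float,
    capacity: int = 0,
    G_min: int = 1,
    G_max: int = 10,
) -> dict[str, object]:
    """Closed-form per-iteration expectations for one frozen group.

    Returns the capacity-increment probability, the expected shared gain
    credited to every member, and the expected private (own) gain of
    each player — all for a single iteration starting from ``capacity``.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a non-empty 1-d probability vector")
    increment_probability = 1.0 - np.prod(1.0 - p * R)
    shared_gain = (capacity + 1) * R * p.sum()
    e_own = expected_individual_gain(R, G_min, G_max)
    own_gain = (1.0 - p) * e_own
    return {
        "increment_probability": float(increment_probability),
        "shared_gain_per_member": float(shared_gain),
        "own_gain_per_player": own_gain,
        "expected_collectivist_count": float(p.sum()),
        "expected_gain_draw": (G_min + G_max) / 2.0,
    }


def _report(quantity: str, analytic: float, samples: np.ndarray,
            z_threshold: float) -> OracleReport:
    n = samples.size
    if n == 0:
        return OracleReport(quantity, analytic, float("nan"), float("nan"),
                            float("nan"), passed=False)
    est = float(samples.mean())
    se = float(samples.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if not np.isfinite(se) or se == 0.0:
        # degenerate sampling distribution: exact agreement required
        z = 0.0 if est == analytic else float("inf")
    else:
        z = (est - analytic) / se
    return OracleReport(quantity, analytic, est, se, float(z),
                        passed=bool(np.isfinite(z) and abs(z) <= z_threshold))


def oracle_suite(
    params: ModelParams,
    n_samples: int,
    rng: np.random.Generator | None = None,
    group_p=None,
    capacity: int = 0,
    iteration_fn=run_iteration,
    z_threshold: float = 3.0,
) -> list[OracleReport]:
    """Monte-Carlo certification of one frozen group configuration.

    Replays ``n_samples`` independent single iterations through the
    engine (``iteration_fn``), always restarting from the same fitness
    and capacity, and z-tests the empirical means of the capacity
    increment, the shared gain per member, the private gains, the
    collectivist head-count and the gain draw against the closed forms
    of :func:`exact_iteration_expectations`.
    """
    rng = rng if rng is not None else spawn_rng(params.seed, 9)
    if group_p is None:
        group_p = rng.random(params.S)
    group_p = np.asarray(group_p, dtype=np.float64).reshape(-1)
    S = group_p.size
    exact = exact_iteration_expectations(
        group_p, params.R, capacity, params.G_min, params.G_max
    )

    inc = np.empty(n_samples)
    shared = np.empty(n_samples)
    own_mean = np.empty(n_samples)
    coll_count = np.empty(n_samples)
    gain_draws = np.empty(n_samples)

    pop = PopulationState(
        p=group_p[None, :],
        fitness=np.zeros((1, S)),
        capacity=np.array([capacity], dtype=np.int64),
    )
    for k in range(n_samples):
        pop.fitness[:] = 0.0
        pop.capacity[0] = capacity
        _, outcome = iteration_fn(pop, params, rng)
        inc[k] = float(outcome.capacity_incremented[0])
        own = np.where(~outcome.collectivist & outcome.solved, outcome.gain, 0)[0]
        # shared receipts observed from the fitness ledger, not recomputed
        shared[k] = (pop.fitness.sum() - own.sum()) / S
        own_mean[k] = own.mean()
        coll_count[k] = outcome.collectivist.sum()
        gain_draws[k] = outcome.gain.mean()

    return [
        _report("capacity_increment_probability",
                exact["increment_probability"], inc, z_threshold),
        _report("shared_gain_per_member",
                exact["shared_gain_per_member"], shared, z_threshold),
        _report("own_gain_per_player",
                float(np.mean(exact["own_gain_per_player"])), own_mean,
                z_threshold),
        _report("collectivist_count",
                exact["expected_collectivist_count"], coll_count, z_threshold),
        _report("gain_draw_mean",
                exact["expected_gain_draw"], gain_draws, z_threshold),
    ]


def run_oracle_battery(
    params: ModelParams,
    n_configs: int = 10,
    n_samples: int = 100_000,
    max_S: int = 10,
    z_threshold: float = 3.0,
) -> list[OracleReport]:
    """Oracle suites over several random small-group configurations.

    Each configuration draws a group size in ``[1, max_S]``, a uniform
    ``p`` vector, a starting capacity in ``[0, 20]`` and a simplicity
    ``R`` in (0, 1]; all reports are returned concatenated.
    """
    meta_rng = spawn_rng(params.seed, 7)
    reports: list[OracleReport] = []
    for c in range(n_configs):
        S = int(meta_rng.integers(1, max_S + 1))
        group_p = meta_rng.random(S)
        cap = int(meta_rng.integers(0, 21))
        R = float(meta_rng.uniform(0.05, 1.0))
        cfg_params = params.with_(N=S, S=S, R=R)
        reports.extend(
            oracle_suite(
                cfg_params,
                n_samples,
                rng=spawn_rng(params.seed, 8, c),
                group_p=group_p,
                capacity=cap,
                z_threshold=z_threshold,
            )
        )
    return reports
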