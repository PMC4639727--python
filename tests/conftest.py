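import numpy as np
import pytest

from crowdsolve import ModelParams, PopulationState


@pytest.fixture
def desk_params() -> ModelParams:
    """Scaled-down study budget used throughout the tests."""
    return ModelParams(
        N=100, S=50, R=0.9,
        iterations_per_round=200, rounds_per_game=200, games=5, seed=1,
    )


@pytest.fixture
def tiny_params() -> ModelParams:
    """Minimal budget for contract/schema tests."""
    return ModelParams(
        N=10, S=5, R=0.5,
        iterations_per_round=5, rounds_per_game=3, games=2, seed=7,
    )


def make_population(p_rows, capacity=None) -> PopulationState:
    """Population with prescribed p values; fitness zero."""
    p = np.asarray(p_rows, dtype=np.float64)
    if p.ndim == 1:
        p = p[None, :]
    n = p.shape[0]
    cap = np.zeros(n, dtype=np.int64) if capacity is None else np.asarray(capacity)
    return PopulationState(p=p, fitness=np.zeros_like(p), capacity=cap)
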