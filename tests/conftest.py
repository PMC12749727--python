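import numpy as np
import pytest

from hiertime import (
    Connectome,
    ModelParams,
    SyntheticSpec,
    synth_connectome,
)
from hiertime.gradient import GradientVector


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def decoupled_area() -> Connectome:
    """Single area with no long-range input."""
    return Connectome(
        areas=["A"],
        fln=np.zeros((1, 1)),
        sln=np.zeros((1, 1)),
        dist=np.zeros((1, 1)),
    )


@pytest.fixture
def conn_two() -> Connectome:
    """Two areas coupled only A -> B (fln[B, A] > 0)."""
    fln = np.array([[0.0, 0.0], [1.0, 0.0]])
    sln = np.array([[0.5, 0.6], [0.6, 0.5]])
    dist = np.array([[0.0, 5.0], [5.0, 0.0]])
    return Connectome(areas=["A", "B"], fln=fln, sln=sln, dist=dist)


@pytest.fixture(scope="session")
def conn_small():
    """Small default-spec synthetic connectome (12 areas)."""
    return synth_connectome(SyntheticSpec(n_areas=12, seed=7))


@pytest.fixture(scope="session")
def conn_default():
    """Full default synthetic fixture (30 areas) with its gradient."""
    conn = synth_connectome(SyntheticSpec(seed=0))
    return conn, GradientVector(conn.h_true)
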